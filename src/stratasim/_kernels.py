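"""Numba inner loops for the mechanics layer.

Everything here operates on flat numpy arrays prepared by ``mechanics``:
pair lists with per-pair parameters, membrane edge/hinge tables.  The pair
potential is

    U(r) = 1/2 k_rep (r_eq - r)^2 - k_adh (r_cut - r_eq)/6          r < r_eq
    U(r) = k_adh/(r_cut-r_eq)^2 * [D u^2/2 - u^3/3] - k_adh D/6     r_eq <= r < r_cut
    U(r) = 0                                                        r >= r_cut

with u = r - r_eq, D = r_cut - r_eq; the constant offsets make U continuous.
The corresponding central force magnitude (positive = repulsive) is
k_rep (r_eq - r) below r_eq and -k_adh u (D - u)/D^2 in the adhesion well.

For spheroidal cells ``r`` is the effective separation: the z-component of
the pair vector is rescaled by beta = (a_i+a_j)/(c_i+c_j) >= 1 before taking
the norm, and the force is the exact gradient in that rescaled metric (the
z-force carries an extra factor beta).
"""

import math

import numpy as np
from numba import njit

__all__ = ["pair_forces_kernel", "membrane_forces_kernel", "integrate_kernel"]


@njit(cache=True, fastmath=True)
def pair_forces_kernel(pos_a, pos_b, ii, jj, req, krep, kadh, rcut, beta,
                       Lx, Ly, Fa, Fb):
    """Accumulate pair forces into Fa/Fb; return (energy, n_coincident).

    ``pos_a``/``Fa`` may be the same arrays as ``pos_b``/``Fb`` (intra-species
    lists with ii < jj).  Periodic minimum image in x and y.
    """
    energy = 0.0
    bad = 0
    for p in range(ii.shape[0]):
        i = ii[p]
        j = jj[p]
        dx = pos_a[i, 0] - pos_b[j, 0]
        dy = pos_a[i, 1] - pos_b[j, 1]
        dz = pos_a[i, 2] - pos_b[j, 2]
        dx -= Lx * round(dx / Lx)
        dy -= Ly * round(dy / Ly)
        b = beta[p]
        zz = b * dz
        s2 = dx * dx + dy * dy + zz * zz
        rc = rcut[p]
        if s2 >= rc * rc:
            continue
        if s2 < 1e-24:
            bad += 1
            continue
        s = math.sqrt(s2)
        re = req[p]
        dlt = rc - re
        if s < re:
            f = krep[p] * (re - s)
            energy += 0.5 * krep[p] * (re - s) * (re - s) - kadh[p] * dlt / 6.0
        else:
            u = s - re
            f = -kadh[p] * u * (rc - s) / (dlt * dlt)
            energy += kadh[p] / (dlt * dlt) * (dlt * u * u / 2.0 - u ** 3 / 3.0) \
                - kadh[p] * dlt / 6.0
        inv = f / s
        fx = inv * dx
        fy = inv * dy
        fz = inv * b * zz
        Fa[i, 0] += fx
        Fa[i, 1] += fy
        Fa[i, 2] += fz
        Fb[j, 0] -= fx
        Fb[j, 1] -= fy
        Fb[j, 2] -= fz
    return energy, bad


@njit(cache=True, fastmath=True)
def membrane_forces_kernel(pos, edges, l0, k_stretch, hinges, k_bend,
                           Lx, Ly, F):
    """Stretching + bending forces on membrane particles.

    Energy: sum_edges 1/2 k_stretch (l - l0)^2
          + sum_hinges k_bend (1 - cos theta),
    theta the dihedral deviation from flat.  Returns (energy, n_degenerate);
    degenerate (zero-area) triangles are counted and skipped.
    """
    energy = 0.0
    degenerate = 0
    for e in range(edges.shape[0]):
        i = edges[e, 0]
        j = edges[e, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= Lx * round(dx / Lx)
        dy -= Ly * round(dy / Ly)
        l = math.sqrt(dx * dx + dy * dy + dz * dz)
        if l < 1e-12:
            degenerate += 1
            continue
        f = k_stretch * (l - l0[e]) / l
        F[i, 0] += f * dx
        F[i, 1] += f * dy
        F[i, 2] += f * dz
        F[j, 0] -= f * dx
        F[j, 1] -= f * dy
        F[j, 2] -= f * dz
        energy += 0.5 * k_stretch * (l - l0[e]) * (l - l0[e])

    for h in range(hinges.shape[0]):
        i0 = hinges[h, 0]
        i1 = hinges[h, 1]
        i2 = hinges[h, 2]
        i3 = hinges[h, 3]
        # all relative to x0, minimum image
        e1x = pos[i1, 0] - pos[i0, 0]
        e1y = pos[i1, 1] - pos[i0, 1]
        e1z = pos[i1, 2] - pos[i0, 2]
        e1x -= Lx * round(e1x / Lx)
        e1y -= Ly * round(e1y / Ly)
        x2x = pos[i2, 0] - pos[i0, 0]
        x2y = pos[i2, 1] - pos[i0, 1]
        x2z = pos[i2, 2] - pos[i0, 2]
        x2x -= Lx * round(x2x / Lx)
        x2y -= Ly * round(x2y / Ly)
        x3x = pos[i3, 0] - pos[i0, 0]
        x3y = pos[i3, 1] - pos[i0, 1]
        x3z = pos[i3, 2] - pos[i0, 2]
        x3x -= Lx * round(x3x / Lx)
        x3y -= Ly * round(x3y / Ly)
        # triangle normals: nA = e1 x (x2 - 0), oriented so flat -> both +z
        nAx = e1y * x2z - e1z * x2y
        nAy = e1z * x2x - e1x * x2z
        nAz = e1x * x2y - e1y * x2x
        nBx = x3y * e1z - x3z * e1y
        nBy = x3z * e1x - x3x * e1z
        nBz = x3x * e1y - x3y * e1x
        nA2 = nAx * nAx + nAy * nAy + nAz * nAz
        nB2 = nBx * nBx + nBy * nBy + nBz * nBz
        if nA2 < 1e-24 or nB2 < 1e-24:
            degenerate += 1
            continue
        nAn = math.sqrt(nA2)
        nBn = math.sqrt(nB2)
        el = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        if el < 1e-12:
            degenerate += 1
            continue
        cosq = (nAx * nBx + nAy * nBy + nAz * nBz) / (nAn * nBn)
        if cosq > 1.0:
            cosq = 1.0
        elif cosq < -1.0:
            cosq = -1.0
        # sin theta from (nA x nB) . e_hat
        cxx = nAy * nBz - nAz * nBy
        cxy = nAz * nBx - nAx * nBz
        cxz = nAx * nBy - nAy * nBx
        sinq = (cxx * e1x + cxy * e1y + cxz * e1z) / (nAn * nBn * el)
        energy += k_bend * (1.0 - cosq)
        # gradient of theta (standard hinge formulas; coefficients of nA and
        # nB sum to zero across the four vertices -> translation invariant)
        g2 = el / nA2
        g3 = el / nB2
        a02 = (x2x - e1x) * e1x + (x2y - e1y) * e1y + (x2z - e1z) * e1z
        a03 = (x3x - e1x) * e1x + (x3y - e1y) * e1y + (x3z - e1z) * e1z
        b02 = x2x * e1x + x2y * e1y + x2z * e1z
        b03 = x3x * e1x + x3y * e1y + x3z * e1z
        # d theta/d x0 = (a02/|e|) * nA/|nA|^2 / ... standard decomposition:
        c0A = a02 / (el * nA2)
        c0B = a03 / (el * nB2)
        c1A = -b02 / (el * nA2)
        c1B = -b03 / (el * nB2)
        # force = -k_bend * sin(theta) * grad(theta); with this vertex
        # ordering the hinge gradient formulas carry an extra sign flip
        s = k_bend * sinq
        F[i2, 0] += s * g2 * nAx
        F[i2, 1] += s * g2 * nAy
        F[i2, 2] += s * g2 * nAz
        F[i3, 0] += s * g3 * nBx
        F[i3, 1] += s * g3 * nBy
        F[i3, 2] += s * g3 * nBz
        F[i0, 0] += s * (c0A * nAx + c0B * nBx)
        F[i0, 1] += s * (c0A * nAy + c0B * nBy)
        F[i0, 2] += s * (c0A * nAz + c0B * nBz)
        F[i1, 0] += s * (c1A * nAx + c1B * nBx)
        F[i1, 1] += s * (c1A * nAy + c1B * nBy)
        F[i1, 2] += s * (c1A * nAz + c1B * nBz)
    return energy, degenerate


@njit(cache=True, fastmath=True)
def integrate_kernel(pos, F, mobile, dt, Lx, Ly, vmax, wrap_xy, zfloor):
    """Overdamped explicit Euler x <- x + F dt (gamma = 1) with a speed clip
    as a numerical guard; wraps x, y periodically and projects z onto the
    rigid support plane underneath the dermal slab.  Returns max
    displacement."""
    maxd = 0.0
    for i in range(pos.shape[0]):
        if not mobile[i]:
            continue
        fx = F[i, 0]
        fy = F[i, 1]
        fz = F[i, 2]
        v = math.sqrt(fx * fx + fy * fy + fz * fz)
        scale = dt
        if v > vmax:
            scale = dt * vmax / v
        dx = fx * scale
        dy = fy * scale
        dz = fz * scale
        pos[i, 0] += dx
        pos[i, 1] += dy
        pos[i, 2] += dz
        if wrap_xy:
            pos[i, 0] %= Lx
            pos[i, 1] %= Ly
        if pos[i, 2] < zfloor:
            pos[i, 2] = zfloor
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if d > maxd:
            maxd = d
    return maxd
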