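"""Pairwise and membrane elastic forces, differential cell-membrane adhesion,
and overdamped time integration for all three particle species.

The force layout:

* dermis-dermis, membrane-dermis and cell-cell interactions use a
  piecewise-quadratic pair potential: linear repulsion below the rest
  separation and a quadratic adhesion well between the rest separation and
  the cutoff (zero force at both ends, peak attraction at the midpoint).
* cell-cell contacts are anisotropic: the z-component of the pair vector is
  rescaled by the mean equatorial-to-polar ratio before taking the norm, so
  flattened cells interact at a shorter vertical range.
* attached basal cells (stem/TA) carry a normal spring to the basement
  membrane with stiffness k_stem or k_TA (k_stem > k_TA); a TA cell whose
  bond is stretched past the detachment gap loses the bond permanently.
* membrane particles carry edge stretching springs and hinge bending
  (energy k_bend (1 - cos theta) per hinge).

Neighbour search uses periodic k-d trees with a Verlet skin; the pair lists
are rebuilt by the engine once per biology tick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._kernels import (integrate_kernel, membrane_forces_kernel,
                       pair_forces_kernel)
from .core_state import CellType, MembraneMesh, SimulationState

__all__ = [
    "pair_force",
    "effective_separation",
    "membrane_elastic_forces",
    "adhesion_to_membrane",
    "NeighborLists",
    "build_neighbor_lists",
    "compute_forces",
    "step",
]


class IntegrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Reference (scalar) operations — also the public spec surface
# ---------------------------------------------------------------------------


def pair_force(pos_i, pos_j, r_eq: float, k_rep: float, k_adh: float,
               r_cut: float):
    """Central pair force on particle i (3-vector).

    Magnitude ``k_rep (r_eq - r)`` (repulsive) for r < r_eq, adhesion well
    ``-k_adh (r - r_eq)(r_cut - r)/(r_cut - r_eq)^2`` for r_eq <= r < r_cut,
    zero beyond the cutoff.  Raises on coincident positions.
    """
    if not (r_cut > r_eq > 0):
        raise ValueError("require r_cut > r_eq > 0")
    d = np.asarray(pos_i, dtype=float) - np.asarray(pos_j, dtype=float)
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise ValueError("coincident positions: pair force direction undefined")
    if r >= r_cut:
        return np.zeros(3)
    if r < r_eq:
        f = k_rep * (r_eq - r)
    else:
        f = -k_adh * (r - r_eq) * (r_cut - r) / (r_cut - r_eq) ** 2
    return f * d / r


def effective_separation(pos_i, pos_j, a_i: float, c_i: float,
                         a_j: float, c_j: float) -> float:
    """Anisotropic contact distance between two spheroidal cells.

    The z-component of the separation is stretched by the mean
    equatorial-to-polar ratio (a_i + a_j)/(c_i + c_j) before taking the
    Euclidean norm; reduces to the plain distance for spheres.  Used with
    rest separation r_eq = a_i + a_j, so two fully flattened cells stacked
    vertically equilibrate at centre distance c_i + c_j.
    """
    d = np.asarray(pos_i, dtype=float) - np.asarray(pos_j, dtype=float)
    beta = (a_i + a_j) / (c_i + c_j)
    return float(math.sqrt(d[0] ** 2 + d[1] ** 2 + (beta * d[2]) ** 2))


def membrane_elastic_forces(mesh: MembraneMesh, k_stretch: float,
                            k_bend: float):
    """Forces on membrane particles from stretching + bending elasticity.

    Returns ``(forces, energy)``; a flat rest mesh gives exactly zero both.
    Raises on degenerate (zero-area) triangles.
    """
    F = np.zeros_like(mesh.pos)
    energy, degenerate = membrane_forces_kernel(
        mesh.pos, mesh.edges, mesh.l0, k_stretch, mesh.hinges, k_bend,
        mesh.Lx, mesh.Ly, F)
    if degenerate:
        raise ValueError(f"{degenerate} degenerate membrane elements")
    return F, energy


def adhesion_to_membrane(cell_pos, cell_type: int, mesh: MembraneMesh,
                         k_stem: float, k_TA: float, rest: float = 1.0,
                         detach_gap: float = 0.5):
    """Spring force on one attached basal cell toward the membrane.

    The bond is a spring on the signed distance to the local membrane
    plane (nearest vertex, vertex normal) with rest length ``rest``;
    returns ``(force_on_cell, still_attached)``.  A TA
    bond stretched beyond ``detach_gap`` breaks (permanently — the engine
    records it); stem bonds never break.
    """
    tree = cKDTree(np.mod(mesh.pos[:, :2], [mesh.Lx, mesh.Ly]),
                   boxsize=[mesh.Lx, mesh.Ly])
    _, v = tree.query(np.mod(np.asarray(cell_pos[:2], dtype=float),
                             [mesh.Lx, mesh.Ly]))
    nrm = mesh.vertex_normals()[v]
    dvec = np.asarray(cell_pos, dtype=float) - mesh.pos[v]
    dvec[0] -= mesh.Lx * round(dvec[0] / mesh.Lx)
    dvec[1] -= mesh.Ly * round(dvec[1] / mesh.Ly)
    d = float(dvec @ nrm)
    k = k_stem if cell_type == CellType.STEM else k_TA
    if cell_type != CellType.STEM and d - rest > detach_gap:
        return np.zeros(3), False
    return -k * (d - rest) * nrm, True


# ---------------------------------------------------------------------------
# Neighbour lists
# ---------------------------------------------------------------------------


@dataclass
class PairList:
    ii: np.ndarray
    jj: np.ndarray
    req: np.ndarray
    krep: np.ndarray
    kadh: np.ndarray
    rcut: np.ndarray
    beta: np.ndarray


@dataclass
class NeighborLists:
    derm_derm: PairList
    mem_derm: PairList
    cell_cell: PairList
    cell_mem: PairList
    nearest_vertex: np.ndarray     # (n_cells,) membrane vertex per cell
    vertex_normals: np.ndarray     # (n_mem, 3)
    travel_sub: float = 0.0        # dermis/membrane travel since substrate build
    travel_cell: float = 0.0       # cell/membrane travel since cell build
    n_cells: int = -1


_ZBIG_PAD = 50.0


def _ptree(pos, Lx, Ly, zlo, zbox):
    q = np.empty_like(pos)
    q[:, 0] = np.mod(pos[:, 0], Lx)
    q[:, 1] = np.mod(pos[:, 1], Ly)
    q[:, 2] = pos[:, 2] - zlo
    return cKDTree(q, boxsize=[Lx, Ly, zbox]), q


def _cross_pairs(tree_a, tree_b, r):
    m = tree_a.sparse_distance_matrix(tree_b, r, output_type="coo_matrix")
    return m.row.astype(np.int64), m.col.astype(np.int64)


def _zbox(state):
    derm, mem, cells = state.dermis, state.membrane, state.cells
    zs = [derm.pos[:, 2].min(), mem.pos[:, 2].min()]
    zmaxs = [derm.pos[:, 2].max(), mem.pos[:, 2].max()]
    if len(cells):
        zs.append(cells.pos[:, 2].min())
        zmaxs.append(cells.pos[:, 2].max())
    zlo = min(zs) - 1.0
    return zlo, (max(zmaxs) - zlo) + _ZBIG_PAD


def _build_substrate_lists(state: SimulationState) -> tuple[PairList, PairList]:
    """Dermis-dermis and membrane-dermis Verlet lists."""
    p = state.params
    Lx, Ly = p.Lx_m, p.Ly_m
    skin = p.skin
    zlo, zbox = _zbox(state)
    t_derm, _ = _ptree(state.dermis.pos, Lx, Ly, zlo, zbox)
    t_mem, _ = _ptree(state.membrane.pos, Lx, Ly, zlo, zbox)

    r_dd = p.r_cut_factor * p.dermis_spacing
    pairs = t_derm.query_pairs(r_dd + skin, output_type="ndarray")         .astype(np.int64).reshape(-1, 2)
    n = len(pairs)
    dd = PairList(pairs[:, 0], pairs[:, 1],
                  np.full(n, p.dermis_spacing), np.full(n, p.k_rep),
                  np.full(n, p.k_adh_derm * p.stiffness_mult),
                  np.full(n, r_dd), np.ones(n))

    r_md = p.r_cut_factor * p.membrane_gap
    mi, di = _cross_pairs(t_mem, t_derm, r_md + skin)
    n = len(mi)
    md = PairList(mi, di, np.full(n, p.membrane_gap), np.full(n, p.k_rep),
                  np.full(n, p.k_adh_md), np.full(n, r_md), np.ones(n))
    return dd, md


def _build_cell_lists(state: SimulationState):
    """Cell-cell and cell-membrane lists plus the membrane-bond cache."""
    p = state.params
    Lx, Ly = p.Lx_m, p.Ly_m
    skin = p.skin
    cells, mem = state.cells, state.membrane
    if len(cells) == 0:
        e = np.zeros(0, dtype=np.int64)
        z = np.zeros(0)
        empty = PairList(e, e, z, z, z, z, z)
        return empty, empty, e, mem.vertex_normals()
    zlo, zbox = _zbox(state)
    t_cell, _ = _ptree(cells.pos, Lx, Ly, zlo, zbox)
    a, c = cells.a, cells.c
    r_cc_max = p.r_cut_factor * 2.0 * a.max()
    pairs = t_cell.query_pairs(r_cc_max + skin, output_type="ndarray")         .astype(np.int64).reshape(-1, 2)
    ii, jj = pairs[:, 0], pairs[:, 1]
    req = a[ii] + a[jj]
    rcut = p.r_cut_factor * req
    # prune pairs that cannot reach their own cutoff before the next
    # rebuild (they would contribute exactly zero force): a pair listed at
    # Euclidean distance >= rcut + skin needs both partners to travel more
    # than skin/2, which triggers a rebuild first
    d = cells.pos[ii] - cells.pos[jj]
    d[:, 0] -= Lx * np.round(d[:, 0] / Lx)
    d[:, 1] -= Ly * np.round(d[:, 1] / Ly)
    keep = np.einsum("ij,ij->i", d, d) < (rcut + skin) ** 2
    ii, jj, req, rcut = ii[keep], jj[keep], req[keep], rcut[keep]
    cc = PairList(ii, jj, req, np.full(len(ii), p.k_rep),
                  np.full(len(ii), p.k_adh_cell), rcut,
                  (a[ii] + a[jj]) / (c[ii] + c[jj]))
    # the cell <-> membrane interaction is a plane barrier + bond spring on
    # the nearest-vertex local plane (see compute_forces), so only the
    # nearest vertex and the vertex normals are cached here
    e = np.zeros(0, dtype=np.int64)
    z = np.zeros(0)
    cm = PairList(e, e, z, z, z, z, z)
    t_mem2d = cKDTree(np.mod(mem.pos[:, :2], [Lx, Ly]), boxsize=[Lx, Ly])
    _, nearest = t_mem2d.query(np.mod(cells.pos[:, :2], [Lx, Ly]))
    return cc, cm, nearest.astype(np.int64), mem.vertex_normals()


def build_neighbor_lists(state: SimulationState) -> NeighborLists:
    """Rebuild all Verlet pair lists and the membrane-bond cache."""
    dd, md = _build_substrate_lists(state)
    cc, cm, nearest, normals = _build_cell_lists(state)
    return NeighborLists(dd, md, cc, cm, nearest, normals,
                         0.0, 0.0, len(state.cells))


def _get_lists(state: SimulationState) -> NeighborLists:
    nl = state._neighbors
    half_skin = state.params.skin * 0.5
    if nl is None:
        nl = build_neighbor_lists(state)
        state._neighbors = nl
        return nl
    if nl.travel_sub > half_skin:
        nl.derm_derm, nl.mem_derm = _build_substrate_lists(state)
        nl.travel_sub = 0.0
    if nl.n_cells != len(state.cells) or nl.travel_cell > half_skin:
        (nl.cell_cell, nl.cell_mem, nl.nearest_vertex,
         nl.vertex_normals) = _build_cell_lists(state)
        nl.travel_cell = 0.0
        nl.n_cells = len(state.cells)
    return nl


# ---------------------------------------------------------------------------
# Force assembly and integration
# ---------------------------------------------------------------------------


def compute_forces(state: SimulationState, nl: NeighborLists | None = None,
                   with_energy: bool = False):
    """Assemble forces on dermal particles, membrane particles and cells.

    Returns ``(F_derm, F_mem, F_cell, energy)``; the energy covers the pair
    potentials, membrane elasticity and the membrane-bond springs.
    """
    if nl is None:
        nl = _get_lists(state)
    p = state.params
    Lx, Ly = p.Lx_m, p.Ly_m
    derm, mem, cells = state.dermis, state.membrane, state.cells

    F_derm = np.zeros_like(derm.pos)
    F_mem = np.zeros_like(mem.pos)
    F_cell = np.zeros_like(cells.pos)
    energy = 0.0
    bad = 0

    g = nl.derm_derm
    e, b = pair_forces_kernel(derm.pos, derm.pos, g.ii, g.jj, g.req, g.krep,
                              g.kadh, g.rcut, g.beta, Lx, Ly, F_derm, F_derm)
    energy += e
    bad += b
    g = nl.mem_derm
    e, b = pair_forces_kernel(mem.pos, derm.pos, g.ii, g.jj, g.req, g.krep,
                              g.kadh, g.rcut, g.beta, Lx, Ly, F_mem, F_derm)
    energy += e
    bad += b
    if len(cells):
        g = nl.cell_cell
        e, b = pair_forces_kernel(cells.pos, cells.pos, g.ii, g.jj, g.req,
                                  g.krep, g.kadh, g.rcut, g.beta, Lx, Ly,
                                  F_cell, F_cell)
        energy += e
        bad += b
    if bad:
        raise IntegrationError(f"{bad} coincident particle pairs")

    e_mem, degenerate = membrane_forces_kernel(
        mem.pos, mem.edges, mem.l0, p.k_stretch, mem.hinges, p.k_bend,
        Lx, Ly, F_mem)
    if degenerate:
        raise IntegrationError(f"{degenerate} degenerate membrane elements")
    energy += e_mem

    # cell <-> membrane: a plane barrier keeps every cell on its side of
    # the local membrane plane (nearest vertex v, vertex normal n), and
    # attached basal cells additionally carry a bond spring on the same
    # signed plane distance h = n . (x - x_v), rest length c_i
    if len(cells):
        v = nl.nearest_vertex
        nrm = nl.vertex_normals[v]
        dvec = cells.pos - mem.pos[v]
        dvec[:, 0] -= Lx * np.round(dvec[:, 0] / Lx)
        dvec[:, 1] -= Ly * np.round(dvec[:, 1] / Ly)
        h = np.einsum("ij,ij->i", dvec, nrm)
        contact = np.abs(h) < cells.c
        if contact.any():
            over = cells.c[contact] - np.abs(h[contact])
            fmag = p.k_rep * over * np.sign(h[contact])
            fv = fmag[:, None] * nrm[contact]
            F_cell[contact] += fv
            np.add.at(F_mem, v[contact], -fv)
            energy += float(np.sum(0.5 * p.k_rep * over ** 2))
        att = cells.attached
        if att.any():
            rest = cells.c[att]
            k = np.where(cells.type[att] == CellType.STEM, p.k_stem, p.k_TA)
            fmag = -k * (h[att] - rest)
            fv = fmag[:, None] * nrm[att]
            F_cell[att] += fv
            np.add.at(F_mem, v[att], -fv)
            energy += float(np.sum(0.5 * k * (h[att] - rest) ** 2))

    return F_derm, F_mem, F_cell, energy


def step(state: SimulationState, dt: float,
         nl: NeighborLists | None = None) -> float:
    """Advance all mobile positions by one overdamped Euler step.

    The immobile dermal bottom layer stays fixed; x and y wrap periodically.
    Returns the maximum single-particle displacement.  Raises
    ``IntegrationError`` on non-finite positions.
    """
    p = state.params
    if nl is None:
        nl = _get_lists(state)
    F_derm, F_mem, F_cell, _ = compute_forces(state, nl)
    Lx, Ly = p.Lx_m, p.Ly_m
    zfloor = float(state.dermis.pos[~state.dermis.mobile, 2].min()) \
        if (~state.dermis.mobile).any() else -np.inf
    d1 = integrate_kernel(state.dermis.pos, F_derm, state.dermis.mobile,
                          dt, Lx, Ly, p.vmax, True, zfloor)
    ones_m = np.ones(len(F_mem), dtype=bool)
    d2 = integrate_kernel(state.membrane.pos, F_mem, ones_m, dt, Lx, Ly,
                          p.vmax, True, zfloor)
    if len(state.cells):
        ones_c = np.ones(len(F_cell), dtype=bool)
        d3 = integrate_kernel(state.cells.pos, F_cell, ones_c, dt, Lx, Ly,
                              p.vmax, True, zfloor)
    else:
        d3 = 0.0
    nl.travel_sub += max(d1, d2)
    nl.travel_cell += max(d2, d3)
    for name, arr in (("dermis", state.dermis.pos),
                      ("membrane", state.membrane.pos),
                      ("cells", state.cells.pos)):
        if len(arr) and not np.all(np.isfinite(arr)):
            raise IntegrationError(f"non-finite position in {name}")
    state.t += dt
    return max(d1, d2, d3)


def total_energy(state: SimulationState) -> float:
    """Mechanical energy (pair + membrane elastic + bond springs)."""
    nl = build_neighbor_lists(state)
    return compute_forces(state, nl, with_energy=True)[3]
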