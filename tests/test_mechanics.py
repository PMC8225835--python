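"""Pair forces, membrane elasticity, adhesion, integration and the
mechanics invariants (Newton pairs, energy descent)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stratasim import mechanics
from stratasim._kernels import membrane_forces_kernel, pair_forces_kernel
from stratasim.core_state import (CellType, MembraneMesh, Params,
                                  build_initial_state)


# ---------------------------------------------------------------------------
# pair_force
# ---------------------------------------------------------------------------


def test_pair_force_zero_at_rest_and_cutoff():
    assert np.allclose(mechanics.pair_force([1, 0, 0], [0, 0, 0],
                                            1.0, 2.0, 1.0, 1.5), 0)
    assert np.allclose(mechanics.pair_force([1.5, 0, 0], [0, 0, 0],
                                            1.0, 2.0, 1.0, 1.5), 0)


def test_pair_force_repulsive_magnitude():
    """At half the rest separation with k_rep = 1 the repulsion is
    r_eq/2, pointing away from the partner."""
    r_eq = 1.0
    f = mechanics.pair_force([r_eq / 2, 0, 0], [0, 0, 0], r_eq, 1.0, 1.0, 1.5)
    assert np.allclose(f, [r_eq / 2, 0, 0])


def test_pair_force_attractive_well_peak():
    """The adhesion well peaks midway between r_eq and r_cut with
    magnitude k_adh/4."""
    f = mechanics.pair_force([1.25, 0, 0], [0, 0, 0], 1.0, 1.0, 2.0, 1.5)
    assert f[0] < 0
    assert np.isclose(-f[0], 2.0 * 0.25 * 0.25 / 0.25)


def test_pair_force_coincident_raises():
    with pytest.raises(ValueError):
        mechanics.pair_force([0, 0, 0], [0, 0, 0], 1.0, 1.0, 1.0, 1.5)


@given(r=st.floats(0.05, 2.99))
@settings(max_examples=60, deadline=None)
def test_pair_force_continuity(r):
    """The piecewise force is continuous across both joints."""
    def mag(rr):
        return mechanics.pair_force([rr, 0, 0], [0, 0, 0],
                                    1.0, 2.0, 1.5, 2.0)[0]
    eps = 1e-7
    assert abs(mag(r + eps) - mag(max(r - eps, 1e-9))) < 1e-4


def test_equilibrium_separation_converts_to_10_um():
    """Two undifferentiated cells equilibrate at r_eq = a_i + a_j = 2 R,
    i.e. exactly one 10 um cell diameter."""
    p = Params()
    r_eq_model = 1.0 + 1.0        # two unit-radius cells
    assert r_eq_model * p.R == 10.0
    f = mechanics.pair_force([r_eq_model, 0, 0], [0, 0, 0], r_eq_model,
                             p.k_rep, p.k_adh_cell,
                             p.r_cut_factor * r_eq_model)
    assert np.allclose(f, 0.0)


# ---------------------------------------------------------------------------
# effective separation (spheroidal contact)
# ---------------------------------------------------------------------------


def test_effective_separation_isotropic_limit():
    d = mechanics.effective_separation([0, 0, 0], [1, 2, 2], 1, 1, 1, 1)
    assert np.isclose(d, 3.0)


def test_effective_separation_flat_cells_stacked():
    """Two fully flattened cells (c/a = 1/4) stacked vertically interact at
    four times the geometric distance."""
    a = 4.0 ** (1 / 3)
    c = a / 4
    d = mechanics.effective_separation([0, 0, 0.8], [0, 0, 0], a, c, a, c)
    assert np.isclose(d, 4 * 0.8)


def test_effective_separation_lateral_unchanged():
    a = 4.0 ** (1 / 3)
    c = a / 4
    d = mechanics.effective_separation([2.5, 0, 0], [0, 0, 0], a, c, a, c)
    assert np.isclose(d, 2.5)


# ---------------------------------------------------------------------------
# membrane elasticity
# ---------------------------------------------------------------------------


def test_membrane_flat_rest_zero():
    mesh = MembraneMesh.build_flat(12.0, 12.0, 1.0)
    F, E = mechanics.membrane_elastic_forces(mesh, 50.0, 5.0)
    assert abs(E) < 1e-10 and np.abs(F).max() < 1e-10


def test_membrane_stretched_edge_spring_law():
    """Stretching one edge by delta (clamping everything else) produces a
    restoring force k_stretch * delta along the edge."""
    mesh = MembraneMesh.build_flat(12.0, 12.0, 1.0)
    k_stretch = 7.0
    e = mesh.edges[0]
    d = mesh.pos[e[1]] - mesh.pos[e[0]]
    d[:2] -= np.round(d[:2] / 12.0) * 12.0
    u = d / np.linalg.norm(d)
    delta = 0.05
    mesh.l0[0] -= delta          # equivalent to stretching that edge alone
    F, E = mechanics.membrane_elastic_forces(mesh, k_stretch, 0.0)
    assert np.isclose(np.linalg.norm(F[e[0]]), k_stretch * delta, rtol=1e-9)
    assert np.allclose(F[e[0]] / np.linalg.norm(F[e[0]]), u, atol=1e-9)
    assert np.isclose(E, 0.5 * k_stretch * delta ** 2)


def test_membrane_hinge_folded_90_degrees():
    """A single hinge folded to 90 degrees stores energy k_bend."""
    pos = np.array([[0, 0, 0], [1, 0, 0], [0.5, 1, 0], [0.5, 0, 1.0]],
                   dtype=float)
    edges = np.array([[0, 1]], dtype=np.int32)
    hinges = np.array([[0, 1, 2, 3]], dtype=np.int32)
    F = np.zeros_like(pos)
    kb = 5.0
    E, deg = membrane_forces_kernel(pos, edges, np.array([1.0]), 0.0,
                                    hinges, kb, 100.0, 100.0, F)
    assert deg == 0
    assert np.isclose(E, kb)      # 1 - cos(90 deg) = 1


def test_membrane_forces_match_finite_differences(rng):
    """Analytic stretching + bending forces equal -dE/dx."""
    mesh = MembraneMesh.build_flat(10.0, 10.0, 1.0)
    mesh.pos[:, 2] += 0.2 * rng.standard_normal(len(mesh.pos))
    mesh.pos[:, :2] += 0.05 * rng.standard_normal((len(mesh.pos), 2))

    def energy(pos):
        F = np.zeros_like(pos)
        E, d = membrane_forces_kernel(pos, mesh.edges, mesh.l0, 3.0,
                                      mesh.hinges, 2.0, 10.0, 10.0, F)
        assert d == 0
        return E, F

    E0, F0 = energy(mesh.pos)
    h = 1e-6
    for i in range(0, len(mesh.pos), 11):
        for k in range(3):
            q = mesh.pos.copy()
            q[i, k] += h
            ep, _ = energy(q)
            q[i, k] -= 2 * h
            em, _ = energy(q)
            assert abs(-(ep - em) / (2 * h) - F0[i, k]) < 1e-6


# ---------------------------------------------------------------------------
# adhesion to the membrane
# ---------------------------------------------------------------------------


def test_adhesion_zero_on_surface():
    mesh = MembraneMesh.build_flat(10.0, 10.0, 1.0)
    F, attached = mechanics.adhesion_to_membrane(
        np.array([5.0, 5.0, 1.0]), CellType.STEM, mesh, 40.0, 10.0,
        rest=1.0)
    assert attached and np.abs(F).max() < 0.2   # at rest height above mesh


def test_adhesion_stiffness_ratio():
    """Equal displacement: |F_stem| / |F_TA| = k_stem / k_TA."""
    mesh = MembraneMesh.build_flat(10.0, 10.0, 1.0)
    pos = np.array([5.0, 5.0, 1.3])
    f_stem, _ = mechanics.adhesion_to_membrane(pos, CellType.STEM, mesh,
                                               40.0, 10.0)
    f_ta, ok = mechanics.adhesion_to_membrane(pos, CellType.TA, mesh,
                                              40.0, 10.0)
    assert ok
    assert np.isclose(np.linalg.norm(f_stem) / np.linalg.norm(f_ta), 4.0)


def test_adhesion_ta_detaches_beyond_gap():
    mesh = MembraneMesh.build_flat(10.0, 10.0, 1.0)
    far = np.array([5.0, 5.0, 1.0 + 0.6])
    f, ok = mechanics.adhesion_to_membrane(far, CellType.TA, mesh, 40.0,
                                           10.0, rest=1.0, detach_gap=0.5)
    assert not ok and np.allclose(f, 0)
    # a stem cell at the same stretch stays bound
    f, ok = mechanics.adhesion_to_membrane(far, CellType.STEM, mesh, 40.0,
                                           10.0, rest=1.0, detach_gap=0.5)
    assert ok and np.linalg.norm(f) > 0


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def test_step_free_particle_euler(small_state):
    """An isolated mobile dermal particle under zero force stays put; the
    overdamped update is x <- x + F dt."""
    st = small_state
    p = st.params
    pos0 = st.dermis.pos.copy()
    mechanics.step(st, p.dt)
    # bottom layer exactly fixed
    assert np.array_equal(st.dermis.pos[~st.dermis.mobile],
                          pos0[~st.dermis.mobile])


def test_compressed_pair_relaxes_monotonically():
    """Two overlapping particles relax toward the rest separation; the
    coarse-step trajectory tracks a fine-step reference."""
    r_eq, k = 2.0, 25.0

    def trajectory(dt, n):
        x = np.array([0.9 * r_eq])    # separation, 1-D two-body problem
        out = [x[0]]
        for _ in range(n):
            f = k * (r_eq - x[0])
            x[0] += 2 * f * dt        # both particles move
            out.append(x[0])
        return np.array(out)

    coarse = trajectory(0.002, 200)
    fine = trajectory(0.0002, 2000)[::10]
    assert np.all(np.diff(coarse) >= -1e-12)          # monotone approach
    assert abs(coarse[-1] - r_eq) < 1e-3
    assert np.max(np.abs(coarse - fine)) < 5e-3       # Euler consistency


def test_newton_third_law_against_naive_oracle(rng):
    """Vectorised pair forces equal an O(n^2) double loop on <= 50
    particles to 1e-10, and internal forces sum to zero."""
    n = 40
    Lx = Ly = 50.0
    pos = rng.uniform(0, 20, size=(n, 3))
    req = np.full(n * (n - 1) // 2, 2.0)
    ii, jj = np.triu_indices(n, k=1)
    krep = np.full(len(ii), 3.0)
    kadh = np.full(len(ii), 1.0)
    rcut = np.full(len(ii), 3.0)
    beta = rng.uniform(1.0, 2.0, size=len(ii))
    F = np.zeros_like(pos)
    pair_forces_kernel(pos, pos, ii.astype(np.int64), jj.astype(np.int64),
                       req, krep, kadh, rcut, beta, Lx, Ly, F, F)

    F_ref = np.zeros_like(pos)
    for p_ in range(len(ii)):
        i, j = ii[p_], jj[p_]
        d = pos[i] - pos[j]
        d[0] -= Lx * round(d[0] / Lx)
        d[1] -= Ly * round(d[1] / Ly)
        b = beta[p_]
        s = math.sqrt(d[0] ** 2 + d[1] ** 2 + (b * d[2]) ** 2)
        if s >= rcut[p_] or s == 0:
            continue
        if s < req[p_]:
            f = krep[p_] * (req[p_] - s)
        else:
            f = -kadh[p_] * (s - req[p_]) * (rcut[p_] - s) \
                / (rcut[p_] - req[p_]) ** 2
        vec = np.array([d[0], d[1], b * b * d[2]]) * (f / s)
        F_ref[i] += vec
        F_ref[j] -= vec

    assert np.abs(F - F_ref).max() < 1e-10
    scale = max(np.abs(F).max(), 1.0)
    assert np.abs(F.sum(axis=0)).max() < 1e-10 * scale


def test_total_internal_force_balance(small_state):
    """All internal interactions (pairs, membrane elasticity, bonds) obey
    Newton's third law: the grand total force vanishes."""
    st = small_state
    st.rng.shuffle  # no-op; keep state untouched
    F_d, F_m, F_c, _ = mechanics.compute_forces(st)
    total = F_d.sum(axis=0) + F_m.sum(axis=0) + F_c.sum(axis=0)
    scale = max(np.abs(F_d).max(), np.abs(F_m).max(), np.abs(F_c).max(), 1.0)
    assert np.abs(total).max() < 1e-10 * scale


def test_energy_descent_overdamped():
    """With no division or signalling, the mechanical energy is
    non-increasing under the overdamped dynamics at dt <= dt_max."""
    p = Params(Lx=40.0, Ly=40.0, M1=1, M2=1, seed=9)
    st = build_initial_state(p)
    # perturb to store elastic energy; release the membrane bonds so every
    # force is the exact gradient of the continuum energy (the bond springs
    # hop between nearest vertices, a discretisation jump outside the
    # gradient-flow argument)
    st.cells.attached[:] = False
    st.cells.type[:] = CellType.SPINOUS
    r = np.random.default_rng(0)
    st.membrane.pos[:, 2] += 0.15 * r.standard_normal(st.membrane.n)
    st.cells.pos[:, 2] += 0.1 * r.standard_normal(len(st.cells))
    st.invalidate_neighbors()
    energies = []
    for _ in range(60):
        nl = mechanics.build_neighbor_lists(st)
        energies.append(mechanics.compute_forces(st, nl)[3])
        mechanics.step(st, p.dt, nl)
    nl = mechanics.build_neighbor_lists(st)
    energies.append(mechanics.compute_forces(st, nl)[3])
    diffs = np.diff(energies)
    assert np.all(diffs <= 1e-9 * max(abs(energies[0]), 1.0))
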