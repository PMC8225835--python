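"""Calcium/stimulant field dynamics, lipid bookkeeping and desquamation."""

import numpy as np
import pytest

from stratasim import signaling
from stratasim.core_state import CellType, Params, build_initial_state
from stratasim.signaling import NeighborGraph


def _cells(n, **kw):
    """Minimal in-memory cell population on a line (spacing 2, spheres)."""
    from stratasim.core_state import Cells

    pos = np.zeros((n, 3))
    pos[:, 0] = 2.0 * np.arange(n)
    base = dict(
        id=np.arange(n), lineage_root=np.zeros(n), abnormal=np.zeros(n, bool),
        type=np.full(n, CellType.GRANULAR), attached=np.zeros(n, bool),
        divisions_left=np.zeros(n), next_division_time=np.full(n, np.inf),
        w=np.full(n, 1.5), a=np.ones(n), c=np.ones(n),
        Ca=np.zeros(n), S=np.zeros(n), L_in=np.zeros(n), L_out=np.zeros(n),
        lipid_released=np.zeros(n, bool), D=np.ones(n),
        t_birth=np.zeros(n), t_cornified=np.full(n, np.nan),
        t_granular=np.zeros(n),
    )
    base.update(kw)
    return Cells(pos, **base)


def _chain_graph(n):
    uu = np.arange(n - 1)
    return NeighborGraph(n, uu, uu + 1)


# ---------------------------------------------------------------------------
# cornification release
# ---------------------------------------------------------------------------


def test_release_equal_split():
    """A star of 4 neighbours: each receives Q_Ca/4; the total equals
    Q_Ca exactly."""
    c = _cells(5)
    g = NeighborGraph(5, np.zeros(4, np.int64), np.arange(1, 5))
    discarded = signaling.cornification_release(c, g, np.array([0]), 2.0)
    assert discarded == 0
    assert np.allclose(c.Ca[1:], 0.5)
    assert np.isclose(c.Ca.sum(), 2.0)


def test_release_no_neighbors_discarded():
    c = _cells(1)
    g = NeighborGraph(1, np.zeros(0, np.int64), np.zeros(0, np.int64))
    discarded = signaling.cornification_release(c, g, np.array([0]), 2.0)
    assert discarded == 1
    assert c.Ca.sum() == 0.0


def test_release_simultaneous_additive():
    """Two simultaneous cornifications: their doses add linearly."""
    c = _cells(3)
    g = _chain_graph(3)
    signaling.cornification_release(c, g, np.array([0, 2]), 1.0)
    assert np.isclose(c.Ca[1], 2.0)        # middle cell gets both full doses
    assert np.isclose(c.Ca.sum(), 2.0)


# ---------------------------------------------------------------------------
# field updates
# ---------------------------------------------------------------------------


def test_fields_pure_decay_matches_exponential():
    """An isolated cell decays as Ca(0) exp(-lambda t) (Euler error
    vanishes with dt)."""
    lam, dt, n_steps = 2.0, 0.001, 500
    c = _cells(1, Ca=np.array([1.0]), type=np.full(1, CellType.SPINOUS))
    g = NeighborGraph(1, np.zeros(0, np.int64), np.zeros(0, np.int64))
    for _ in range(n_steps):
        signaling.update_fields(c, g, dt, 1.0, lam, 1.0, 0.0, 0.0)
    assert abs(c.Ca[0] - np.exp(-lam * dt * n_steps)) < 1e-3


def test_fields_diffusion_conserves_mass(rng):
    """Graph diffusion without decay or sources conserves total calcium."""
    n = 20
    c = _cells(n, Ca=rng.random(20), type=np.full(20, CellType.SPINOUS))
    g = _chain_graph(n)
    total0 = c.Ca.sum()
    for _ in range(200):
        signaling.update_fields(c, g, 0.01, 1.0, 0.0, 1.0, 0.0, 0.0)
    assert abs(c.Ca.sum() - total0) < 1e-10


def test_fields_two_cell_equilibration():
    """Two coupled cells with Ca = (1, 0) and no decay converge to 0.5
    each, following the closed-form two-state relaxation."""
    D, dt = 1.0, 0.005
    c = _cells(2, Ca=np.array([1.0, 0.0]), type=np.full(2, CellType.SPINOUS))
    g = _chain_graph(2)
    t = 0.0
    for _ in range(400):
        signaling.update_fields(c, g, dt, D, 0.0, 1.0, 0.0, 0.0)
        t += dt
    exact = 0.5 + 0.5 * np.exp(-2 * D * t)
    assert abs(c.Ca[0] - exact) < 2e-3
    assert abs(c.Ca[0] + c.Ca[1] - 1.0) < 1e-12


def test_fields_stability_bound_enforced():
    c = _cells(3)
    g = _chain_graph(3)
    with pytest.raises(ValueError):
        signaling.update_fields(c, g, 1.0, 5.0, 0.0, 5.0, 0.0, 0.0)


def test_stimulant_secreted_by_cornified_neighbors():
    c = _cells(3, type=np.array([CellType.CORNIFIED, CellType.GRANULAR,
                                 CellType.GRANULAR]))
    g = _chain_graph(3)
    signaling.update_fields(c, g, 0.01, 0.0, 0.0, 0.0, 0.0, 1.0)
    assert c.S[1] > 0 and c.S[2] == 0.0   # only the contact neighbour
    assert c.S[0] == 0.0                  # cornified cells do not accumulate


# ---------------------------------------------------------------------------
# lipids
# ---------------------------------------------------------------------------


def test_lipid_linear_accumulation_granular_only():
    c = _cells(2, type=np.array([CellType.GRANULAR, CellType.SPINOUS]))
    for _ in range(10):
        signaling.lipid_update(c, 0.1, 0.3, 1.0, 0.5)
    assert np.isclose(c.L_in[0], 0.3)
    assert c.L_in[1] == 0.0               # production is granular-only
    assert c.L_out.sum() == 0.0


def test_lipid_one_shot_release_conserves_sum():
    c = _cells(1, L_in=np.array([0.4]))
    c.Ca[0] = 1.0                         # above threshold -> release
    signaling.lipid_update(c, 0.0, 0.3, 1.0, 0.5)
    assert np.isclose(c.L_out[0], 0.4) and c.L_in[0] == 0.0
    assert c.lipid_released[0]


def test_lipid_release_at_cornification():
    c = _cells(1, L_in=np.array([0.7]), type=np.full(1, CellType.CORNIFIED))
    signaling.lipid_update(c, 0.0, 0.3, 1.0, 0.5, just_cornified=np.array([0]))
    assert np.isclose(c.L_out[0], 0.7)


def test_lipid_cap_respected():
    c = _cells(1)
    for _ in range(100):
        signaling.lipid_update(c, 0.1, 0.5, 1.0, 9.0)
    assert c.L_in[0] + c.L_out[0] <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# desquamation
# ---------------------------------------------------------------------------


def _corn_state():
    p = Params(Lx=60.0, Ly=60.0, M1=2, M2=2, seed=2)
    stt = build_initial_state(p)
    c = stt.cells
    c.type[:] = CellType.CORNIFIED
    c.attached[:] = False
    c.t_cornified[:] = 0.0
    c.next_division_time[:] = np.inf
    stt.invalidate_neighbors()
    return stt


def test_desquamation_decay_monotone():
    stt = _corn_state()
    D0 = stt.cells.D.copy()
    signaling.desquamation_update(stt, 0.5, 6.0, 1e-9)
    D1 = stt.cells.D.copy()
    signaling.desquamation_update(stt, 0.5, 6.0, 1e-9)
    assert np.all(D1 < D0)
    assert np.all(stt.cells.D < D1)


def test_desquamation_buried_cell_retained():
    """A cornified cell with depleted corneodesmosomes survives while a
    cell centre sits above it within one lateral radius."""
    stt = _corn_state()
    c = stt.cells
    c.D[:] = 1.0
    i = 0
    c.D[i] = 1e-6
    # bury it: put another cell directly above
    j = 1
    c.pos[j] = c.pos[i] + np.array([0.1, 0.0, 1.5])
    stt.invalidate_neighbors()
    removed = signaling.desquamation_update(stt, 1e-9, 6.0, 0.1)
    assert int(c.id[0]) not in removed    # buried -> retained
    # expose it and it goes
    stt.cells.pos[j, 2] = stt.cells.pos[i, 2] - 1.5
    stt.invalidate_neighbors()
    removed = signaling.desquamation_update(stt, 1e-9, 6.0, 0.1)
    assert 0 in removed


def test_desquamation_logs_timestamps():
    stt = _corn_state()
    stt.t = 20.0
    stt.cells.t_birth[:] = 3.0
    stt.cells.t_cornified[:] = 6.0
    stt.cells.D[:] = 1e-6
    signaling.desquamation_update(stt, 1e-9, 6.0, 0.1)
    ev = stt.events.to_dataframe()
    d = ev[ev["event"] == "desquamation"]
    assert len(d) > 0
    assert np.allclose(d["t_birth"], 3.0)
    assert np.allclose(d["t_cornified"], 6.0)


def test_calcium_mass_balance_audited(homeo_run):
    """d(total Ca)/dt = injections - decay, audited at every tick of the
    homeostasis run to 1e-8 relative."""
    assert homeo_run.audit.n_ticks > 0
    assert homeo_run.audit.max_ca_balance_error < 1e-8


def test_calcium_localized_below_cornified_layer(homeo_run):
    """Time-averaged Ca is maximal in the granular layer adjacent to the
    cornified cells (the localized calcium layer)."""
    c = homeo_run.state.cells
    by_type = {t: c.Ca[c.type == t].mean()
               for t in (CellType.SPINOUS, CellType.GRANULAR)}
    assert by_type[CellType.GRANULAR] > by_type[CellType.SPINOUS]


def test_stimulant_longer_ranged_than_calcium():
    p = Params()
    assert p.lambda_S < p.lambda_Ca
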