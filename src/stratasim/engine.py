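"""Time-stepping driver: mechanics substeps interleaved with the biology
tick (attachment/delamination, division, differentiation, signalling,
lipids, desquamation, shape update).

The biology tick runs every ``n_mech_per_tick`` mechanics steps; all
stochastic draws go through the state's single RNG stream in a fixed order,
so runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lifecycle, mechanics, signaling
from .core_state import CellType, SimulationState

__all__ = ["advance", "biology_tick", "AuditReport"]


@dataclass
class AuditReport:
    """Invariant audits accumulated over a run (criterion checks)."""

    max_ca_balance_error: float = 0.0  # relative calcium mass-balance error
    lineage_ok: bool = True
    n_ticks: int = 0


def _attachment_and_delamination(state: SimulationState) -> None:
    cells = state.cells
    p = state.params
    nl = mechanics._get_lists(state)
    att = np.flatnonzero(cells.attached)
    if len(att) == 0:
        return
    v = nl.nearest_vertex[att]
    nrm = nl.vertex_normals[v]
    dvec = cells.pos[att] - state.membrane.pos[v]
    Lx, Ly = p.Lx_m, p.Ly_m
    dvec[:, 0] -= Lx * np.round(dvec[:, 0] / Lx)
    dvec[:, 1] -= Ly * np.round(dvec[:, 1] / Ly)
    d = np.einsum("ij,ij->i", dvec, nrm)
    stretch = d - cells.c[att]
    is_ta = cells.type[att] == CellType.TA
    detach = is_ta & (stretch > p.detach_gap)
    for i in att[detach]:
        cells.attached[i] = False
        lifecycle.delaminate(cells, i)


def _divisions(state: SimulationState) -> None:
    cells = state.cells
    due = np.flatnonzero(cells.attached
                         & (cells.next_division_time <= state.t))
    # indices shift as TA mothers are retired; process by cell id
    for cid in cells.id[due]:
        i = int(np.flatnonzero(state.cells.id == cid)[0])
        if state.cells.next_division_time[i] <= state.t \
                and state.cells.attached[i]:
            lifecycle.divide(state, i)


def _differentiation(state: SimulationState) -> np.ndarray:
    """Advance w for suprabasal cells; returns indices of cells that crossed
    the cornification threshold this tick."""
    cells = state.cells
    p = state.params
    supra = (cells.type == CellType.SPINOUS) | (cells.type == CellType.GRANULAR)
    idx = np.flatnonzero(supra)
    if len(idx) == 0:
        return idx
    w_new = lifecycle.advance_differentiation(
        cells.w[idx], cells.Ca[idx], cells.S[idx], p.dt_bio, p.alpha,
        p.beta_Ca, p.beta_S, abnormal=cells.abnormal[idx],
        diff_factor=p.abnormal_diff_factor)
    cells.w[idx] = w_new
    # type transitions (half-open intervals)
    to_gran = idx[(cells.type[idx] == CellType.SPINOUS)
                  & (cells.w[idx] >= p.w1)]
    cells.type[to_gran] = CellType.GRANULAR
    cells.t_granular[to_gran] = state.t
    just_corn = idx[(cells.w[idx] >= p.w2)]
    for i in just_corn:
        cells.type[i] = CellType.CORNIFIED
        cells.t_cornified[i] = state.t
        cells.D[i] = 1.0
        state.events.record_cornification(state.t, cells.id[i],
                                          cells.pos[i] * p.R)
    return just_corn


def biology_tick(state: SimulationState, audit: AuditReport | None = None
                 ) -> None:
    """One biology update of length ``params.dt_bio``."""
    p = state.params
    cells = state.cells

    _attachment_and_delamination(state)
    _divisions(state)
    just_corn = _differentiation(state)

    nl = state._neighbors
    pairs = None
    if nl is not None and nl.n_cells == len(cells):
        pairs = (nl.cell_cell.ii, nl.cell_cell.jj)
    graph = signaling.build_graph(cells, p.Lx_m, p.Ly_m, p.graph_cut_factor,
                                  pairs=pairs)

    ca_before = float(cells.Ca.sum())
    discarded = signaling.cornification_release(cells, graph, just_corn,
                                                p.Q_Ca)
    state.events.discarded_ca_doses += discarded
    injected = p.Q_Ca * (len(just_corn) - discarded)
    ca_mid = float(cells.Ca.sum())

    # sub-cycle the explicit field update to stay below its diffusive
    # stability bound (contact degree grows in densely packed regions)
    deg = graph.degree
    dmax = int(deg.max()) if len(deg) else 0
    lam = max(p.lambda_Ca, p.lambda_S)
    m = max(1, int(np.ceil(p.dt_bio * (max(p.D_Ca, p.D_S) * max(dmax, 1)
                                       + lam) / 0.5)))
    err2 = 0.0
    for _ in range(m):
        ca_pre = float(cells.Ca.sum())
        signaling.update_fields(cells, graph, p.dt_bio / m, p.D_Ca,
                                p.lambda_Ca, p.D_S, p.lambda_S, p.s_rate)
        if audit is not None:
            expected = ca_pre * (1.0 - p.lambda_Ca * p.dt_bio / m)
            err2 = max(err2, abs(float(cells.Ca.sum()) - expected))
    if audit is not None:
        # mass balance: release injects exactly Q_Ca per cornification;
        # diffusion conserves; decay removes lambda*Ca*dt (explicit Euler)
        err1 = abs(ca_mid - ca_before - injected)
        scale = max(ca_mid, 1.0)
        audit.max_ca_balance_error = max(audit.max_ca_balance_error,
                                         err1 / scale, err2 / scale)

    signaling.lipid_update(cells, p.dt_bio, p.p_lip, p.L_max,
                           p.Ca_lipid_threshold, just_cornified=just_corn)
    signaling.desquamation_update(state, p.dt_bio, p.tau_desq, p.D_th)

    # shape follows the differentiation state
    a, c = lifecycle.update_shape(cells.w, p.w2, 1.0, p.q_min)
    cells.a[:] = a
    cells.c[:] = c

    if audit is not None:
        audit.n_ticks += 1
        # lineage conservation:
        # alive + removed == initial + daughters created - mothers retired
        ev = state.events
        audit.lineage_ok &= (len(cells) + ev.n_removed
                             == state.n_initial_cells + ev.n_created
                             - ev.n_retired)


def advance(state: SimulationState, t_end: float,
            recorder=None, audit: AuditReport | None = None) -> None:
    """Run the simulation until ``t_end`` (days)."""
    p = state.params
    while state.t < t_end - 1e-12:
        for _ in range(p.n_mech_per_tick):
            mechanics.step(state, p.dt)
        biology_tick(state, audit)
        if recorder is not None:
            recorder.maybe_sample(state)
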