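"""Cell division, stem/TA rules, delamination-triggered differentiation,
state-variable dynamics, type assignment and shape flattening.

Division is gated purely mechanically: only cells still bound to the
basement membrane cycle, so crowding (cells pushed off the membrane) is what
terminates proliferation, not an explicit contact rule.  Stem divisions are
asymmetric (the stem persists and spawns a TA with a fresh division budget),
which keeps the stem census fixed.
"""

from __future__ import annotations

import math

import numpy as np

from .core_state import (INF_DIVISIONS, Cells, CellType, Params,
                         SimulationState)

__all__ = [
    "schedule_next_division",
    "divide",
    "delaminate",
    "advance_differentiation",
    "assign_type",
    "update_shape",
    "aspect_ratio",
]


def schedule_next_division(now: float, T_div: float, cycle_cv: float,
                           rng: np.random.Generator,
                           abnormal: bool = False,
                           division_factor: float = 2.0) -> float:
    """Draw the next division time: now + T_div * X.

    X is lognormal with mean 1 and coefficient of variation ``cycle_cv``
    (X = 1 exactly when cycle_cv = 0).  Cells of an abnormal (corn) lineage
    use T_div divided by ``division_factor``.
    """
    T = T_div / division_factor if abnormal else T_div
    if cycle_cv <= 0:
        return now + T
    sigma2 = math.log1p(cycle_cv ** 2)
    x = rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2))
    return now + T * x


def _is_proliferative(cells: Cells, i: int) -> bool:
    t = cells.type[i]
    if t == CellType.STEM:
        return True
    return (t == CellType.TA and cells.attached[i]
            and cells.divisions_left[i] > 0)


def divide(state: SimulationState, i: int) -> tuple[int, ...]:
    """Divide cell ``i`` (array index); returns the ids of the daughters.

    Stem mother: the mother persists as the stem daughter and one new TA
    with a full division budget is created (asymmetric division).  TA
    mother: replaced by two TA daughters with one fewer division each.
    Daughters are displaced by +-eps/2 along a random tangential direction.
    Raises ``RuntimeError`` if the cell is not proliferative/attached.
    """
    cells = state.cells
    p = state.params
    if not cells.attached[i] or not _is_proliferative(cells, i):
        raise RuntimeError("division of a non-proliferative or detached cell")

    rng = state.rng
    phi = rng.uniform(0.0, 2.0 * math.pi)
    # daughters appear one radius apart along a random tangential
    # direction (inside the mother's footprint), so the post-division
    # relaxation stays gentle
    eps = 1.0
    off = 0.5 * eps * np.array([math.cos(phi), math.sin(phi), 0.0])
    mother_pos = cells.pos[i].copy()
    abnormal = bool(cells.abnormal[i])
    lineage = cells.lineage_root[i]

    common = dict(
        lineage_root=[lineage], abnormal=[abnormal], attached=[True],
        w=[0.0], a=[1.0], c=[1.0],
        Ca=[cells.Ca[i]], S=[cells.S[i]], L_in=[0.0], L_out=[0.0],
        lipid_released=[False], D=[1.0], t_birth=[state.t],
        t_cornified=[np.nan], t_granular=[np.nan],
    )

    if cells.type[i] == CellType.STEM:
        # mother stays stem; one TA daughter with a fresh budget
        new_id = state.new_ids(1)
        cells.pos[i] = mother_pos - off
        cells.next_division_time[i] = schedule_next_division(
            state.t, p.T_div, p.cycle_cv, rng, abnormal,
            p.abnormal_division_factor)
        state.cells.append(
            (mother_pos + off)[None, :], id=new_id,
            type=[CellType.TA], divisions_left=[p.N_div],
            next_division_time=[schedule_next_division(
                state.t, p.T_div, p.cycle_cv, rng, abnormal,
                p.abnormal_division_factor)],
            **common)
        state.events.record_division(state.t, cells.id[i], list(new_id),
                                     CellType.STEM, mother_pos,
                                     mother_retired=False)
        daughters = (int(cells.id[i]), int(new_id[0]))
    else:
        left = int(cells.divisions_left[i]) - 1
        mother_id = int(cells.id[i])
        new_ids = state.new_ids(2)
        common2 = {k: v * 2 for k, v in common.items()}
        nd = [(schedule_next_division(state.t, p.T_div, p.cycle_cv, rng,
                                      abnormal, p.abnormal_division_factor)
               if left > 0 else np.inf) for _ in range(2)]
        state.cells.append(
            np.stack([mother_pos + off, mother_pos - off]),
            id=new_ids, type=[CellType.TA] * 2,
            divisions_left=[left] * 2, next_division_time=nd, **common2)
        # retire the mother (note: the row index of appended cells is at the
        # end, so removing i here is index-safe)
        state.cells.remove(np.arange(len(state.cells)) == i)
        state.events.record_division(state.t, mother_id, list(new_ids),
                                     CellType.TA, mother_pos,
                                     mother_retired=True)
        daughters = tuple(int(x) for x in new_ids)
    state.invalidate_neighbors()
    return daughters


def delaminate(cells: Cells, i: int) -> None:
    """Mark a detached TA cell as differentiated (spinous, w = 0).

    Irreversible; the cell stops cycling.  Raises if the cell is still
    attached or is not a TA cell.
    """
    if cells.attached[i]:
        raise RuntimeError("delaminate called on an attached cell")
    if cells.type[i] != CellType.TA:
        raise RuntimeError("only TA cells delaminate")
    cells.type[i] = CellType.SPINOUS
    cells.w[i] = 0.0
    cells.next_division_time[i] = np.inf


def advance_differentiation(w, Ca, S, dt: float, alpha: float,
                            beta_Ca: float, beta_S: float,
                            abnormal=None, diff_factor: float = 2.0):
    """Advance the differentiation state variable.

    dw/dt = alpha (1 + beta_Ca Ca + beta_S S), doubled (``diff_factor``) for
    the abnormal corn lineage; w never decreases.  Vectorised over arrays.
    """
    w = np.asarray(w, dtype=float)
    Ca = np.asarray(Ca, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(Ca < 0) or np.any(S < 0) or dt < 0 or alpha < 0:
        raise ValueError("negative inputs to advance_differentiation")
    rate = alpha * (1.0 + beta_Ca * Ca + beta_S * S)
    if abnormal is not None:
        rate = rate * np.where(np.asarray(abnormal, dtype=bool),
                               diff_factor, 1.0)
    return w + rate * dt


def assign_type(w: float, w1: float, w2: float) -> CellType:
    """Suprabasal type from the state variable: spinous for w < w1, granular
    for w1 <= w < w2, cornified for w >= w2 (half-open intervals)."""
    if w < w1:
        return CellType.SPINOUS
    if w < w2:
        return CellType.GRANULAR
    return CellType.CORNIFIED


def aspect_ratio(w, w2: float, q_min: float = 0.25):
    """Aspect ratio q = c/a: linear in w from 1 at w = 0 down to ``q_min``
    at w = w2, constant afterwards."""
    w = np.asarray(w, dtype=float)
    return np.maximum(q_min, 1.0 - (1.0 - q_min) * w / w2)


def update_shape(w, w2: float, R: float = 1.0, q_min: float = 0.25):
    """Semi-axes (a, c) of the flattening spheroid at state w.

    Volume is conserved: a^2 c = R^3 with c = q(w) a.
    """
    q = aspect_ratio(w, w2, q_min)
    a = R * q ** (-1.0 / 3.0)
    return a, q * a
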