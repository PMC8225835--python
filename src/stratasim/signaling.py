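"""Calcium/stimulant dynamics on the cell-neighbour graph, lipid
production and release, and corneodesmosome-controlled desquamation.

Both fields live on cells and exchange along the contact graph
(graph-Laplacian diffusion) rather than on a continuum grid; calcium decays
fast (short-ranged, forming the localized layer beneath the cornified
cells), the stimulant decays slowly (longer-ranged), so the two factors set
the two layer boundaries at w1 and w2.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .core_state import Cells, CellType, SimulationState

__all__ = [
    "NeighborGraph",
    "build_graph",
    "cornification_release",
    "update_fields",
    "lipid_update",
    "desquamation_update",
]


class NeighborGraph:
    """Symmetric cell-contact adjacency as an edge list (u < v)."""

    def __init__(self, n: int, uu: np.ndarray, vv: np.ndarray):
        self.n = n
        self.uu = np.asarray(uu, dtype=np.int64)
        self.vv = np.asarray(vv, dtype=np.int64)

    @property
    def degree(self) -> np.ndarray:
        d = np.zeros(self.n, dtype=np.int64)
        np.add.at(d, self.uu, 1)
        np.add.at(d, self.vv, 1)
        return d

    def neighbor_counts_of(self, mask: np.ndarray) -> np.ndarray:
        """Per-cell count of neighbours belonging to ``mask``."""
        c = np.zeros(self.n, dtype=np.int64)
        np.add.at(c, self.uu, mask[self.vv].astype(np.int64))
        np.add.at(c, self.vv, mask[self.uu].astype(np.int64))
        return c


def build_graph(cells: Cells, Lx: float, Ly: float,
                cut_factor: float = 1.2,
                pairs: tuple[np.ndarray, np.ndarray] | None = None
                ) -> NeighborGraph:
    """Contact graph: cells whose effective separation is below
    ``cut_factor * (a_i + a_j)``.

    ``pairs`` may supply candidate pairs (e.g. the mechanics Verlet list);
    otherwise candidates come from a fresh periodic k-d tree query.
    """
    n = len(cells)
    if n == 0:
        return NeighborGraph(0, np.zeros(0, np.int64), np.zeros(0, np.int64))
    if pairs is None:
        zlo = cells.pos[:, 2].min() - 1.0
        zbox = cells.pos[:, 2].max() - zlo + 50.0
        q = np.empty_like(cells.pos)
        q[:, 0] = np.mod(cells.pos[:, 0], Lx)
        q[:, 1] = np.mod(cells.pos[:, 1], Ly)
        q[:, 2] = cells.pos[:, 2] - zlo
        tree = cKDTree(q, boxsize=[Lx, Ly, zbox])
        r = cut_factor * 2.0 * cells.a.max()
        pr = tree.query_pairs(r, output_type="ndarray")
        uu, vv = pr[:, 0].astype(np.int64), pr[:, 1].astype(np.int64)
    else:
        uu, vv = pairs
    d = cells.pos[uu] - cells.pos[vv]
    d[:, 0] -= Lx * np.round(d[:, 0] / Lx)
    d[:, 1] -= Ly * np.round(d[:, 1] / Ly)
    beta = (cells.a[uu] + cells.a[vv]) / (cells.c[uu] + cells.c[vv])
    s = np.sqrt(d[:, 0] ** 2 + d[:, 1] ** 2 + (beta * d[:, 2]) ** 2)
    keep = s < cut_factor * (cells.a[uu] + cells.a[vv])
    return NeighborGraph(n, uu[keep], vv[keep])


def cornification_release(cells: Cells, graph: NeighborGraph,
                          just_cornified: np.ndarray, Q_Ca: float) -> int:
    """Distribute a fixed calcium dose from each newly cornified cell
    equally among its graph neighbours.

    Total added calcium is exactly Q_Ca per cornifying cell; a cell with no
    neighbours discards its dose (count returned for the warning log).
    Simultaneous cornifications are additive.
    """
    just = np.asarray(just_cornified)
    if just.dtype == bool:
        just = np.flatnonzero(just)
    if len(just) == 0:
        return 0
    mask = np.zeros(graph.n, dtype=bool)
    mask[just] = True
    deg = graph.degree
    discarded = int(np.sum(deg[just] == 0))
    share = np.zeros(graph.n)
    nz = deg > 0
    share[nz] = Q_Ca / deg[nz]
    # each edge carries dose share[source] to the other endpoint
    np.add.at(cells.Ca, graph.vv, np.where(mask[graph.uu],
                                           share[graph.uu], 0.0))
    np.add.at(cells.Ca, graph.uu, np.where(mask[graph.vv],
                                           share[graph.vv], 0.0))
    return discarded


def update_fields(cells: Cells, graph: NeighborGraph, dt: float,
                  D_Ca: float, lambda_Ca: float, D_S: float,
                  lambda_S: float, s_rate: float) -> None:
    """Explicit Euler update of Ca and S on the contact graph.

    Ca_i += dt [D_Ca sum_j (Ca_j - Ca_i) - lambda_Ca Ca_i]; S likewise, plus
    a continuous source s_rate*dt to every neighbour of every cornified
    cell.  Raises if dt violates the explicit diffusive stability bound.
    """
    deg = graph.degree
    dmax = deg.max() if len(deg) else 0
    if dt * (max(D_Ca, D_S) * max(dmax, 1) + max(lambda_Ca, lambda_S)) > 1.0:
        raise ValueError("dt above the explicit-scheme stability bound")
    for field, D, lam in (("Ca", D_Ca, lambda_Ca), ("S", D_S, lambda_S)):
        x = getattr(cells, field)
        flux = np.zeros_like(x)
        dxe = x[graph.vv] - x[graph.uu]
        np.add.at(flux, graph.uu, dxe)
        np.add.at(flux, graph.vv, -dxe)
        x += dt * (D * flux - lam * x)
    corn = cells.type == CellType.CORNIFIED
    if corn.any():
        n_corn_nb = graph.neighbor_counts_of(corn)
        noncorn = ~corn
        cells.S[noncorn] += s_rate * dt * n_corn_nb[noncorn]


def lipid_update(cells: Cells, dt: float, p_lip: float, L_max: float,
                 Ca_threshold: float,
                 just_cornified: np.ndarray | None = None) -> None:
    """Lipid production in granular cells and one-shot release.

    Granular cells accumulate internal lipid at ``p_lip`` up to ``L_max``;
    the entire internal store transfers to the released pool the first time
    the cell's calcium exceeds ``Ca_threshold`` or the cell cornifies.
    """
    gran = cells.type == CellType.GRANULAR
    cells.L_in[gran] = np.minimum(cells.L_in[gran] + p_lip * dt,
                                  L_max - cells.L_out[gran])
    trigger = (~cells.lipid_released) & (cells.Ca > Ca_threshold) \
        & (gran | (cells.type == CellType.CORNIFIED))
    if just_cornified is not None:
        jc = np.zeros(len(cells), dtype=bool)
        jc[np.asarray(just_cornified)] = True
        trigger |= jc & ~cells.lipid_released
    if trigger.any():
        cells.L_out[trigger] += cells.L_in[trigger]
        cells.L_in[trigger] = 0.0
        cells.lipid_released[trigger] = True


def desquamation_update(state: SimulationState, dt: float, tau_desq: float,
                        D_th: float) -> list[int]:
    """Decay corneodesmosome integrity and remove shed cornified cells.

    D decays exponentially with timescale ``tau_desq``; a cornified cell is
    removed once D < D_th *and* it is surface-exposed (no cell centre above
    it within one equatorial radius laterally).  Returns removed cell ids;
    removals are logged with their birth/cornification timestamps.
    """
    cells = state.cells
    p = state.params
    corn = cells.type == CellType.CORNIFIED
    if not corn.any():
        return []
    cells.D[corn] *= np.exp(-dt / tau_desq)
    cand = np.flatnonzero(corn & (cells.D < D_th))
    if len(cand) == 0:
        return []
    Lx, Ly = p.Lx_m, p.Ly_m
    tree = cKDTree(np.mod(cells.pos[:, :2], [Lx, Ly]), boxsize=[Lx, Ly])
    removed = []
    for i in cand:
        nb = tree.query_ball_point(np.mod(cells.pos[i, :2], [Lx, Ly]),
                                   cells.a[i])
        if any(cells.pos[j, 2] > cells.pos[i, 2] for j in nb if j != i):
            continue  # buried: retained until exposed
        removed.append(i)
    if removed:
        for i in removed:
            state.events.record_desquamation(
                state.t, cells.id[i], cells.pos[i] * p.R,
                cells.t_birth[i], cells.t_cornified[i])
        mask = np.zeros(len(cells), dtype=bool)
        mask[removed] = True
        ids = [int(cells.id[i]) for i in removed]
        cells.remove(mask)
        state.invalidate_neighbors()
        return ids
    return []
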