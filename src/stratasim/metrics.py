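"""Layer-quality metrics on a subregion grid, lipid statistics, basal-layer
diagnostics, membrane deformation amplitude and turnover measurement.

For each layer (granular or cornified) the lateral domain is divided into
M1 x M2 tiles of size Dx x Dy; per tile

    H_ij = 4 pi R^3 n_ij / (3 Dx Dy)          (bulk thickness; flattening
                                               deliberately ignored)
    G_ij = z_max - z_min - H_ij               (vertical dispersion)

and the per-snapshot summaries are the tile means H(t), G(t) and the
population standard deviation E(t) of H_ij.  All lengths in micrometres.

Empty tiles contribute H_ij = 0 to H and E but are excluded from G (the
extremes are undefined there).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_state import CellType, SimulationState

__all__ = [
    "SubregionGrid",
    "thickness_grid",
    "dispersion_grid",
    "layer_means",
    "spatial_variation",
    "lipid_stats",
    "basal_stats",
    "membrane_amplitude",
    "turnover_stats",
    "layer_metrics",
    "MetricsRecorder",
    "stationary_mean",
]


@dataclass(frozen=True)
class SubregionGrid:
    """M1 x M2 tiling of [0, Lx) x [0, Ly); tile (i, j) covers
    [(i-1)Dx, iDx) x [(j-1)Dy, jDy) with half-open edges, so every cell
    lands in exactly one tile."""

    Lx: float
    Ly: float
    M1: int
    M2: int

    @property
    def dx(self) -> float:
        return self.Lx / self.M1

    @property
    def dy(self) -> float:
        return self.Ly / self.M2

    def tile_of(self, x, y):
        ix = np.minimum((np.mod(x, self.Lx) / self.dx).astype(int),
                        self.M1 - 1)
        iy = np.minimum((np.mod(y, self.Ly) / self.dy).astype(int),
                        self.M2 - 1)
        return ix, iy


def thickness_grid(xy: np.ndarray, grid: SubregionGrid, R: float
                   ) -> np.ndarray:
    """Tile thickness H_ij (um) from the lateral cell-centre positions (um)
    of one layer; H_ij = 4 pi R^3 n_ij / (3 Dx Dy)."""
    if R <= 0:
        raise ValueError("R must be > 0")
    H = np.zeros((grid.M1, grid.M2))
    if len(xy):
        ix, iy = grid.tile_of(xy[:, 0], xy[:, 1])
        np.add.at(H, (ix, iy), 1.0)
    return H * (4.0 * math.pi * R ** 3) / (3.0 * grid.dx * grid.dy)


def dispersion_grid(xyz: np.ndarray, grid: SubregionGrid, H: np.ndarray
                    ) -> np.ndarray:
    """Tile dispersion G_ij = z_max - z_min - H_ij (um) using cell-centre z;
    empty tiles are NaN (undefined extremes, excluded from the mean)."""
    G = np.full((grid.M1, grid.M2), np.nan)
    if len(xyz) == 0:
        return G
    ix, iy = grid.tile_of(xyz[:, 0], xyz[:, 1])
    zmax = np.full((grid.M1, grid.M2), -np.inf)
    zmin = np.full((grid.M1, grid.M2), np.inf)
    np.maximum.at(zmax, (ix, iy), xyz[:, 2])
    np.minimum.at(zmin, (ix, iy), xyz[:, 2])
    filled = np.isfinite(zmax)
    G[filled] = zmax[filled] - zmin[filled] - H[filled]
    return G


def layer_means(H: np.ndarray, G: np.ndarray) -> tuple[float, float]:
    """Snapshot means over tiles: H(t) over all tiles (empty tiles count as
    zero thickness), G(t) over the non-empty tiles only."""
    Hm = float(np.mean(H))
    Gm = float(np.nanmean(G)) if np.any(np.isfinite(G)) else float("nan")
    return Hm, Gm


def spatial_variation(H: np.ndarray, Hmean: float | None = None) -> float:
    """E(t): population standard deviation of the tile thicknesses."""
    if Hmean is None:
        Hmean = float(np.mean(H))
    return float(np.sqrt(np.mean((Hmean - H) ** 2)))


def lipid_stats(L_out: np.ndarray, L_max: float
                ) -> tuple[float, int]:
    """Mean released-lipid ratio over cornified cells and the count of
    lipid-deficient cells (strictly below 50% of the maximum)."""
    if len(L_out) == 0:
        return float("nan"), 0
    ratio = np.asarray(L_out, dtype=float) / L_max
    return float(ratio.mean()), int(np.sum(ratio < 0.5))


def basal_stats(events: pd.DataFrame, cells, window: tuple[float, float]
                ) -> tuple[float, int, int]:
    """(divisions/day over the window, n_basal, n_proliferative).

    n_basal counts membrane-attached cells; n_proliferative counts attached
    cells that can still divide (stem cells always count).
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("empty basal-stats window")
    if len(events):
        div = events[(events["event"] == "division")
                     & (events["time"] >= t0) & (events["time"] < t1)]
        rate = len(div) / (t1 - t0)
    else:
        rate = 0.0
    att = cells.attached
    n_basal = int(att.sum())
    prolif = att & ((cells.type == CellType.STEM)
                    | ((cells.type == CellType.TA)
                       & (cells.divisions_left > 0)))
    return rate, n_basal, int(prolif.sum())


def membrane_amplitude(mesh) -> float:
    """Vertical deformation amplitude: max z - min z over membrane
    particles (model units in, converted by the caller if needed)."""
    z = mesh.pos[:, 2]
    return float(z.max() - z.min())


def turnover_stats(events: pd.DataFrame, exclude_initial: bool = True,
                   window: tuple[float, float] | None = None
                   ) -> tuple[float, float, int]:
    """Mean birth->removal and cornification->removal intervals (days).

    Uses desquamation events with recorded timestamps; ``exclude_initial``
    drops cells born at t = 0 (no division of record).  Returns
    (mean_turnover, mean_corn_lag, n_removals).
    """
    d = events[events["event"] == "desquamation"]
    if window is not None:
        d = d[(d["time"] >= window[0]) & (d["time"] < window[1])]
    if exclude_initial:
        d = d[d["t_birth"] > 0.0]
    n = len(d)
    if n == 0:
        return float("nan"), float("nan"), 0
    turnover = float((d["time"] - d["t_birth"]).mean())
    lag = float((d["time"] - d["t_cornified"]).mean())
    return turnover, lag, n


# ---------------------------------------------------------------------------
# Snapshot metrics and the time-series recorder
# ---------------------------------------------------------------------------


def layer_metrics(state: SimulationState, window: float = 1.0) -> dict:
    """All per-snapshot metrics (lengths in um, times in days)."""
    p = state.params
    R = p.R
    grid = SubregionGrid(p.Lx, p.Ly, p.M1, p.M2)
    cells = state.cells
    out: dict = {"t": state.t, "n_cells": len(cells)}
    pos_um = cells.pos * R
    for name, ct in (("gran", CellType.GRANULAR),
                     ("corn", CellType.CORNIFIED)):
        m = cells.type == ct
        H = thickness_grid(pos_um[m][:, :2], grid, R)
        G = dispersion_grid(pos_um[m], grid, H)
        Hm, Gm = layer_means(H, G)
        E = spatial_variation(H, Hm)
        out[f"H_{name}"] = Hm
        out[f"G_{name}"] = Gm
        out[f"E_{name}"] = E
    corn = cells.type == CellType.CORNIFIED
    ratio, ndef = lipid_stats(cells.L_out[corn], p.L_max)
    out["lipid_ratio"] = ratio
    out["n_deficient"] = ndef
    # recent division count via a reverse scan of the chronological log
    # (cheaper than materialising the full event table every sample)
    t0 = max(0.0, state.t - window)
    n_div = 0
    for row in reversed(state.events.rows):
        if row[0] < t0:
            break
        if row[1] == "division":
            n_div += 1
    rate = n_div / (state.t - t0) if state.t > t0 else 0.0
    att = cells.attached
    n_basal = int(att.sum())
    prolif = att & ((cells.type == CellType.STEM)
                    | ((cells.type == CellType.TA)
                       & (cells.divisions_left > 0)))
    n_prolif = int(prolif.sum())
    out["divisions_per_day"] = rate
    out["n_basal"] = n_basal
    out["n_proliferative"] = n_prolif
    out["membrane_amplitude"] = membrane_amplitude(state.membrane) * R
    out["n_spinous"] = int(np.sum(cells.type == CellType.SPINOUS))
    out["n_granular"] = int(np.sum(cells.type == CellType.GRANULAR))
    out["n_cornified"] = int(np.sum(corn))
    return out


class MetricsRecorder:
    """Samples ``layer_metrics`` on a fixed cadence during a run."""

    def __init__(self, every: float, rate_window: float = 1.0):
        self.every = every
        self.rate_window = rate_window
        self.rows: list[dict] = []
        self._next = 0.0

    def maybe_sample(self, state: SimulationState) -> None:
        if state.t + 1e-9 >= self._next:
            self.rows.append(layer_metrics(state, self.rate_window))
            while self._next <= state.t + 1e-9:
                self._next += self.every

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def stationary_mean(df: pd.DataFrame, burn_in: float) -> pd.Series:
    """Time-average of a metrics time series over t >= burn_in (the
    transient, conventionally the first two turnovers, excluded)."""
    sel = df[df["t"] >= burn_in]
    if len(sel) == 0:
        raise ValueError("no samples after the burn-in window")
    return sel.mean(numeric_only=True)
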