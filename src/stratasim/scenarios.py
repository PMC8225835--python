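"""Scenario presets, run drivers, parameter sweeps, the corn experiment and
the desquamation-lag calibration.

Presets
-------
homeostasis      (N_div, T_div) = (14, 4.0), 200 x 200 um, 280 days
reduced_supply   (N_div, T_div) = (8, 4.4), otherwise as homeostasis
supply_sweep     grid template over (N_div, T_div)
stiff_dermis     homeostasis with a 4x stiffer dermis
corn             one central abnormal stem lineage, 2x lateral extent
fixture_small    80 x 80 um, 60 days — a desk-scale run that still shows
                 layering, protrusions and desquamation
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from . import metrics
from .core_state import CellType, Params, SimulationState, build_initial_state
from .engine import AuditReport, advance

__all__ = [
    "Scenario",
    "PRESETS",
    "make_scenario",
    "run_scenario",
    "run_sweep",
    "run_corn",
    "calibrate",
    "RunResult",
]


@dataclass
class Scenario:
    name: str
    overrides: dict = dc_field(default_factory=dict)
    duration: float = 60.0
    seed: int = 0
    snapshot_every: float | None = None

    def params(self) -> Params:
        return Params(seed=self.seed, **self.overrides)


PRESETS: dict[str, dict] = {
    "homeostasis": dict(
        overrides=dict(N_div=14, T_div=4.0, Lx=200.0, Ly=200.0, M1=4, M2=4),
        duration=280.0),
    "reduced_supply": dict(
        overrides=dict(N_div=8, T_div=4.4, Lx=200.0, Ly=200.0, M1=4, M2=4),
        duration=280.0),
    "supply_sweep": dict(
        overrides=dict(Lx=100.0, Ly=100.0, M1=2, M2=2),
        duration=140.0),
    "stiff_dermis": dict(
        overrides=dict(N_div=14, T_div=4.0, stiffness_mult=4.0,
                       Lx=200.0, Ly=200.0, M1=4, M2=4),
        duration=280.0),
    "corn": dict(
        overrides=dict(N_div=14, T_div=4.0, Lx=200.0, Ly=200.0, M1=8, M2=8),
        duration=90.0),
    "fixture_small": dict(
        overrides=dict(N_div=14, T_div=4.0, Lx=80.0, Ly=80.0, M1=2, M2=2),
        duration=60.0),
}


def make_scenario(name: str, seed: int = 0, duration: float | None = None,
                  **extra_overrides) -> Scenario:
    if name not in PRESETS:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"choose from {sorted(PRESETS)}")
    preset = PRESETS[name]
    ov = dict(preset["overrides"])
    ov.update(extra_overrides)
    return Scenario(name=name, overrides=ov,
                    duration=duration if duration is not None
                    else preset["duration"], seed=seed)


@dataclass
class RunResult:
    scenario: Scenario
    state: SimulationState
    metrics: pd.DataFrame
    events: pd.DataFrame
    audit: AuditReport
    summary: dict


def _summary(state: SimulationState, df: pd.DataFrame, events: pd.DataFrame,
             burn_in: float) -> dict:
    turn, lag, nrem = metrics.turnover_stats(
        events, window=(burn_in, state.t))
    out = {"t_end": state.t, "n_cells": len(state.cells),
           "mean_turnover_days": turn, "mean_corn_lag_days": lag,
           "n_removals": nrem, "burn_in_days": burn_in}
    if len(df):
        sm = metrics.stationary_mean(df, burn_in)
        for k in ("H_gran", "G_gran", "E_gran", "H_corn", "G_corn", "E_corn",
                  "lipid_ratio", "n_deficient", "membrane_amplitude",
                  "divisions_per_day", "n_basal", "n_proliferative"):
            out[f"mean_{k}"] = float(sm[k])
    return out


def run_scenario(scenario: Scenario, outdir=None, burn_in: float | None = None,
                 audit: bool = False) -> RunResult:
    """Run one scenario end to end; deterministic given the seed.

    Writes (if ``outdir``): the resolved config first, then the metrics time
    series, event log, exit summary with turnover stats and time-averaged
    layer metrics, a final snapshot and visual exports.
    """
    params = scenario.params()
    if burn_in is None:
        burn_in = min(56.0, 0.5 * scenario.duration)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.dump_config(params, outdir / "config.yaml",
                        scenario=scenario.name, duration=scenario.duration)
    state = build_initial_state(params)
    rec = metrics.MetricsRecorder(every=params.sample_every)
    rec.maybe_sample(state)
    rep = AuditReport()
    advance(state, scenario.duration, recorder=rec,
            audit=rep if audit else None)
    df = rec.to_dataframe()
    events = state.events.to_dataframe()
    summary = _summary(state, df, events, burn_in)
    if outdir is not None:
        df.to_csv(outdir / "metrics.csv", index=False)
        events.to_csv(outdir / "events.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        sio.save_state(state, outdir / "final.h5")
        sio.export_membrane_ply(state, outdir / "membrane.ply")
        sio.export_cells_vtk(state, outdir / "cells.vtk")
    return RunResult(scenario, state, df, events, rep, summary)


def run_sweep(ndiv_values, tdiv_values, duration: float = 140.0,
              seed: int = 0, base: str = "supply_sweep",
              outdir=None) -> pd.DataFrame:
    """One run per (N_div, T_div) grid point; returns a heat-map-ready table
    of time-averaged layer metrics.  Per-point failures are recorded, not
    fatal."""
    if not len(ndiv_values) or not len(tdiv_values):
        raise ValueError("empty sweep grid")
    rows = []
    for nd in ndiv_values:
        for td in tdiv_values:
            sc = make_scenario(base, seed=seed, duration=duration,
                               N_div=int(nd), T_div=float(td))
            row = {"N_div": int(nd), "T_div": float(td), "failed": False}
            try:
                res = run_scenario(sc)
                s = res.summary

                def ratio(num, den):
                    return num / den if den else float("nan")

                row.update(
                    H_gran=s["mean_H_gran"],
                    GH_gran=ratio(s["mean_G_gran"], s["mean_H_gran"]),
                    EH_gran=ratio(s["mean_E_gran"], s["mean_H_gran"]),
                    H_corn=s["mean_H_corn"],
                    GH_corn=ratio(s["mean_G_corn"], s["mean_H_corn"]),
                    EH_corn=ratio(s["mean_E_corn"], s["mean_H_corn"]),
                    lipid_ratio=s["mean_lipid_ratio"],
                    n_deficient=s["mean_n_deficient"],
                    divisions_per_day=s["mean_divisions_per_day"],
                    n_basal=s["mean_n_basal"],
                    n_proliferative=s["mean_n_proliferative"],
                )
            except Exception as exc:   # noqa: BLE001 — sweep keeps going
                row["failed"] = True
                row["error"] = str(exc)
            rows.append(row)
    df = pd.DataFrame(rows)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(outdir) / "sweep.csv", index=False)
    return df


# ---------------------------------------------------------------------------
# Corn experiment
# ---------------------------------------------------------------------------


def _flag_central_stem(state: SimulationState) -> int:
    """Mark the most central stem cell (and its future lineage) abnormal."""
    cells = state.cells
    stems = np.flatnonzero(cells.type == CellType.STEM)
    if len(stems) == 0:
        raise ValueError("no stem cells to flag abnormal")
    p = state.params
    centre = np.array([p.Lx_m / 2, p.Ly_m / 2])
    d2 = np.sum((cells.pos[stems, :2] - centre) ** 2, axis=1)
    i = stems[np.argmin(d2)]
    cells.abnormal[i] = True
    return int(cells.id[i])


def lesion_report(state: SimulationState) -> dict:
    """Quantify the corn lesion.

    The lesion footprint is the lateral convex hull of abnormal-lineage
    basal cells.  Reported: intrusion depth of the cornified layer's lower
    boundary above the footprint, membrane mean height inside vs outside,
    and the abnormal-lineage fraction among intruding cornified cells.
    All lengths in micrometres.
    """
    from scipy.spatial import Delaunay

    p = state.params
    cells = state.cells
    R = p.R
    ab_basal = cells.abnormal & cells.attached
    if not ab_basal.any():
        raise ValueError("no abnormal basal cells; corn run not configured")
    pts = cells.pos[ab_basal][:, :2] * R
    # footprint as convex hull (lesion is compact around the domain centre)
    if len(pts) >= 4:
        hull = Delaunay(pts)
        inside = lambda q: hull.find_simplex(q) >= 0
    else:
        centre = pts.mean(axis=0)
        rad = 2 * R
        inside = lambda q: np.sum((q - centre) ** 2, axis=1) < rad ** 2

    corn = cells.type == CellType.CORNIFIED
    grid = metrics.SubregionGrid(p.Lx, p.Ly, p.M1, p.M2)
    xy = cells.pos[corn][:, :2] * R
    z = cells.pos[corn][:, 2] * R
    ix, iy = grid.tile_of(xy[:, 0], xy[:, 1])
    lower = np.full((grid.M1, grid.M2), np.inf)
    np.minimum.at(lower, (ix, iy), z)
    lower[~np.isfinite(lower)] = np.nan
    tx = (np.arange(grid.M1) + 0.5) * grid.dx
    ty = (np.arange(grid.M2) + 0.5) * grid.dy
    TX, TY = np.meshgrid(tx, ty, indexing="ij")
    centres = np.column_stack([TX.ravel(), TY.ravel()])
    lesion_tiles = inside(centres).reshape(grid.M1, grid.M2)
    # a small footprint may miss every tile centre; fall back to the tiles
    # actually holding abnormal basal cells
    ax, ay = grid.tile_of(pts[:, 0], pts[:, 1])
    lesion_tiles[ax, ay] = True
    nonlesion = ~lesion_tiles
    mean_nonlesion_lower = float(np.nanmean(lower[nonlesion])) \
        if np.any(np.isfinite(lower[nonlesion])) else float("nan")
    lesion_lower = lower[lesion_tiles]
    if np.any(np.isfinite(lesion_lower)) and np.isfinite(mean_nonlesion_lower):
        intrusion_depth = mean_nonlesion_lower - float(np.nanmin(lesion_lower))
    else:
        # no cornified material dips into the footprint: no intrusion
        intrusion_depth = 0.0

    mem_xy = state.membrane.pos[:, :2] * R
    mem_z = state.membrane.pos[:, 2] * R
    in_mem = inside(mem_xy)
    mem_in = float(mem_z[in_mem].mean()) if in_mem.any() else float("nan")
    mem_out = float(mem_z[~in_mem].mean())

    # intruding cornified cells: below the non-lesional lower boundary,
    # inside the footprint
    corn_idx = np.flatnonzero(corn)
    in_fp = inside(xy)
    intruding = in_fp & (z < mean_nonlesion_lower)
    n_intr = int(intruding.sum())
    frac_ab = float(cells.abnormal[corn_idx[intruding]].mean()) \
        if n_intr else float("nan")

    return {
        "intrusion_depth_um": intrusion_depth,
        "membrane_mean_lesion_um": mem_in,
        "membrane_mean_nonlesion_um": mem_out,
        "n_intruding_cornified": n_intr,
        "fraction_intruding_abnormal": frac_ab,
        "n_abnormal_basal": int(ab_basal.sum()),
    }


def run_corn(scenario: Scenario | None = None, seed: int = 0,
             duration: float | None = None, outdir=None,
             **overrides) -> tuple[RunResult, dict]:
    """Corn experiment: flag the most central stem cell abnormal, run, and
    return (result, lesion report)."""
    if scenario is None:
        scenario = make_scenario("corn", seed=seed, duration=duration,
                                 **overrides)
    params = scenario.params()
    state = build_initial_state(params)
    _flag_central_stem(state)
    rec = metrics.MetricsRecorder(every=params.sample_every)
    advance(state, scenario.duration, recorder=rec)
    df = rec.to_dataframe()
    events = state.events.to_dataframe()
    burn_in = 0.5 * scenario.duration
    summary = _summary(state, df, events, burn_in)
    report = lesion_report(state)
    summary["lesion"] = report
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.dump_config(params, outdir / "config.yaml",
                        scenario=scenario.name, duration=scenario.duration)
        df.to_csv(outdir / "metrics.csv", index=False)
        events.to_csv(outdir / "events.csv", index=False)
        with open(outdir / "lesion.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        sio.save_state(state, outdir / "final.h5")
    return RunResult(scenario, state, df, events, AuditReport(), summary), \
        report


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def _measure_lag(params: Params, duration: float, burn_in: float) -> float:
    state = build_initial_state(params)
    advance(state, duration)
    _, lag, n = metrics.turnover_stats(state.events.to_dataframe(),
                                       window=(burn_in, duration))
    return lag if n else float("nan")


def calibrate(target_lag: float = 14.0, tol: float = 1.0,
              Lx: float = 80.0, Ly: float = 80.0, duration: float = 55.0,
              burn_in: float = 35.0, seed: int = 0,
              max_iter: int = 8) -> dict:
    """Fit tau_desq by bisection so the mean cornification -> removal lag
    hits ``target_lag`` +- ``tol`` days (D_th fixed).

    The lag is a per-cell decay property, so the fit runs on a reduced
    domain.  Returns the fitted value, the achieved lag and the iteration
    trace; raises if the initial bracket does not contain the target.
    """
    base = Params(Lx=Lx, Ly=Ly, M1=2, M2=2, seed=seed)
    trace = []

    def f(tau):
        lag = _measure_lag(base.replace(tau_desq=tau), duration, burn_in)
        trace.append({"tau_desq": tau, "lag": lag})
        return lag

    lag0 = f(base.tau_desq)
    if abs(lag0 - target_lag) <= tol:
        return {"tau_desq": base.tau_desq, "lag": lag0, "iterations": trace,
                "converged": True, "changed": False}
    lo, hi = 0.5 * base.tau_desq, 2.0 * base.tau_desq
    lag_lo, lag_hi = f(lo), f(hi)
    if not (lag_lo < target_lag < lag_hi):
        raise RuntimeError(
            f"calibration bracket failure: lag({lo:.2f}) = {lag_lo:.2f}, "
            f"lag({hi:.2f}) = {lag_hi:.2f} do not bracket {target_lag}")
    tau = base.tau_desq
    for _ in range(max_iter):
        tau = 0.5 * (lo + hi)
        lag = f(tau)
        if abs(lag - target_lag) <= tol:
            return {"tau_desq": tau, "lag": lag, "iterations": trace,
                    "converged": True, "changed": True}
        if lag < target_lag:
            lo = tau
        else:
            hi = tau
    return {"tau_desq": tau, "lag": trace[-1]["lag"], "iterations": trace,
            "converged": False, "changed": True}
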