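"""Config files, lossless HDF5 snapshots, CSV outputs and visual exports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .core_state import (Cells, Dermis, EventLog, MembraneMesh, Params,
                         SimulationState, _CELL_FIELDS, validate_params)

__all__ = [
    "load_config",
    "dump_config",
    "save_state",
    "load_state",
    "export_membrane_ply",
    "export_cells_vtk",
]

SNAPSHOT_VERSION = 1


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def load_config(path) -> tuple[Params, dict]:
    """Read a YAML config: one key per Params field plus optional
    ``scenario``/``duration``/``outdir``.  Unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    meta_keys = {"scenario", "duration", "outdir"}
    fields = {f.name for f in dataclasses.fields(Params)}
    unknown = set(raw) - fields - meta_keys
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    meta = {k: raw.pop(k) for k in list(raw) if k in meta_keys}
    params = Params(**raw)
    violations = validate_params(params)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    return params, meta


def dump_config(params: Params, path, **meta) -> None:
    d = dict(meta)
    d.update(params.to_dict())
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Snapshots (lossless round-trip of the full world)
# ---------------------------------------------------------------------------


def save_state(state: SimulationState, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["version"] = SNAPSHOT_VERSION
        f.attrs["t"] = state.t
        f.attrs["params"] = json.dumps(state.params.to_dict())
        f.attrs["rng_state"] = json.dumps(state.rng.bit_generator.state)
        f.attrs["next_cell_id"] = state.next_cell_id
        f.attrs["n_initial_cells"] = state.n_initial_cells
        g = f.create_group("dermis")
        g.create_dataset("pos", data=state.dermis.pos)
        g.create_dataset("mobile", data=state.dermis.mobile)
        g = f.create_group("membrane")
        m = state.membrane
        for name, arr in (("pos", m.pos), ("edges", m.edges), ("l0", m.l0),
                          ("hinges", m.hinges), ("triangles", m.triangles)):
            g.create_dataset(name, data=arr)
        g = f.create_group("cells")
        g.create_dataset("pos", data=state.cells.pos)
        for name in _CELL_FIELDS:
            g.create_dataset(name, data=getattr(state.cells, name))
        g = f.create_group("events")
        ev = state.events.to_dataframe()
        for col in ev.columns:
            data = ev[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(col, data=data)
        g.attrs["discarded_ca_doses"] = state.events.discarded_ca_doses
        g.attrs["n_created"] = state.events.n_created
        g.attrs["n_retired"] = state.events.n_retired
        g.attrs["n_removed"] = state.events.n_removed
        # the Verlet-list cache is part of the dynamical state: the rebuild
        # schedule depends on travel accumulated since the last build, so a
        # lossless resume must restore the lists verbatim
        nl = state._neighbors
        if nl is not None:
            from .mechanics import NeighborLists, PairList

            gn = f.create_group("neighbors")
            gn.attrs["travel_sub"] = nl.travel_sub
            gn.attrs["travel_cell"] = nl.travel_cell
            gn.attrs["n_cells"] = nl.n_cells
            gn.create_dataset("nearest_vertex", data=nl.nearest_vertex)
            gn.create_dataset("vertex_normals", data=nl.vertex_normals)
            for name in ("derm_derm", "mem_derm", "cell_cell", "cell_mem"):
                pl = getattr(nl, name)
                gg = gn.create_group(name)
                for fld in ("ii", "jj", "req", "krep", "kadh", "rcut",
                            "beta"):
                    gg.create_dataset(fld, data=getattr(pl, fld))


def load_state(path) -> SimulationState:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise IOError(f"unreadable snapshot {path}: {exc}") from exc
    with f:
        if f.attrs.get("version") != SNAPSHOT_VERSION:
            raise IOError(
                f"snapshot version mismatch: {f.attrs.get('version')!r}")
        params = Params(**json.loads(f.attrs["params"]))
        dermis = Dermis(f["dermis/pos"][:], f["dermis/mobile"][:])
        membrane = MembraneMesh(
            f["membrane/pos"][:], f["membrane/edges"][:],
            f["membrane/l0"][:], f["membrane/hinges"][:],
            f["membrane/triangles"][:], params.Lx_m, params.Ly_m)
        cells = Cells(f["cells/pos"][:],
                      **{k: f[f"cells/{k}"][:] for k in _CELL_FIELDS})
        rng = np.random.default_rng()
        rng.bit_generator.state = json.loads(f.attrs["rng_state"])
        events = EventLog()
        ev = f["events"]
        n = len(ev["time"])
        cols = []
        for col in EventLog.COLUMNS:
            data = ev[col][:]
            if data.dtype.kind == "S":
                data = data.astype(str)
            cols.append(data)
        events.rows = [tuple(c[i] for c in cols) for i in range(n)]
        events.discarded_ca_doses = int(ev.attrs["discarded_ca_doses"])
        events.n_created = int(ev.attrs["n_created"])
        events.n_retired = int(ev.attrs["n_retired"])
        events.n_removed = int(ev.attrs["n_removed"])
        state = SimulationState(
            params=params, t=float(f.attrs["t"]), dermis=dermis,
            membrane=membrane, cells=cells, rng=rng, events=events,
            next_cell_id=int(f.attrs["next_cell_id"]),
            n_initial_cells=int(f.attrs["n_initial_cells"]))
        if "neighbors" in f:
            from .mechanics import NeighborLists, PairList

            gn = f["neighbors"]
            groups = []
            for name in ("derm_derm", "mem_derm", "cell_cell", "cell_mem"):
                gg = gn[name]
                groups.append(PairList(*[gg[fld][:] for fld in
                                         ("ii", "jj", "req", "krep",
                                          "kadh", "rcut", "beta")]))
            state._neighbors = NeighborLists(
                *groups, gn["nearest_vertex"][:], gn["vertex_normals"][:],
                float(gn.attrs["travel_sub"]),
                float(gn.attrs["travel_cell"]), int(gn.attrs["n_cells"]))
        return state


# ---------------------------------------------------------------------------
# Visual exports
# ---------------------------------------------------------------------------


def export_membrane_ply(state: SimulationState, path) -> None:
    """ASCII PLY of the basement-membrane mesh (positions in um)."""
    import trimesh

    mesh = trimesh.Trimesh(vertices=state.membrane.pos * state.params.R,
                           faces=state.membrane.triangles, process=False)
    mesh.export(path, encoding="ascii")


def export_cells_vtk(state: SimulationState, path) -> None:
    """Legacy-VTK point cloud of the cells with type/w/lipid scalars."""
    cells = state.cells
    n = len(cells)
    pos = cells.pos * state.params.R
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nstratasim cells\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        for x, y, z in pos:
            fh.write(f"{x:.4f} {y:.4f} {z:.4f}\n")
        fh.write(f"POINT_DATA {n}\n")
        for name, arr in (("cell_type", cells.type),
                          ("state_w", cells.w),
                          ("lipid_out", cells.L_out)):
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for v in arr:
                fh.write(f"{float(v):.5f}\n")
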