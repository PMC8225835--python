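"""Domain types, unit system, parameter defaults and initial-world construction.

Internal unit system: length is measured in units of the undifferentiated cell
radius ``R`` (so the cell diameter is 2 model units) and time in days.  The
conversion to micrometres uses ``Params.R`` (default 5 um, i.e. a 10 um cell
diameter).  All positions, rest lengths and force constants below are in model
units unless a docstring says otherwise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "CellType",
    "Params",
    "Cells",
    "MembraneMesh",
    "Dermis",
    "EventLog",
    "SimulationState",
    "validate_params",
    "build_initial_state",
]


class CellType(IntEnum):
    STEM = 0
    TA = 1
    SPINOUS = 2
    GRANULAR = 3
    CORNIFIED = 4


# sentinel for "divides indefinitely" (stem cells)
INF_DIVISIONS = -1


@dataclass
class Params:
    """All model constants.

    Force constants are in model force units (damping gamma = 1, so a force f
    moves a particle at speed f model-lengths/day).  Rates are 1/day.
    """

    # --- cell supply ---------------------------------------------------
    N_div: int = 14              # max TA division count
    T_div: float = 4.0           # division period (days)
    cycle_cv: float = 0.2        # CV of the lognormal cycle-length jitter
    # --- geometry ------------------------------------------------------
    R: float = 5.0               # undifferentiated cell radius (um); unit scale
    Lx: float = 200.0            # lateral domain size (um)
    Ly: float = 200.0
    dermis_layers: int = 4       # particle layers in the dermal slab
    dermis_spacing: float = 2.0  # dermal particle spacing (model units)
    membrane_spacing: float = 1.0  # membrane lattice spacing (model units)
    membrane_gap: float = 1.2    # rest separation membrane <-> top dermal layer
    stem_spacing: float = 50.0   # stem sub-lattice spacing (um)
    # --- mechanics -----------------------------------------------------
    k_rep: float = 25.0          # contact repulsion, all species
    k_adh_cell: float = 5.0      # cell-cell adhesion well depth scale
    k_adh_derm: float = 10.0     # dermis-dermis adhesion (stiffness handle)
    k_adh_md: float = 5.0        # membrane-dermis adhesion
    stiffness_mult: float = 1.0  # multiplier on k_adh_derm (1 = normal dermis)
    k_stem: float = 60.0         # stem-membrane bond stiffness
    k_TA: float = 20.0           # TA-membrane bond stiffness
    k_stretch: float = 50.0      # membrane edge-spring modulus
    k_bend: float = 2.0          # membrane hinge bending modulus
    r_cut_factor: float = 1.5    # pair-force cutoff / rest separation
    detach_gap: float = 0.75     # TA detaches when bond stretch exceeds this
    q_min: float = 0.25          # terminal aspect ratio c/a of cornified cells
    # --- differentiation / signalling ----------------------------------
    w1: float = 1.0              # spinous -> granular threshold
    w2: float = 2.0              # granular -> cornified threshold
    alpha: float = 0.095         # baseline differentiation speed (state/day)
    beta_Ca: float = 1.0         # calcium acceleration coefficient
    beta_S: float = 4.0          # stimulant acceleration coefficient
    lambda_Ca: float = 2.0       # calcium decay rate (1/day)
    lambda_S: float = 0.4        # stimulant decay rate (1/day); < lambda_Ca
    D_Ca: float = 1.0            # calcium neighbour-exchange rate (1/day)
    D_S: float = 1.0             # stimulant neighbour-exchange rate (1/day)
    Q_Ca: float = 1.0            # calcium dose released at cornification
    s_rate: float = 0.2          # stimulant secretion per cornified neighbour
    graph_cut_factor: float = 1.2  # neighbour graph: eff. sep. < factor * r_eq
    # --- lipids ---------------------------------------------------------
    p_lip: float = 0.133         # lipid production rate in granular cells
    L_max: float = 1.0           # lipid cap
    Ca_lipid_threshold: float = 0.25  # Ca level triggering lipid release
    # --- desquamation ---------------------------------------------------
    tau_desq: float = 5.95       # corneodesmosome decay timescale (days)
    D_th: float = 0.1            # removal threshold on corneodesmosome integrity
    # --- abnormal (corn) lineage ----------------------------------------
    abnormal_division_factor: float = 2.0  # divides this much faster
    abnormal_diff_factor: float = 2.0      # differentiates this much faster
    # --- numerics --------------------------------------------------------
    dt: float = 0.0024           # mechanics step (days)
    n_mech_per_tick: int = 9     # mechanics substeps per biology tick
    skin: float = 0.75           # Verlet-list skin (model units)
    vmax: float = 60.0           # speed clip (model units/day), numerical guard
    # --- metrics ---------------------------------------------------------
    M1: int = 4                  # metric-grid subdivisions in x
    M2: int = 4                  # in y
    sample_every: float = 0.07   # metric sampling cadence (days)
    # --- bookkeeping ------------------------------------------------------
    stem_fraction_mode: str = "lattice"
    seed: int = 0

    # derived helpers ----------------------------------------------------
    @property
    def Lx_m(self) -> float:
        """Lateral domain size in model units."""
        return self.Lx / self.R

    @property
    def Ly_m(self) -> float:
        return self.Ly / self.R

    @property
    def dt_bio(self) -> float:
        return self.dt * self.n_mech_per_tick

    def stability_bound(self) -> float:
        """Conservative explicit-Euler bound on dt for the overdamped dynamics.

        Two stiffness classes: contact networks (a particle caged by up to
        ~12 pair contacts or 6 membrane springs) and the single membrane
        bond per cell; dt must stay below 2 / lambda_max for each.
        """
        k_net = max(self.k_rep, self.k_stretch)
        k_bond = max(self.k_stem, self.k_TA)
        return min(1.0 / (8.0 * k_net), 1.0 / (4.0 * k_bond))

    def replace(self, **kw) -> "Params":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_params(params: Params) -> list[str]:
    """Check all Params invariants; return a list of human-readable violations.

    Reports rather than raises so a config loader can show every problem at
    once.
    """
    v: list[str] = []
    p = params
    if p.N_div < 0:
        v.append("N_div: must be >= 0")
    for name in ("T_div", "R", "dt", "stiffness_mult", "tau_desq",
                 "dermis_spacing", "membrane_spacing", "Lx", "Ly"):
        if getattr(p, name) <= 0:
            v.append(f"{name}: must be > 0")
    for name in ("k_rep", "k_adh_cell", "k_adh_derm", "k_adh_md", "k_stem",
                 "k_TA", "k_stretch", "k_bend", "alpha", "beta_Ca", "beta_S",
                 "lambda_Ca", "lambda_S", "D_Ca", "D_S", "p_lip", "L_max",
                 "cycle_cv", "Q_Ca", "s_rate"):
        if getattr(p, name) < 0:
            v.append(f"{name}: must be >= 0")
    if not (p.w2 > p.w1 > 0):
        v.append("w1/w2: thresholds must satisfy w2 > w1 > 0")
    if p.M1 < 1 or p.M2 < 1:
        v.append("M1/M2: metric-grid subdivisions must be >= 1")
    if p.r_cut_factor <= 1.0:
        v.append("r_cut_factor: must exceed 1 (cutoff beyond rest separation)")
    if not (0 < p.D_th < 1):
        v.append("D_th: removal threshold must lie in (0, 1)")
    if not (0 < p.q_min <= 1):
        v.append("q_min: terminal aspect ratio must lie in (0, 1]")
    if p.dt > 0 and p.T_div > 0 and p.dt > p.stability_bound():
        v.append(
            f"dt: {p.dt} exceeds the mechanics stability bound "
            f"{p.stability_bound():.3g}")
    if p.n_mech_per_tick < 1:
        v.append("n_mech_per_tick: must be >= 1")
    return v


# ---------------------------------------------------------------------------
# Cell storage (structure of arrays)
# ---------------------------------------------------------------------------

_CELL_FIELDS = dict(
    id=np.int64, lineage_root=np.int64, abnormal=bool,
    type=np.int8, attached=bool,
    divisions_left=np.int32, next_division_time=np.float64,
    w=np.float64, a=np.float64, c=np.float64,
    Ca=np.float64, S=np.float64, L_in=np.float64, L_out=np.float64,
    lipid_released=bool,
    D=np.float64, t_birth=np.float64, t_cornified=np.float64,
    t_granular=np.float64,
)


class Cells:
    """Structure-of-arrays container for all epidermal cells.

    ``pos`` is (n, 3) in model units; the scalar per-cell variables live in
    one numpy array each (see ``_CELL_FIELDS``).
    """

    def __init__(self, pos: np.ndarray, **fields: np.ndarray):
        self.pos = np.asarray(pos, dtype=np.float64).reshape(-1, 3)
        n = len(self.pos)
        for name, dtype in _CELL_FIELDS.items():
            arr = fields.get(name)
            if arr is None:
                raise ValueError(f"missing cell field {name}")
            arr = np.asarray(arr, dtype=dtype)
            if arr.shape != (n,):
                raise ValueError(f"cell field {name} has shape {arr.shape}")
            setattr(self, name, arr)

    # -- constructors ----------------------------------------------------
    @classmethod
    def empty(cls) -> "Cells":
        return cls(np.zeros((0, 3)),
                   **{k: np.zeros(0, dtype=d) for k, d in _CELL_FIELDS.items()})

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n(self) -> int:
        return len(self.pos)

    def copy(self) -> "Cells":
        return Cells(self.pos.copy(),
                     **{k: getattr(self, k).copy() for k in _CELL_FIELDS})

    def append(self, pos, **fields) -> None:
        pos = np.asarray(pos, dtype=np.float64).reshape(-1, 3)
        m = len(pos)
        self.pos = np.concatenate([self.pos, pos])
        for name, dtype in _CELL_FIELDS.items():
            arr = np.asarray(fields[name], dtype=dtype).reshape(m)
            setattr(self, name, np.concatenate([getattr(self, name), arr]))

    def remove(self, mask: np.ndarray) -> None:
        keep = ~np.asarray(mask, dtype=bool)
        self.pos = self.pos[keep]
        for name in _CELL_FIELDS:
            setattr(self, name, getattr(self, name)[keep])

    def equals(self, other: "Cells") -> bool:
        if len(self) != len(other):
            return False
        if not np.array_equal(self.pos, other.pos):
            return False
        return all(
            np.array_equal(getattr(self, k), getattr(other, k),
                           equal_nan=(_CELL_FIELDS[k] == np.float64))
            for k in _CELL_FIELDS)

    def to_dataframe(self):
        import pandas as pd

        d = {"x": self.pos[:, 0], "y": self.pos[:, 1], "z": self.pos[:, 2]}
        d.update({k: getattr(self, k) for k in _CELL_FIELDS})
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# Membrane mesh
# ---------------------------------------------------------------------------


@dataclass
class MembraneMesh:
    """Periodic triangular lattice carrying stretching + bending elasticity.

    ``edges`` (E, 2) with rest lengths ``l0``; ``hinges`` (H, 4) hold the two
    shared-edge vertices followed by the two opposite vertices of the adjacent
    triangles; the rest dihedral angle is 0 (flat).
    """

    pos: np.ndarray          # (M, 3) model units
    edges: np.ndarray        # (E, 2) int32
    l0: np.ndarray           # (E,) float64
    hinges: np.ndarray       # (H, 4) int32
    triangles: np.ndarray    # (T, 3) int32
    Lx: float
    Ly: float

    def copy(self) -> "MembraneMesh":
        return MembraneMesh(self.pos.copy(), self.edges.copy(),
                            self.l0.copy(), self.hinges.copy(),
                            self.triangles.copy(), self.Lx, self.Ly)

    @property
    def n(self) -> int:
        return len(self.pos)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals, oriented +z for a flat mesh."""
        p = self.pos
        tri = self.triangles
        d1 = _minimg(p[tri[:, 1]] - p[tri[:, 0]], self.Lx, self.Ly)
        d2 = _minimg(p[tri[:, 2]] - p[tri[:, 0]], self.Lx, self.Ly)
        fn = np.cross(d1, d2)
        vn = np.zeros_like(p)
        for k in range(3):
            np.add.at(vn, tri[:, k], fn)
        nrm = np.linalg.norm(vn, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        vn /= nrm
        # orient upward (flat lattice built counter-clockwise gives +z already;
        # guard against inverted patches)
        flip = vn[:, 2] < 0
        vn[flip] *= -1.0
        return vn

    @classmethod
    def build_flat(cls, Lx: float, Ly: float, spacing: float,
                   z: float = 0.0) -> "MembraneMesh":
        """Flat periodic triangular lattice at height ``z``, at rest.

        The lattice is fitted to the periodic box (row count rounded to an
        even number), and rest lengths are taken from the constructed
        geometry, so the flat configuration has exactly zero elastic energy.
        """
        nx = max(3, round(Lx / spacing))
        dy_t = spacing * math.sqrt(3.0) / 2.0
        ny = max(4, round(Ly / dy_t))
        if ny % 2:
            ny += 1
        dx = Lx / nx
        dy = Ly / ny

        idx = lambda i, j: (j % ny) * nx + (i % nx)
        pos = np.zeros((nx * ny, 3))
        for j in range(ny):
            off = 0.5 * dx if (j % 2) else 0.0
            for i in range(nx):
                pos[idx(i, j), 0] = i * dx + off
                pos[idx(i, j), 1] = j * dy
        pos[:, 2] = z

        tris = []
        for j in range(ny):
            s = 0 if (j % 2 == 0) else 1
            for i in range(nx):
                # up-right / up-left neighbours depend on row parity
                ur = idx(i + s, j + 1)
                ul = idx(i + s - 1, j + 1)
                r = idx(i + 1, j)
                v = idx(i, j)
                tris.append((v, r, ur))
                tris.append((v, ur, ul))
        triangles = np.asarray(tris, dtype=np.int32)

        # unique edges + hinge adjacency
        edge_tris: dict[tuple[int, int], list[int]] = {}
        for t, (a, b, c) in enumerate(triangles):
            for u, v in ((a, b), (b, c), (c, a)):
                key = (min(u, v), max(u, v))
                edge_tris.setdefault(key, []).append(t)
        edges = np.asarray(sorted(edge_tris), dtype=np.int32)
        hinges = []
        for (u, v), ts in sorted(edge_tris.items()):
            if len(ts) != 2:
                raise ValueError("membrane lattice is not a closed 2-manifold")
            opp = []
            for t in ts:
                verts = set(triangles[t]) - {u, v}
                opp.append(verts.pop())
            hinges.append((u, v, opp[0], opp[1]))
        hinges = np.asarray(hinges, dtype=np.int32)

        d = _minimg(pos[edges[:, 1]] - pos[edges[:, 0]], Lx, Ly)
        l0 = np.linalg.norm(d, axis=1)
        return cls(pos, edges, l0, hinges, triangles, Lx, Ly)


def _minimg(d: np.ndarray, Lx: float, Ly: float) -> np.ndarray:
    d = np.array(d, dtype=np.float64, copy=True)
    d[..., 0] -= Lx * np.round(d[..., 0] / Lx)
    d[..., 1] -= Ly * np.round(d[..., 1] / Ly)
    return d


# ---------------------------------------------------------------------------
# Dermis
# ---------------------------------------------------------------------------


@dataclass
class Dermis:
    pos: np.ndarray      # (N, 3)
    mobile: np.ndarray   # (N,) bool; bottom layer anchored

    def copy(self) -> "Dermis":
        return Dermis(self.pos.copy(), self.mobile.copy())

    @property
    def n(self) -> int:
        return len(self.pos)

    @classmethod
    def build_slab(cls, Lx: float, Ly: float, spacing: float, n_layers: int,
                   z_top: float) -> "Dermis":
        """Close-packed slab filling z < 0: triangular in-plane lattice,
        ABAB-stacked layers, bottom layer immobile."""
        nx = max(2, round(Lx / spacing))
        dy_t = spacing * math.sqrt(3.0) / 2.0
        ny = max(2, round(Ly / dy_t))
        if ny % 2:
            ny += 1
        dx = Lx / nx
        dy = Ly / ny
        dz = spacing * math.sqrt(2.0 / 3.0)

        pts = []
        for k in range(n_layers):
            zk = z_top - k * dz
            ox = 0.5 * dx if (k % 2) else 0.0
            oy = dy / 3.0 if (k % 2) else 0.0
            for j in range(ny):
                off = 0.5 * dx if (j % 2) else 0.0
                for i in range(nx):
                    pts.append((((i * dx + off + ox) % Lx),
                                ((j * dy + oy) % Ly), zk))
        pos = np.asarray(pts, dtype=np.float64)
        mobile = pos[:, 2] > (z_top - (n_layers - 1) * dz + 1e-9)
        return cls(pos, mobile)


# ---------------------------------------------------------------------------
# Event log
# ---------------------------------------------------------------------------


class EventLog:
    """Append-only record of divisions, cornifications and desquamations."""

    COLUMNS = ("time", "event", "cell_id", "mother_id", "daughter_id",
               "cell_type", "x", "y", "z", "t_birth", "t_cornified")

    def __init__(self):
        self.rows: list[tuple] = []
        self.discarded_ca_doses: int = 0
        # lineage audit counters
        self.n_created = 0
        self.n_retired = 0
        self.n_removed = 0

    def record_division(self, t, mother_id, daughter_ids, mother_type, pos,
                        mother_retired: bool):
        self.rows.append((t, "division", int(mother_id),
                          int(mother_id), int(daughter_ids[-1]),
                          int(mother_type), pos[0], pos[1], pos[2],
                          np.nan, np.nan))
        # daughter_ids lists only genuinely new rows (an asymmetric stem
        # division lists just the new TA; the mother persists as the stem)
        self.n_created += len(daughter_ids)
        self.n_retired += int(mother_retired)

    def record_cornification(self, t, cell_id, pos):
        self.rows.append((t, "cornification", int(cell_id), -1, -1,
                          int(CellType.CORNIFIED), pos[0], pos[1], pos[2],
                          np.nan, np.nan))

    def record_desquamation(self, t, cell_id, pos, t_birth, t_cornified):
        self.rows.append((t, "desquamation", int(cell_id), -1, -1,
                          int(CellType.CORNIFIED), pos[0], pos[1], pos[2],
                          t_birth, t_cornified))
        self.n_removed += 1

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=self.COLUMNS)

    def copy(self) -> "EventLog":
        log = EventLog()
        log.rows = list(self.rows)
        log.discarded_ca_doses = self.discarded_ca_doses
        log.n_created = self.n_created
        log.n_retired = self.n_retired
        log.n_removed = self.n_removed
        return log


# ---------------------------------------------------------------------------
# Full world
# ---------------------------------------------------------------------------


@dataclass
class SimulationState:
    """The full mutable world: particles, mesh, cells, clock and RNG stream."""

    params: Params
    t: float
    dermis: Dermis
    membrane: MembraneMesh
    cells: Cells
    rng: np.random.Generator
    events: EventLog = field(default_factory=EventLog)
    next_cell_id: int = 0
    n_initial_cells: int = 0
    # caches managed by the mechanics layer
    _neighbors: object = None

    def new_ids(self, k: int) -> np.ndarray:
        ids = np.arange(self.next_cell_id, self.next_cell_id + k,
                        dtype=np.int64)
        self.next_cell_id += k
        return ids

    def invalidate_neighbors(self) -> None:
        self._neighbors = None


def build_initial_state(params: Params) -> SimulationState:
    """Construct the initial world: flat dermal slab, flat membrane at z = 0
    at rest, and a basal monolayer (stem sub-lattice + TA) attached to it.

    Deterministic given ``params.seed``.  Raises ``ValueError`` for invalid
    parameters or a domain too small to host a single stem cell.
    """
    violations = validate_params(params)
    if violations:
        raise ValueError("invalid params: " + "; ".join(violations))

    p = params
    Lx, Ly = p.Lx_m, p.Ly_m
    if Lx < 2.0 or Ly < 2.0:
        raise ValueError("domain too small to host one cell")

    membrane = MembraneMesh.build_flat(Lx, Ly, p.membrane_spacing, z=0.0)
    dermis = Dermis.build_slab(Lx, Ly, p.dermis_spacing, p.dermis_layers,
                               z_top=-p.membrane_gap)

    # basal monolayer on a square lattice of spacing one cell diameter
    ncx = max(1, round(Lx / 2.0))
    ncy = max(1, round(Ly / 2.0))
    gx = (np.arange(ncx) + 0.5) * (Lx / ncx)
    gy = (np.arange(ncy) + 0.5) * (Ly / ncy)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    n = ncx * ncy
    pos = np.column_stack([X.ravel(), Y.ravel(), np.full(n, 1.0)])

    # stem cells on a regular sub-lattice with spacing ~ stem_spacing
    s_m = p.stem_spacing / p.R
    nsx = max(1, round(Lx / s_m))
    nsy = max(1, round(Ly / s_m))
    if nsx * nsy < 1:
        raise ValueError("domain too small to host one stem cell")
    sx = (np.arange(nsx) + 0.5) * (Lx / nsx)
    sy = (np.arange(nsy) + 0.5) * (Ly / nsy)
    stem_mask = np.zeros(n, dtype=bool)
    lateral = pos[:, :2]
    for xs in sx:
        for ys in sy:
            d = _minimg(np.column_stack(
                [lateral[:, 0] - xs, lateral[:, 1] - ys,
                 np.zeros(n)]), Lx, Ly)
            stem_mask[np.argmin(np.einsum("ij,ij->i", d[:, :2], d[:, :2]))] = True

    rng = np.random.default_rng(p.seed)
    types = np.where(stem_mask, CellType.STEM, CellType.TA).astype(np.int8)
    ids = np.arange(n, dtype=np.int64)

    cells = Cells(
        pos,
        id=ids,
        lineage_root=ids,
        abnormal=np.zeros(n, dtype=bool),
        type=types,
        attached=np.ones(n, dtype=bool),
        divisions_left=np.where(stem_mask, INF_DIVISIONS, p.N_div).astype(np.int32),
        next_division_time=np.zeros(n),
        w=np.zeros(n),
        a=np.ones(n),
        c=np.ones(n),
        Ca=np.zeros(n),
        S=np.zeros(n),
        L_in=np.zeros(n),
        L_out=np.zeros(n),
        lipid_released=np.zeros(n, dtype=bool),
        D=np.ones(n),
        t_birth=np.zeros(n),
        t_cornified=np.full(n, np.nan),
        t_granular=np.full(n, np.nan),
    )

    state = SimulationState(params=p, t=0.0, dermis=dermis, membrane=membrane,
                            cells=cells, rng=rng, next_cell_id=n,
                            n_initial_cells=n)

    # desynchronised first divisions: uniform phase in [0, T_div); later
    # cycles are drawn by lifecycle.schedule_next_division at division time
    cells.next_division_time[:] = rng.uniform(0.0, p.T_div, size=n)
    return state
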