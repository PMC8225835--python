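"""Shared fixtures.

The expensive simulation runs are session-scoped and shared by several
tests; sizes are chosen so the whole suite stays desk-scale while still
exercising at least two full turnovers beyond the burn-in of each run.
"""

from __future__ import annotations

import numpy as np
import pytest

from stratasim import make_scenario, run_scenario, run_corn
from stratasim.core_state import Params, build_initial_state


TURNOVER_DAYS = 28.0          # calibrated whole-epidermis turnover
FIXTURE_DAYS = 168.0          # 2-turnover burn-in + 4 turnovers
FIXTURE_BURN_IN = 56.0


@pytest.fixture(scope="session")
def homeo_run():
    """Calibrated fixture_small homeostasis run (the turnover/desquamation
    anchor run): two-turnover burn-in plus four turnovers of data."""
    sc = make_scenario("fixture_small", seed=11, duration=FIXTURE_DAYS)
    return run_scenario(sc, burn_in=FIXTURE_BURN_IN, audit=True)


@pytest.fixture(scope="session")
def regime_runs():
    """Paired-seed runs of the two cell-supply regimes (N_div, T_div) =
    (14, 4.0) and (8, 4.4).  The window extends well past the point where
    TA division budgets start to bind (N_div * T_div), which is where the
    supply difference expresses itself."""
    out = {"normal": [], "reduced": []}
    for seed in (3, 4, 5):
        for key, ov in (("normal", {}),
                        ("reduced", dict(N_div=8, T_div=4.4))):
            sc = make_scenario("fixture_small", seed=seed, duration=70.0,
                               **ov)
            out[key].append(run_scenario(sc, burn_in=42.0))
    return out


@pytest.fixture(scope="session")
def stiff_pair():
    """Normal vs 4x-stiffened dermis, same seed and domain.  The pair runs
    past the supply-rate transient so the stiffness effect on the layer
    structure has expressed itself."""
    out = {}
    for key, mult in (("normal", 1.0), ("stiff", 4.0)):
        sc = make_scenario("fixture_small", seed=3, duration=84.0,
                           stiffness_mult=mult)
        out[key] = run_scenario(sc, burn_in=42.0)
    return out


@pytest.fixture(scope="session")
def corn_runs():
    """Corn run plus its null control (abnormality factors = 1)."""
    runs = {}
    for key, ov in (("corn", {}),
                    ("null", dict(abnormal_division_factor=1.0,
                                  abnormal_diff_factor=1.0))):
        sc = make_scenario("corn", seed=5, duration=45.0, Lx=140.0, Ly=140.0,
                           M1=7, M2=7, **ov)
        runs[key] = run_corn(sc)
    return runs


@pytest.fixture()
def small_state():
    """A small freshly built world (fast construction, no dynamics)."""
    p = Params(Lx=60.0, Ly=60.0, M1=2, M2=2, seed=7)
    return build_initial_state(p)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
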