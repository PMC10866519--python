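"""Shared fixtures.

The acceptance-level checks compare populations of simulated tissue
shapes, which are expensive; the campaigns below are session-scoped and
shared between tests.  Desk-scale study conditions (36 cells, 20,000
MCS) are used throughout: small enough to run on one CPU, large enough
that the convergent-extension phenomenology (initial round phase,
elongation past L2/L1 = 0.25, occasional non-elongating runs) is
preserved.  See docs/methods.md for the scaling rationale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from gastrusim import SimConfig, Simulation

DESK_CELLS = 36
DESK_MCS = 20_000
DESK_RECORD = 1_000
# desk-scale phase windows: the 0.25 crossing happens around MCS 5-8k
# at this tissue size, so the "initial phase" is the first quarter and
# the "final phase" the last half of a run
INITIAL_WINDOW = 5_000
FINAL_WINDOW_START = 10_000


def run_campaign(n_runs: int, base_seed: int, record_every: int = DESK_RECORD,
                 mcs: int = DESK_MCS, **config_kwargs) -> pd.DataFrame:
    """Run ``n_runs`` independent simulations; tidy table of recorded
    scaled coefficients (columns run, mcs, l2_over_l1, l3_over_l1)."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_runs):
            sim = Simulation(SimConfig(seed=base_seed + rep, **config_kwargs))
            rec = sim.run(mcs, record_every=record_every)
            for t, r2, r3 in zip(rec.mcs, rec.l2_over_l1, rec.l3_over_l1):
                rows.append({"run": rep, "mcs": int(t),
                             "l2_over_l1": r2, "l3_over_l1": r3})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def pulling_campaign() -> pd.DataFrame:
    """25 one-cell-type runs with pulling force 20 and gamma(c, M) = 15
    (J(c, M) = 20): the variability/phase-count study conditions."""
    return run_campaign(25, base_seed=42, model="ce_one_type",
                        n_cells=DESK_CELLS, j_cell_medium=20.0,
                        lambda_f=20.0)


@pytest.fixture(scope="session")
def no_pulling_campaign() -> pd.DataFrame:
    """20 matched runs without pulling (lambda_f = 0)."""
    return run_campaign(20, base_seed=4200, model="ce_one_type",
                        n_cells=DESK_CELLS, j_cell_medium=20.0,
                        lambda_f=0.0)


@pytest.fixture(scope="session")
def repolarization_clouds() -> dict[str, np.ndarray]:
    """Final (L2/L1, L3/L1) clouds of 30 runs per repolarization rule at
    the one-type optimum (lambda_f = 15, gamma(c, M) = 5)."""
    out = {}
    for i, mode in enumerate(("vicsek", "belmonte")):
        table = run_campaign(30, base_seed=9000 + 500 * i,
                             record_every=12_000, mcs=12_000,
                             model="ce_one_type", n_cells=DESK_CELLS,
                             lambda_f=15.0, repolarization_mode=mode)
        final = table[table["mcs"] == 12_000]
        out[mode] = final[["l2_over_l1", "l3_over_l1"]].to_numpy()
    return out


@pytest.fixture(scope="session")
def adhesion_slope_campaigns() -> dict[float, pd.DataFrame]:
    """8 differential-adhesion runs per slope in {1, 2.5, 4} (offset 25,
    30 cells, 15,000 MCS)."""
    out = {}
    for i, slope in enumerate((1.0, 2.5, 4.0)):
        out[slope] = run_campaign(8, base_seed=7000 + 100 * i,
                                  record_every=15_000, mcs=15_000,
                                  model="diff_adhesion", n_cells=30,
                                  slope=slope)
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def small_sim() -> Simulation:
    """A small, partially relaxed one-type simulation for structural tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = Simulation(SimConfig(model="ce_one_type", n_cells=12,
                                   lambda_f=15.0, seed=5))
        sim.step(200)
    return sim
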