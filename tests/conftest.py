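import numpy as np
import pandas as pd
import pytest

import mapthresh as mt


def design_from_frame(df: pd.DataFrame, cols=("map",)) -> mt.DesignMatrix:
    return mt.DesignMatrix(
        strata=df["set_id"].to_numpy(),
        y=df["is_case"].to_numpy(),
        X=df[list(cols)].to_numpy(dtype=float),
        names=list(cols),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pairs_design():
    """1:1 matched pairs, one binary exposure: 10 case-exposed-only and 5
    control-exposed-only discordant pairs (closed-form beta = ln 2)."""
    strata = np.repeat(np.arange(15), 2)
    y = np.tile([1, 0], 15)
    x = np.zeros(30)
    x[0:20:2] = 1.0  # case exposed in first 10 pairs
    x[21:30:2] = 1.0  # control exposed in last 5 pairs
    return mt.DesignMatrix(strata=strata, y=y, X=x[:, None], names=["exposed"])


@pytest.fixture
def small_random_design(rng):
    """3 sets of 1:2 with two continuous covariates."""
    strata = np.repeat(np.arange(3), 3)
    y = np.tile([1, 0, 0], 3)
    X = rng.normal(size=(9, 2))
    return mt.DesignMatrix(strata=strata, y=y, X=X, names=["a", "b"])


@pytest.fixture(scope="session")
def hinge_sets():
    """500 matched sets, 1:5, symmetric hinge truth at 95 mmHg."""
    cfg = mt.CohortConfig(
        theta_true=95.0,
        slope_below_low_hba1c=0.05, slope_below_high_hba1c=0.05,
        slope_above_low_hba1c=0.05, slope_above_high_hba1c=0.05,
    )
    return mt.simulate_matched_sets(500, 5, config=cfg, seed=77)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = mt.CohortConfig(n_subjects=4000, seed=11, baseline_rate=1.5e-4)
    return mt.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matched(small_cohort):
    from mapthresh.matching import identify_cases, matched_frame, risk_set_sample

    cases = mt.identify_cases(small_cohort)
    sets, report = mt.risk_set_sample(small_cohort, cases, age_caliper=5.0, seed=3)
    frame = mt.matched_frame(small_cohort, sets)
    frame["hba1c_high"] = (frame["hba1c_pct"] >= 7.0).astype(int)
    return frame
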