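"""Synthetic cohort of type 2 diabetes patients with a U-shaped MAP risk profile.

The generator emulates the source population of a UK primary-care diabetes
register: covariate marginals follow the control column of the study's
descriptive table, and cardiovascular-hospitalisation event times are drawn
from an exponential waiting-time model whose log-rate is piecewise linear
(hinge) in mean arterial pressure with HbA1c-group-specific slopes:

    log rate_i = log(baseline_rate)
               + beta_below,g * (theta - MAP_i)_+ + beta_above,g * (MAP_i - theta)_+
               + sum_c gamma_c * x_ic

where g indexes the HbA1c group (< cut vs >= cut) and theta is the true MAP
nadir.  A smooth-quadratic alternative (``effect_shape="quadratic"``) is
provided for robustness checks, and ``effect_shape="linear"`` for
calibration studies of the linearity test.

A direct matched-set simulator (:func:`simulate_matched_sets`) draws
covariates per matched set and assigns the case by the conditional-logistic
probabilities implied by the same linear predictor; it is the fast,
statistically equivalent route used by the repeated-simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "DEFAULT_COVARIATE_PARAMS",
    "compute_map",
    "hba1c_pct_to_mmol",
    "hba1c_mmol_to_pct",
    "generate_cohort",
    "validate_cohort",
    "simulate_matched_sets",
]

# IFCC <-> NGSP master equation coefficients
_IFCC_SLOPE = 10.929
_IFCC_INTERCEPT = 2.15

# Control-column marginals of the study's descriptive table; age, sex split,
# diabetes duration and practice count are not tabulated there and use
# values typical of a UK type 2 diabetes register (see docs/methods.md).
DEFAULT_COVARIATE_PARAMS: dict = {
    "age": {"mean": 70.0, "sd": 10.0, "min": 35.0, "max": 95.0},
    "male_frac": 0.55,
    "n_practices": 18,
    "sbp": {"mean": 134.0, "sd": 11.1},
    "dbp": {"mean": 72.0, "sd": 10.0},
    "sbp_dbp_corr": 0.6,
    "bmi": {"mean": 29.0, "sd": 5.8, "min": 15.0},
    "hba1c_pct": {"mean": 7.4, "sd": 1.3, "min": 3.5, "max": 18.0},
    "tc": {"mean": 4.2, "sd": 1.0, "min": 1.5},
    "tg": {"mean": 1.7, "sd": 0.9, "min": 0.3},
    "hdl": {"mean": 1.2, "sd": 0.4, "min": 0.4},
    "ldl": {"mean": 2.4, "sd": 0.8, "min": 0.5},
    "egfr": {"mean": 56.6, "sd": 17.9, "min": 5.0},
    "smoker": 0.658,
    "lipid_tx": 0.722,
    "aspirin": 0.537,
    "chd_history": 0.356,
    "cerebrovascular_history": 0.144,
    "diabetes_duration": {"mean": 7.0, "sd": 5.0, "min": 0.25},
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort and its event process.

    Slopes are per-mmHg log-rate-ratios on either side of the nadir
    ``theta_true``; ``*_low`` applies to the HbA1c < ``hba1c_cut_pct`` group,
    ``*_high`` to the rest.  Defaults encode the study's qualitative pattern:
    below the nadir, risk rises faster in the low-HbA1c group; above it, only
    the high-HbA1c group's risk rises materially.
    """

    n_subjects: int = 20_000
    seed: int = 0
    followup_days: float = 730.0
    covariate_params: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS))
    baseline_rate: float = 4e-5  # events per person-day at the nadir
    theta_true: float = 97.0
    slope_below_low_hba1c: float = 0.05
    slope_below_high_hba1c: float = 0.02
    slope_above_low_hba1c: float = 0.005
    slope_above_high_hba1c: float = 0.05
    covariate_effects: dict = field(
        default_factory=lambda: {"chd_history": 0.7, "bmi": 0.03, "tg": 0.2}
    )
    hba1c_cut_pct: float = 7.0
    effect_shape: Literal["hinge", "quadratic", "linear"] = "hinge"
    quad_curvature: float = 0.002  # log-rate per mmHg^2, quadratic mode
    linear_slope: float = 0.03  # log-rate per mmHg, linear mode

    def validate(self) -> None:
        if self.n_subjects < 12:
            raise ValueError("n_subjects must be >= 12 (at least two fillable risk sets)")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.followup_days <= 0:
            raise ValueError("followup_days must be positive")
        for name, spec in self.covariate_params.items():
            if isinstance(spec, dict) and "sd" in spec and spec["sd"] <= 0:
                raise ValueError(f"covariate {name!r} has non-positive SD")
        cp = self.covariate_params
        sbp, dbp = cp["sbp"], cp["dbp"]
        map_mean = (2 * dbp["mean"] + sbp["mean"]) / 3
        map_sd = np.sqrt(
            (4 * dbp["sd"] ** 2 + sbp["sd"] ** 2 + 4 * cp["sbp_dbp_corr"] * sbp["sd"] * dbp["sd"]) / 9
        )
        if abs(self.theta_true - map_mean) > 6 * map_sd:
            raise ValueError(
                f"theta_true={self.theta_true} lies outside the configured MAP support "
                f"({map_mean:.1f} +/- 6*{map_sd:.1f})"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubjectRecord:
    """One simulated (or imported) person; field order matches the cohort CSV."""

    subject_id: int
    age: float
    sex: str
    practice_id: int
    sbp: float
    dbp: float
    map: float
    pulse_pressure: float
    hba1c_pct: float
    hba1c_mmol: float
    bmi: float
    tc: float
    tg: float
    hdl: float
    ldl: float
    egfr: float
    smoker: int
    lipid_tx: int
    aspirin: int
    chd_history: int
    cerebrovascular_history: int
    diabetes_duration: float
    event: int
    event_time: float


COHORT_COLUMNS = [f.name for f in SubjectRecord.__dataclass_fields__.values()]  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def compute_map(sbp, dbp):
    """Mean arterial pressure [(2 x DBP) + SBP] / 3, in mmHg.

    Raises ``ValueError`` when SBP < DBP (an invalid measurement pair).
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.any(dbp <= 0) or np.any(sbp <= 0):
        raise ValueError("blood pressures must be positive")
    if np.any(sbp < dbp):
        raise ValueError("invalid measurement: SBP < DBP")
    out = (2.0 * dbp + sbp) / 3.0
    return float(out) if out.ndim == 0 else out


def hba1c_pct_to_mmol(pct, rounded: bool = False):
    """NGSP % to IFCC mmol/mol: 10.929 * (% - 2.15)."""
    pct = np.asarray(pct, dtype=float)
    if np.any((pct < 3.0 - 1e-9) | (pct > 20.0 + 1e-9)):
        raise ValueError("HbA1c % out of plausible range [3, 20]")
    out = _IFCC_SLOPE * (pct - _IFCC_INTERCEPT)
    if rounded:
        out = np.rint(out)
    return float(out) if out.ndim == 0 else out


def hba1c_mmol_to_pct(mmol):
    """IFCC mmol/mol to NGSP %: inverse of the master equation."""
    mmol = np.asarray(mmol, dtype=float)
    out = mmol / _IFCC_SLOPE + _IFCC_INTERCEPT
    if np.any((out < 3.0 - 1e-6) | (out > 20.0 + 1e-6)):
        raise ValueError("HbA1c mmol/mol out of plausible range")
    return float(out) if out.ndim == 0 else out


def map_log_rate_shape(
    map_values: np.ndarray,
    high_group: np.ndarray,
    config: CohortConfig,
) -> np.ndarray:
    """True MAP contribution to the log event rate, per effect shape."""
    m = np.asarray(map_values, dtype=float)
    hi = np.asarray(high_group, dtype=bool)
    theta = config.theta_true
    if config.effect_shape == "hinge":
        below = np.clip(theta - m, 0.0, None)
        above = np.clip(m - theta, 0.0, None)
        b = np.where(hi, config.slope_below_high_hba1c, config.slope_below_low_hba1c)
        a = np.where(hi, config.slope_above_high_hba1c, config.slope_above_low_hba1c)
        return b * below + a * above
    if config.effect_shape == "quadratic":
        return config.quad_curvature * (m - theta) ** 2
    if config.effect_shape == "linear":
        return config.linear_slope * (m - theta)
    raise ValueError(f"unknown effect_shape {config.effect_shape!r}")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, n, lo=-np.inf, hi=np.inf):
    x = rng.normal(mean, sd, size=n)
    bad = (x < lo) | (x > hi)
    while np.any(bad):  # redraw out-of-support values; support is wide, loop is short
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate the cohort; deterministic given ``config.seed``.

    Returns one row per subject with the :class:`SubjectRecord` columns.
    Covariates are independent except (SBP, DBP), drawn bivariate normal with
    the configured correlation so MAP and pulse pressure have realistic joint
    support.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    cp = config.covariate_params

    age = _truncated_normal(rng, cp["age"]["mean"], cp["age"]["sd"], n,
                            cp["age"].get("min", -np.inf), cp["age"].get("max", np.inf))
    sex = np.where(rng.random(n) < cp["male_frac"], "M", "F")
    practice = rng.integers(0, cp["n_practices"], size=n)

    rho = cp["sbp_dbp_corr"]
    cov = np.array(
        [
            [cp["sbp"]["sd"] ** 2, rho * cp["sbp"]["sd"] * cp["dbp"]["sd"]],
            [rho * cp["sbp"]["sd"] * cp["dbp"]["sd"], cp["dbp"]["sd"] ** 2],
        ]
    )
    bp = rng.multivariate_normal([cp["sbp"]["mean"], cp["dbp"]["mean"]], cov, size=n)
    bad = bp[:, 0] <= bp[:, 1]  # SBP must exceed DBP
    while np.any(bad):
        bp[bad] = rng.multivariate_normal([cp["sbp"]["mean"], cp["dbp"]["mean"]], cov,
                                          size=int(bad.sum()))
        bad = bp[:, 0] <= bp[:, 1]
    sbp, dbp = bp[:, 0], bp[:, 1]

    def cont(name):
        s = cp[name]
        return _truncated_normal(rng, s["mean"], s["sd"], n,
                                 s.get("min", -np.inf), s.get("max", np.inf))

    hba1c = cont("hba1c_pct")
    frame = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "age": age,
            "sex": sex,
            "practice_id": practice,
            "sbp": sbp,
            "dbp": dbp,
            "map": compute_map(sbp, dbp),
            "pulse_pressure": sbp - dbp,
            "hba1c_pct": hba1c,
            "hba1c_mmol": hba1c_pct_to_mmol(hba1c),
            "bmi": cont("bmi"),
            "tc": cont("tc"),
            "tg": cont("tg"),
            "hdl": cont("hdl"),
            "ldl": cont("ldl"),
            "egfr": cont("egfr"),
            "smoker": (rng.random(n) < cp["smoker"]).astype(int),
            "lipid_tx": (rng.random(n) < cp["lipid_tx"]).astype(int),
            "aspirin": (rng.random(n) < cp["aspirin"]).astype(int),
            "chd_history": (rng.random(n) < cp["chd_history"]).astype(int),
            "cerebrovascular_history": (rng.random(n) < cp["cerebrovascular_history"]).astype(int),
            "diabetes_duration": cont("diabetes_duration"),
        }
    )

    high = frame["hba1c_pct"].to_numpy() >= config.hba1c_cut_pct
    # covariate effects are centred so baseline_rate stays interpretable at the nadir
    cov_part = np.zeros(n)
    for name, eff in config.covariate_effects.items():
        col = frame[name].to_numpy(dtype=float)
        cov_part += eff * (col - col.mean())
    lin_pred = map_log_rate_shape(frame["map"].to_numpy(), high, config) + cov_part

    rate = config.baseline_rate * np.exp(lin_pred)
    t = rng.exponential(1.0 / rate)
    event = t <= config.followup_days
    frame["event"] = event.astype(int)
    frame["event_time"] = np.where(event, t, config.followup_days)
    return frame[COHORT_COLUMNS]


def validate_cohort(frame: pd.DataFrame, followup_days: float | None = None) -> None:
    """Assert the SubjectRecord invariants on a cohort frame."""
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort frame missing columns: {missing}")
    m = compute_map(frame["sbp"].to_numpy(), frame["dbp"].to_numpy())
    if not np.allclose(frame["map"], m, atol=1e-9):
        raise ValueError("map column inconsistent with (2*dbp + sbp)/3")
    if not np.allclose(frame["pulse_pressure"], frame["sbp"] - frame["dbp"], atol=1e-9):
        raise ValueError("pulse_pressure inconsistent with sbp - dbp")
    expect = hba1c_pct_to_mmol(frame["hba1c_pct"].to_numpy())
    if not np.allclose(frame["hba1c_mmol"], expect, atol=1e-6):
        raise ValueError("hba1c_mmol inconsistent with the declared unit conversion")
    ev = frame["event"].astype(bool)
    if np.any(frame.loc[ev, "event_time"] <= 0):
        raise ValueError("event times must be positive")
    if followup_days is not None and np.any(frame["event_time"] > followup_days + 1e-9):
        raise ValueError("event_time beyond follow-up horizon")


# ---------------------------------------------------------------------------
# direct matched-set simulation (fast path for repeated-simulation studies)
# ---------------------------------------------------------------------------

def simulate_matched_sets(
    n_sets: int,
    controls_per_case: int = 5,
    config: CohortConfig | None = None,
    map_mean: float = 92.0,
    map_sd: float = 9.5,
    map_range: tuple[float, float] = (55.0, 130.0),
    high_hba1c_frac: float = 0.55,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate matched case-control sets directly from the conditional model.

    For each set, ``controls_per_case + 1`` members receive independent MAP
    and HbA1c-group draws; the case is the member selected with probability
    proportional to ``exp`` of the true log-rate linear predictor.  This is
    the conditional-likelihood data-generating process itself and is
    distributionally equivalent to exponential event times plus risk-set
    sampling, at a fraction of the cost — it is the workhorse of the
    calibration, power, recovery and coverage simulations.

    Returns a long frame with columns ``set_id, is_case, map, hba1c_high``
    (plus ``hba1c_pct`` consistent with the group label).
    """
    cfg = config if config is not None else CohortConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = controls_per_case + 1
    total = n_sets * m

    map_vals = _truncated_normal(rng, map_mean, map_sd, total, *map_range)
    high = rng.random(total) < high_hba1c_frac
    lin = map_log_rate_shape(map_vals, high, cfg).reshape(n_sets, m)
    lin = lin - lin.max(axis=1, keepdims=True)
    probs = np.exp(lin)
    probs /= probs.sum(axis=1, keepdims=True)
    # vectorised categorical draw per set
    cum = np.cumsum(probs, axis=1)
    u = rng.random((n_sets, 1))
    case_pos = (u > cum).sum(axis=1)

    is_case = np.zeros((n_sets, m), dtype=int)
    is_case[np.arange(n_sets), case_pos] = 1
    # HbA1c % consistent with the group label, for unit round-trips downstream
    hba1c_pct = np.where(
        high,
        cfg.hba1c_cut_pct + np.abs(rng.normal(0.8, 0.6, total)),
        cfg.hba1c_cut_pct - np.abs(rng.normal(0.6, 0.4, total)) - 0.01,
    )
    hba1c_pct = np.clip(hba1c_pct, 3.5, 18.0)
    return pd.DataFrame(
        {
            "set_id": np.repeat(np.arange(n_sets), m),
            "is_case": is_case.ravel(),
            "map": map_vals,
            "hba1c_high": high.astype(int),
            "hba1c_pct": hba1c_pct,
        }
    )
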