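"""MAP threshold (breakpoint) detection with a bootstrap confidence interval.

Candidate thresholds are scanned over the P5-P95 range of observed MAP.  At
each candidate t the scan model gains a hinge column (MAP - t)_+ — the
minimal break in slope — and the fit records the AIC, the hinge coefficient
and its Wald p-value.  The selected threshold is the candidate with a
significant break (p < alpha) achieving the minimum AIC; when no candidate
breaks significantly the result carries an explicit no-threshold status.
The CI comes from a percentile bootstrap that resamples matched sets (the
stratum is the resampling unit) and reruns the whole scan-and-select
pipeline per replicate.

Two scan models are available.  ``segmented`` (default) adds the hinge to a
linear MAP term, so the break coefficient is the slope change at t and the
kink location is well identified.  ``spline_hinge`` adds the hinge to the
full natural cubic spline; because the spline can absorb a kink smoothly,
the break coefficient there is weakly identified and the test has little
power — the mode is kept for comparability, not as the default (see
docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .clogit import DesignMatrix, fit_clogit
from .splines import SplineSpec, default_spec

logger = logging.getLogger("mapthresh")

__all__ = [
    "ThresholdEstimate",
    "candidate_grid",
    "scan_thresholds",
    "select_threshold",
    "bootstrap_ci",
    "estimate_threshold",
]

HINGE_COL = "map_hinge"


@dataclass
class ThresholdEstimate:
    """Selected breakpoint, its bootstrap CI, and the full scan table."""

    threshold: float | None
    status: str  # "ok" | "no_threshold"
    scan: pd.DataFrame
    ci_low: float | None = None
    ci_high: float | None = None
    n_bootstrap: int = 0
    bootstrap_thresholds: np.ndarray = field(default_factory=lambda: np.array([]))
    n_boot_no_threshold: int = 0
    ci_unreliable: bool = False

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "status": self.status,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_bootstrap": self.n_bootstrap,
            "n_boot_no_threshold": self.n_boot_no_threshold,
            "ci_unreliable": self.ci_unreliable,
        }


def candidate_grid(map_values, p_lo: float = 5.0, p_hi: float = 95.0,
                   step: float = 1.0) -> np.ndarray:
    """Evenly stepped candidates between the P5 and P95 empirical percentiles.

    Percentiles use the linear-interpolation convention.  The grid starts at
    the lower percentile and advances by ``step``; the upper percentile is
    included when it falls on the step lattice.
    """
    m = np.asarray(map_values, dtype=float)
    if np.ptp(m) == 0:
        raise ValueError("MAP is constant; no candidate thresholds exist")
    lo, hi = np.percentile(m, [p_lo, p_hi])
    if hi <= lo:
        return np.array([lo])
    return np.arange(lo, hi + 1e-9, step)


def _hinge_design(base: DesignMatrix, map_values: np.ndarray, t: float) -> DesignMatrix | None:
    """Base design plus the hinge column (map - t)_+; None when degenerate."""
    h = np.clip(map_values - t, 0.0, None)
    mins = np.minimum.reduceat(h, base.starts)
    maxs = np.maximum.reduceat(h, base.starts)
    if np.all(maxs - mins == 0):  # constant within every stratum: no information
        return None
    return base.with_column_fast(h, HINGE_COL)


def scan_thresholds(
    design: DesignMatrix,
    map_column: str = "map",
    spec: SplineSpec | None = None,
    candidates: np.ndarray | None = None,
    adjust: list[str] | None = None,
    scan_model: str = "segmented",
) -> pd.DataFrame:
    """Fit the scan model + hinge at every candidate; table of (candidate, aic, coef, p).

    A candidate whose hinge column is degenerate (all zero, or constant in
    every stratum) wastes its degree of freedom: it is recorded with
    ``aic = base AIC + 2`` and an undefined coefficient.  Non-convergence at
    a candidate is recorded and the candidate excluded from selection.
    Consecutive candidates warm-start from the previous solution, which keeps
    the scan cheap inside the bootstrap.
    """
    from .splines import _family_design

    mvals = design.X[:, design.names.index(map_column)]
    if spec is None:
        if scan_model == "segmented":
            spec = SplineSpec(family="linear")
        elif scan_model == "spline_hinge":
            spec = default_spec(mvals, family="natural_cubic")
        else:
            raise ValueError(f"unknown scan_model {scan_model!r}")
    if candidates is None:
        candidates = candidate_grid(mvals)

    # `design` rows are already strata-sorted, so `base` rows align with `mvals`
    base = _family_design(design, mvals, spec, adjust)
    base_fit = fit_clogit(base)

    rows = []
    warm = None
    for t in np.asarray(candidates, dtype=float):
        hd = _hinge_design(base, mvals, t)
        if hd is None:
            rows.append({"candidate": t, "aic": base_fit.aic + 2.0,
                         "break_coefficient": np.nan, "break_se": np.nan,
                         "break_p": np.nan, "converged": True, "degenerate": True})
            continue
        beta0 = None
        if warm is not None and len(warm) == hd.n_params:
            beta0 = warm
        fit = fit_clogit(hd, beta0=beta0)
        if not fit.converged and beta0 is not None:  # retry cold
            fit = fit_clogit(hd)
        if fit.converged:
            warm = fit.beta.copy()
        j = fit.names.index(HINGE_COL)
        se = fit.se[j]
        z = fit.beta[j] / se if se > 0 else np.nan
        rows.append(
            {
                "candidate": t,
                "aic": fit.aic,
                "break_coefficient": fit.beta[j],
                "break_se": se,
                # two-sided normal p via erfc (cheaper than stats.norm in this loop)
                "break_p": float(special.erfc(abs(z) / np.sqrt(2.0))) if np.isfinite(z) else np.nan,
                "converged": fit.converged,
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)


def select_threshold(scan: pd.DataFrame, alpha: float = 0.05) -> ThresholdEstimate:
    """Minimum-AIC candidate among those with a significant break.

    AIC ties break toward the candidate nearest the scan median.  An empty
    significant set yields status ``no_threshold`` rather than an error.
    """
    if scan.empty:
        raise ValueError("empty scan table")
    ok = scan[scan["converged"] & ~scan["degenerate"] & (scan["break_p"] < alpha)]
    if ok.empty:
        return ThresholdEstimate(threshold=None, status="no_threshold", scan=scan)
    amin = ok["aic"].min()
    tied = ok[np.isclose(ok["aic"], amin, rtol=0, atol=1e-9)]
    if len(tied) > 1:
        med = float(scan["candidate"].median())
        tied = tied.iloc[[int(np.argmin(np.abs(tied["candidate"] - med)))]]
        logger.info("AIC tie in threshold scan broken toward the scan median")
    return ThresholdEstimate(threshold=float(tied["candidate"].iloc[0]), status="ok", scan=scan)


def bootstrap_ci(
    design: DesignMatrix,
    map_column: str = "map",
    spec: SplineSpec | None = None,
    adjust: list[str] | None = None,
    n_boot: int = 1000,
    level: float = 95.0,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    p_lo: float = 5.0,
    p_hi: float = 95.0,
    step: float = 1.0,
    scan_model: str = "segmented",
) -> dict:
    """Percentile bootstrap CI for the threshold, resampling matched sets.

    Each replicate redraws ``n_sets`` strata with replacement, rebuilds the
    candidate grid from the resampled MAP distribution, and reruns
    scan-and-select.  Replicates returning no-threshold are excluded from the
    percentile computation but counted; more than 50% of them flags the CI
    unreliable.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = design.n_sets
    thresholds = []
    n_none = 0
    for _ in range(n_boot):
        boot = design.subset_sets(rng.integers(0, S, size=S))
        mvals = boot.X[:, boot.names.index(map_column)]
        try:
            cand = candidate_grid(mvals, p_lo=p_lo, p_hi=p_hi, step=step)
            est = select_threshold(
                scan_thresholds(boot, map_column, spec, cand, adjust, scan_model=scan_model),
                alpha=alpha,
            )
        except Exception as exc:  # pragma: no cover - degenerate resample
            logger.warning("bootstrap replicate failed: %s", exc)
            n_none += 1
            continue
        if est.threshold is None:
            n_none += 1
        else:
            thresholds.append(est.threshold)

    thresholds = np.asarray(thresholds, dtype=float)
    out = {
        "n_bootstrap": n_boot,
        "n_boot_no_threshold": n_none,
        "bootstrap_thresholds": thresholds,
        "ci_unreliable": n_none > 0.5 * n_boot,
    }
    if thresholds.size:
        tail = (100.0 - level) / 2.0
        lo, hi = np.percentile(thresholds, [tail, 100.0 - tail])
        out.update({"ci_low": float(lo), "ci_high": float(hi)})
    else:
        out.update({"ci_low": None, "ci_high": None})
    if out["ci_unreliable"]:
        logger.warning("more than half of bootstrap replicates found no threshold; CI unreliable")
    return out


def estimate_threshold(
    design: DesignMatrix,
    map_column: str = "map",
    adjust: list[str] | None = None,
    n_boot: int = 1000,
    level: float = 95.0,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    p_lo: float = 5.0,
    p_hi: float = 95.0,
    step: float = 1.0,
    scan_model: str = "segmented",
) -> ThresholdEstimate:
    """Full pipeline: scan, select, and (when a threshold is found) bootstrap CI."""
    mvals = design.X[:, design.names.index(map_column)]
    cand = candidate_grid(mvals, p_lo=p_lo, p_hi=p_hi, step=step)
    est = select_threshold(
        scan_thresholds(design, map_column, None, cand, adjust, scan_model=scan_model),
        alpha=alpha,
    )
    if est.threshold is None or n_boot <= 0:
        return est
    ci = bootstrap_ci(design, map_column, None, adjust, n_boot=n_boot, level=level,
                      seed=seed, alpha=alpha, p_lo=p_lo, p_hi=p_hi, step=step,
                      scan_model=scan_model)
    est.ci_low = ci["ci_low"]
    est.ci_high = ci["ci_high"]
    est.n_bootstrap = ci["n_bootstrap"]
    est.bootstrap_thresholds = ci["bootstrap_thresholds"]
    est.n_boot_no_threshold = ci["n_boot_no_threshold"]
    est.ci_unreliable = ci["ci_unreliable"]
    if est.ci_low is not None and not (est.ci_low <= est.threshold <= est.ci_high):
        logger.warning(
            "percentile bootstrap CI (%.1f, %.1f) does not bracket the point estimate %.1f",
            est.ci_low, est.ci_high, est.threshold,
        )
    return est
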