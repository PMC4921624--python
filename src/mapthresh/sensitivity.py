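"""HbA1c x MAP interaction, restriction sensitivity analyses, and the
unmeasured-confounder bias array.

The interaction model splits MAP at the detected threshold theta into the
segments (theta - MAP)_+ and (MAP - theta)_+ and lets each segment's slope
differ between the HbA1c groups (< cut vs >= cut, cut at the usual ADA
target of 7% = 53 mmol/mol).  Sensitivity analyses restrict the MAP range
or drop early admissions and refit.  The bias array quantifies how strong
an unmeasured binary confounder would have to be to explain the observed
rate ratio away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clogit import DesignMatrix, FitResult, fit_clogit

logger = logging.getLogger("mapthresh")

__all__ = [
    "InteractionResult",
    "ConfounderGrid",
    "dichotomize_hba1c",
    "fit_interaction",
    "restrict_range",
    "exclude_early_cases",
    "confounder_array",
]


# ---------------------------------------------------------------------------
# HbA1c dichotomy
# ---------------------------------------------------------------------------

def dichotomize_hba1c(values, cut_pct: float = 7.0, unit: str = "auto") -> np.ndarray:
    """Group labels 0 (< cut) / 1 (>= cut) from HbA1c in % or mmol/mol.

    ``unit="auto"`` treats values above 20 as mmol/mol (no NGSP HbA1c is
    that high).  Values in mmol/mol are compared against the *rounded*
    mmol/mol cut (7% -> 53 mmol/mol), matching how the dual-unit target is
    quoted clinically; the boundary value itself goes to the high group.
    """
    from .cohort import hba1c_pct_to_mmol

    v = np.asarray(values, dtype=float)
    cut_mmol = float(hba1c_pct_to_mmol(cut_pct, rounded=True))
    if unit == "auto":
        is_mmol = v > 20.0
        high = np.where(is_mmol, v >= cut_mmol - 1e-12, v >= cut_pct - 1e-12)
        return high.astype(int)
    if unit == "pct":
        return (v >= cut_pct - 1e-12).astype(int)
    if unit == "mmol":
        return (v >= cut_mmol - 1e-12).astype(int)
    raise ValueError(f"unknown unit {unit!r}")


# ---------------------------------------------------------------------------
# segmented interaction model
# ---------------------------------------------------------------------------

@dataclass
class InteractionResult:
    """Per-group, per-segment MAP slopes around the threshold with Wald inference.

    Slopes are per-mmHg log incidence-rate-ratios: ``below`` slopes multiply
    (theta - MAP)_+, ``above`` slopes multiply (MAP - theta)_+; positive
    values mean risk rises moving away from the threshold.
    """

    threshold: float
    hba1c_cut_pct: float
    slope_below_low: float
    slope_below_low_se: float
    slope_below_high: float
    slope_below_high_se: float
    slope_above_low: float
    slope_above_low_se: float
    slope_above_high: float
    slope_above_high_se: float
    interaction_p_below: float
    interaction_p_above: float
    fit: FitResult | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "fit"}
        return d


def fit_interaction(
    design: DesignMatrix,
    map_column: str = "map",
    threshold: float = 97.0,
    hba1c_groups: np.ndarray | None = None,
    hba1c_column: str = "hba1c_high",
    adjust: list[str] | None = None,
    include_interactions: bool = True,
) -> InteractionResult:
    """Conditional-logistic segmented fit with HbA1c-group-specific slopes.

    Model columns: (theta-MAP)_+, (MAP-theta)_+, the high-HbA1c indicator
    (dropped automatically, with a warning, when constant within every
    stratum), and the two products of segment x indicator.  Group membership
    comes from ``hba1c_groups`` (0/1 per design row, in the design's sorted
    row order) or, by default, from the ``hba1c_column`` of the design.
    Group slopes are linear combinations of the coefficients; the
    per-segment interaction p-values are Wald tests of the product terms.
    """
    m = design.X[:, design.names.index(map_column)]
    if hba1c_groups is not None:
        hi = np.asarray(hba1c_groups, dtype=float)
        if hi.shape[0] != design.X.shape[0]:
            raise ValueError("hba1c_groups length must match the design rows")
    else:
        hi = design.X[:, design.names.index(hba1c_column)]
    below = np.clip(threshold - m, 0.0, None)
    above = np.clip(m - threshold, 0.0, None)

    cols = {
        "seg_below": below,
        "seg_above": above,
        "hba1c_high": hi,
    }
    if include_interactions:
        cols["seg_below_x_high"] = below * hi
        cols["seg_above_x_high"] = above * hi
    adj_idx = [design.names.index(a) for a in (adjust or [])]
    X = np.column_stack(list(cols.values()) + ([design.X[:, adj_idx]] if adj_idx else []))
    seg_design = DesignMatrix(
        strata=design.strata.copy(),
        y=design.y.copy(),
        X=X,
        names=list(cols) + [design.names[i] for i in adj_idx],
    )
    fit = fit_clogit(seg_design)
    names = fit.names

    def slope(base: str, inter: str | None):
        i = names.index(base)
        if inter is None or inter not in names:
            return float(fit.beta[i]), float(fit.se[i])
        j = names.index(inter)
        est = fit.beta[i] + fit.beta[j]
        var = fit.cov[i, i] + fit.cov[j, j] + 2 * fit.cov[i, j]
        return float(est), float(np.sqrt(max(var, 0.0)))

    def inter_p(term: str) -> float:
        if term not in names:
            return float("nan")
        j = names.index(term)
        se = fit.se[j]
        if se <= 0:
            return float("nan")
        return float(2 * stats.norm.sf(abs(fit.beta[j] / se)))

    bl, bl_se = slope("seg_below", None)
    bh, bh_se = slope("seg_below", "seg_below_x_high")
    al, al_se = slope("seg_above", None)
    ah, ah_se = slope("seg_above", "seg_above_x_high")
    return InteractionResult(
        threshold=threshold,
        hba1c_cut_pct=7.0,
        slope_below_low=bl, slope_below_low_se=bl_se,
        slope_below_high=bh, slope_below_high_se=bh_se,
        slope_above_low=al, slope_above_low_se=al_se,
        slope_above_high=ah, slope_above_high_se=ah_se,
        interaction_p_below=inter_p("seg_below_x_high"),
        interaction_p_above=inter_p("seg_above_x_high"),
        fit=fit,
    )


# ---------------------------------------------------------------------------
# dataset restrictions
# ---------------------------------------------------------------------------

def restrict_range(matched: pd.DataFrame, lo: float, hi: float,
                   map_column: str = "map") -> tuple[pd.DataFrame, dict]:
    """Keep subjects with MAP in [lo, hi]; drop any set whose case is dropped.

    Sets left without controls are dropped too.  Returns the restricted
    frame and an accounting report.
    """
    if not lo < hi:
        raise ValueError("lo must be below hi")
    n0 = len(matched)
    keep = matched[(matched[map_column] >= lo) & (matched[map_column] <= hi)]
    cases_per_set = keep.groupby("set_id")["is_case"].sum()
    controls_per_set = keep.groupby("set_id")["is_case"].apply(lambda s: (s == 0).sum())
    good_sets = cases_per_set[(cases_per_set == 1)].index.intersection(
        controls_per_set[controls_per_set >= 1].index
    )
    out = keep[keep["set_id"].isin(good_sets)].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"MAP restriction to [{lo}, {hi}] leaves no usable sets")
    report = {
        "rows_before": n0,
        "rows_outside_range": int(n0 - len(keep)),
        "sets_before": int(matched["set_id"].nunique()),
        "sets_after": int(out["set_id"].nunique()),
        "rows_after": len(out),
    }
    return out, report


def exclude_early_cases(matched: pd.DataFrame, days: float = 90.0) -> tuple[pd.DataFrame, dict]:
    """Drop whole sets whose case's event time is within the first ``days``.

    Mirrors the early-admission sensitivity analysis; controls of a removed
    set are removed with it.  ``days=0`` is the identity.
    """
    early_sets = matched.loc[
        (matched["is_case"] == 1) & (matched["index_date"] <= days), "set_id"
    ].unique()
    out = matched[~matched["set_id"].isin(early_sets)].reset_index(drop=True)
    report = {
        "sets_before": int(matched["set_id"].nunique()),
        "sets_removed": int(len(early_sets)),
        "sets_after": int(out["set_id"].nunique()),
    }
    if out.empty:
        report["status"] = "empty: every case occurred within the exclusion window"
    return out, report


# ---------------------------------------------------------------------------
# unmeasured-confounder bias array
# ---------------------------------------------------------------------------

@dataclass
class ConfounderGrid:
    """External-adjustment bias array for a binary unmeasured confounder.

    ``bias`` is B(p0, gamma) = (1 + p1 (gamma-1)) / (1 + p0 (gamma-1)) with
    p1 = min(f * p0, 1): the factor by which a confounder of
    prevalence-ratio f between exposure groups and confounder-outcome odds
    ratio gamma distorts the observed rate ratio.  ``required_factor`` is,
    per p0, the confounder-outcome effect magnitude needed to move the
    adjusted IRR to 1 (inf when no finite effect suffices).
    """

    observed_irr: float
    prevalence_ratio: float
    p0_grid: np.ndarray
    gamma_grid: np.ndarray
    bias: np.ndarray  # (len(p0), len(gamma))
    adjusted_irr: np.ndarray
    required_factor: np.ndarray  # per p0
    capped_cells: list

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, p0 in enumerate(self.p0_grid):
            for j, g in enumerate(self.gamma_grid):
                recs.append({"p0": p0, "gamma": g, "bias": self.bias[i, j],
                             "adjusted_irr": self.adjusted_irr[i, j]})
        return pd.DataFrame(recs)


def bias_factor(p0, gamma, f: float = 1.5):
    """B(p0, gamma) = (1 + p1 (gamma-1)) / (1 + p0 (gamma-1)), p1 = min(f p0, 1)."""
    p0 = np.asarray(p0, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    p1 = np.minimum(f * p0, 1.0)
    return (1.0 + p1 * (gamma - 1.0)) / (1.0 + p0 * (gamma - 1.0))


def confounder_array(
    observed_irr: float,
    f: float = 1.5,
    p0_grid=None,
    gamma_grid=None,
) -> ConfounderGrid:
    """Bias array over (p0, gamma) and the effect size that explains the IRR away.

    For an observed IRR above 1 the bias can only reach it with a confounder
    concentrated among the exposed whose outcome effect magnitude gamma
    exceeds 1 (the same statement, by relabelling the confounder to its
    complement, as a protective factor 1/gamma); the closed-form solution of
    B(p0, gamma) = IRR is

        gamma = 1 + (IRR - 1) / (p1 - IRR * p0),

    finite only while IRR < p1/p0 <= f.  Cells where f*p0 exceeds 1 are
    capped at p1 = 1 and flagged.
    """
    if observed_irr <= 0:
        raise ValueError("observed IRR must be positive")
    if f <= 0:
        raise ValueError("prevalence ratio f must be positive")
    p0_grid = np.asarray(
        p0_grid if p0_grid is not None else np.arange(0.05, 0.96, 0.05), dtype=float
    )
    gamma_grid = np.asarray(
        gamma_grid if gamma_grid is not None else
        np.concatenate([np.arange(0.05, 1.0, 0.05), np.arange(1.0, 30.5, 0.5)]),
        dtype=float,
    )
    B = bias_factor(p0_grid[:, None], gamma_grid[None, :], f=f)
    adjusted = observed_irr / B

    # per-p0 effect magnitude solving B = observed (or 1/observed when IRR < 1)
    target = observed_irr if observed_irr >= 1.0 else 1.0 / observed_irr
    required = np.full(p0_grid.shape, np.inf)
    capped = []
    for i, p0 in enumerate(p0_grid):
        p1 = min(f * p0, 1.0)
        if f * p0 > 1.0:
            capped.append(float(p0))
        denom = p1 - target * p0
        if denom > 1e-12 and target > 1.0:
            required[i] = 1.0 + (target - 1.0) / denom
    return ConfounderGrid(
        observed_irr=float(observed_irr),
        prevalence_ratio=float(f),
        p0_grid=p0_grid,
        gamma_grid=gamma_grid,
        bias=B,
        adjusted_irr=adjusted,
        required_factor=required,
        capped_cells=capped,
    )
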