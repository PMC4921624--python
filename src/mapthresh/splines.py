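"""Spline bases for MAP and the adjusted dose-response curve.

Three basis families model the MAP / log-rate relationship inside the
conditional-logistic linear predictor:

* ``linear`` — MAP itself (one column);
* ``natural_cubic`` — natural cubic spline with interior knots plus boundary
  knots, C2 at interior knots and constrained linear beyond the boundaries;
  ``k_interior + 1`` columns (the intercept is absorbed by stratification);
* ``quadratic`` — C1 truncated-power spline of degree 2 on the same interior
  knots (``2 + k_interior`` columns).

Model choice follows minimum AIC across the families; nonlinearity is a
likelihood-ratio test of the spline model against the linear one.  The
fitted curve is reported as the incidence rate ratio relative to a reference
MAP (by default the estimated nadir) with delta-method pointwise confidence
bands and rag-plot bin counts of the observed MAP distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clogit import DesignMatrix, FitResult, fit_clogit, lrt, wald_joint

__all__ = [
    "SplineSpec",
    "DoseResponseCurve",
    "make_basis",
    "default_spec",
    "fit_family",
    "linearity_test",
    "dose_response",
    "knot_sensitivity",
]

FAMILIES = ("linear", "natural_cubic", "quadratic")


@dataclass
class SplineSpec:
    """Family + knot layout for the MAP basis."""

    family: str = "natural_cubic"
    interior_knots: list[float] = field(default_factory=list)
    boundary_knots: tuple[float, float] | None = None
    reference: float | None = None  # None: reference at the estimated nadir

    def validate(self, x: np.ndarray | None = None) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.family != "linear":
            ks = list(self.interior_knots)
            if sorted(set(ks)) != ks:
                raise ValueError("interior knots must be strictly increasing")
            if self.boundary_knots is not None:
                lo, hi = self.boundary_knots
                if not all(lo < k < hi for k in ks):
                    raise ValueError("interior knots must lie strictly inside the boundary knots")
            if x is not None:
                xmin, xmax = float(np.min(x)), float(np.max(x))
                allk = list(ks) + (list(self.boundary_knots) if self.boundary_knots else [])
                if any(k < xmin - 1e-9 or k > xmax + 1e-9 for k in allk):
                    raise ValueError("knots outside the observed data range")

    def column_names(self) -> list[str]:
        if self.family == "linear":
            return ["map"]
        if self.family == "natural_cubic":
            return [f"map_ns{j + 1}" for j in range(len(self.interior_knots) + 1)]
        return ["map", "map_sq"] + [f"map_qs{j + 1}" for j in range(len(self.interior_knots))]


def default_spec(x, family: str = "natural_cubic", n_interior: int = 3,
                 knot_rule: str = "equal_spacing", reference: float | None = None) -> SplineSpec:
    """Default knot layout for the observed MAP values.

    ``equal_spacing`` places ``n_interior`` knots at the 1/(n+1) ... n/(n+1)
    points of [min(x), max(x)] (3 knots -> quartile points of the range) with
    boundary knots at min/max; ``percentile`` uses the matching empirical
    percentiles instead, as the sensitivity alternative.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    fracs = np.arange(1, n_interior + 1) / (n_interior + 1)
    if family == "linear":
        return SplineSpec(family="linear", reference=reference)
    if knot_rule == "equal_spacing":
        interior = (lo + fracs * (hi - lo)).tolist()
    elif knot_rule == "percentile":
        interior = np.percentile(x, 100 * fracs).tolist()
    else:
        raise ValueError(f"unknown knot_rule {knot_rule!r}")
    return SplineSpec(family=family, interior_knots=interior,
                      boundary_knots=(lo, hi), reference=reference)


# ---------------------------------------------------------------------------
# basis construction
# ---------------------------------------------------------------------------

def _natural_cubic(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic basis on all knots (boundary + interior), K-1 columns.

    Truncated-cubic divided-difference construction: with knots
    xi_1 < ... < xi_K,

        N_1(x) = x,
        N_{k+1}(x) = d_k(x) - d_{K-1}(x),  k = 1..K-2,
        d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k),

    which is C2 everywhere and exactly linear outside [xi_1, xi_K].
    """
    K = len(knots)
    if K < 3:
        raise ValueError("natural cubic basis needs at least 3 distinct knots")

    def d(k):
        return (np.clip(x - knots[k], 0, None) ** 3
                - np.clip(x - knots[K - 1], 0, None) ** 3) / (knots[K - 1] - knots[k])

    cols = [x] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


def make_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the basis columns of ``spec`` at points ``x`` (no intercept)."""
    x = np.asarray(x, dtype=float)
    spec.validate()
    if spec.family == "linear":
        return x[:, None].copy()
    if spec.boundary_knots is None:
        raise ValueError("boundary knots are required for spline families")
    if spec.family == "natural_cubic":
        knots = np.array([spec.boundary_knots[0], *spec.interior_knots, spec.boundary_knots[1]])
        return _natural_cubic(x, knots)
    # quadratic: degree-2 truncated power basis, C1 at interior knots
    cols = [x, x**2] + [np.clip(x - k, 0, None) ** 2 for k in spec.interior_knots]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# family fitting and selection
# ---------------------------------------------------------------------------

def _family_design(design: DesignMatrix, map_values: np.ndarray, spec: SplineSpec,
                   adjust: list[str] | None) -> DesignMatrix:
    """Design with the MAP basis columns plus the named adjustment columns."""
    B = make_basis(map_values, spec)
    adj_idx = [design.names.index(a) for a in (adjust or [])]
    X = np.column_stack([B] + ([design.X[:, adj_idx]] if adj_idx else []))
    return DesignMatrix(
        strata=design.strata.copy(),
        y=design.y.copy(),
        X=X,
        names=spec.column_names() + [design.names[i] for i in adj_idx],
    )


def fit_family(
    design: DesignMatrix,
    map_column: str = "map",
    families: tuple[str, ...] = FAMILIES,
    adjust: list[str] | None = None,
    knot_rule: str = "equal_spacing",
) -> dict:
    """Fit each basis family and rank by AIC.

    All families are fitted on identical rows; the selected family is the
    AIC minimum with ties broken toward fewer parameters.  Non-converged
    families are excluded from the ranking with a warning entry.
    """
    mvals = design.X[:, design.names.index(map_column)]
    fits: dict[str, FitResult] = {}
    specs: dict[str, SplineSpec] = {}
    rows = []
    for fam in families:
        spec = default_spec(mvals, family=fam, knot_rule=knot_rule)
        fd = _family_design(design, mvals, spec, adjust)
        fit = fit_clogit(fd)
        specs[fam] = spec
        fits[fam] = fit
        rows.append(
            {
                "family": fam,
                "k": len(fit.names),
                "loglik": fit.loglik,
                "aic": fit.aic,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values(["aic", "k"], kind="stable").reset_index(drop=True)
    ranked = table[table["converged"]]
    if ranked.empty:
        raise RuntimeError("no basis family converged")
    best = ranked.sort_values(["aic", "k"], kind="stable").iloc[0]["family"]
    return {"aic_table": table, "selected": str(best), "fits": fits, "specs": specs,
            "map_values": mvals, "adjust": list(adjust or [])}


def linearity_test(design: DesignMatrix, map_column: str = "map",
                   spec: SplineSpec | None = None, adjust: list[str] | None = None,
                   method: str = "lrt") -> dict:
    """Test of linearity: spline model against the nested linear model.

    ``lrt`` (default) compares conditional log-likelihoods; ``wald`` jointly
    tests the nonlinear basis coefficients.
    """
    mvals = design.X[:, design.names.index(map_column)]
    if spec is None:
        spec = default_spec(mvals, family="natural_cubic")
    fd_spline = _family_design(design, mvals, spec, adjust)
    fit_spline = fit_clogit(fd_spline)
    lin = _family_design(design, mvals, SplineSpec(family="linear"), adjust)
    # rename so the linear column is recognised as nested in the spline basis
    lin.names[0] = spec.column_names()[0]
    fit_lin = fit_clogit(lin)
    if method == "wald":
        nonlinear = spec.column_names()[1:]
        res = wald_joint(fit_spline, nonlinear)
        return {"statistic": res["statistic"], "df": res["df"], "p": res["p"],
                "method": "wald", "fit_spline": fit_spline, "fit_linear": fit_lin}
    res = lrt(fit_spline, fit_lin)
    res.update({"method": "lrt", "fit_spline": fit_spline, "fit_linear": fit_lin})
    return res


# ---------------------------------------------------------------------------
# dose-response curve
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseCurve:
    """Fitted IRR curve on a MAP grid, relative to ``reference``."""

    grid: np.ndarray
    log_irr: np.ndarray
    se: np.ndarray
    irr: np.ndarray
    irr_ci_low: np.ndarray
    irr_ci_high: np.ndarray
    reference: float
    rag_bins: np.ndarray
    rag_counts: np.ndarray
    extrapolated: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "map": self.grid,
                "log_irr": self.log_irr,
                "se": self.se,
                "irr": self.irr,
                "irr_ci_low": self.irr_ci_low,
                "irr_ci_high": self.irr_ci_high,
                "extrapolated": self.extrapolated.astype(int),
            }
        )

    @property
    def nadir(self) -> float:
        return float(self.grid[np.argmin(self.log_irr)])


def curve_nadir(fit: FitResult, spec: SplineSpec, lo: float, hi: float,
                step: float = 0.1) -> float:
    """Argmin of the fitted MAP curve over [lo, hi]."""
    grid = np.arange(lo, hi + step / 2, step)
    B = make_basis(grid, spec)
    idx = [fit.names.index(c) for c in spec.column_names()]
    return float(grid[np.argmin(B @ fit.beta[idx])])


def dose_response(
    fit: FitResult,
    spec: SplineSpec,
    map_values: np.ndarray,
    grid_step: float = 0.5,
    level: float = 0.95,
    grid: np.ndarray | None = None,
) -> DoseResponseCurve:
    """Adjusted dose-response curve with delta-method pointwise CI.

    log IRR at grid point g is ``(B(g) - B(ref)) . beta`` restricted to the
    basis columns; its variance is the quadratic form of the contrast in the
    coefficient covariance.  The reference defaults to the estimated nadir
    over the observed MAP range, so the curve reads as risk relative to the
    optimum.  Grid points beyond the boundary knots are flagged as
    extrapolation.  Rag counts use 1-mmHg bins of the observed MAP values.
    """
    from scipy import stats

    map_values = np.asarray(map_values, dtype=float)
    lo = spec.boundary_knots[0] if spec.boundary_knots else float(map_values.min())
    hi = spec.boundary_knots[1] if spec.boundary_knots else float(map_values.max())
    if grid is None:
        grid = np.arange(lo, hi + grid_step / 2, grid_step)
    ref = spec.reference if spec.reference is not None else curve_nadir(fit, spec, lo, hi)

    idx = [fit.names.index(c) for c in spec.column_names()]
    beta = fit.beta[idx]
    cov = fit.cov[np.ix_(idx, idx)]
    C = make_basis(grid, spec) - make_basis(np.array([ref]), spec)
    log_irr = C @ beta
    var = np.einsum("ij,jk,ik->i", C, cov, C)
    se = np.sqrt(np.clip(var, 0.0, None))
    zcrit = stats.norm.ppf(0.5 + level / 2)

    bins = np.arange(np.floor(map_values.min()), np.ceil(map_values.max()) + 1.0)
    counts, edges = np.histogram(map_values, bins=bins)
    return DoseResponseCurve(
        grid=grid,
        log_irr=log_irr,
        se=se,
        irr=np.exp(log_irr),
        irr_ci_low=np.exp(log_irr - zcrit * se),
        irr_ci_high=np.exp(log_irr + zcrit * se),
        reference=float(ref),
        rag_bins=edges[:-1],
        rag_counts=counts,
        extrapolated=(grid < lo - 1e-9) | (grid > hi + 1e-9),
    )


def knot_sensitivity(
    design: DesignMatrix,
    map_column: str = "map",
    knot_sets: list[list[float]] | None = None,
    adjust: list[str] | None = None,
) -> pd.DataFrame:
    """Refit the natural cubic spline under alternative interior-knot sets.

    Returns a table of AIC and estimated curve nadir per knot set; a knot set
    invalid for the data (e.g. outside the observed range) is recorded as an
    error row and the run continues.
    """
    mvals = design.X[:, design.names.index(map_column)]
    lo, hi = float(mvals.min()), float(mvals.max())
    if knot_sets is None:
        knot_sets = [
            default_spec(mvals, knot_rule="equal_spacing").interior_knots,
            default_spec(mvals, knot_rule="percentile").interior_knots,
        ]
    rows = []
    for ks in knot_sets:
        try:
            spec = SplineSpec(family="natural_cubic", interior_knots=list(ks),
                              boundary_knots=(lo, hi))
            spec.validate(mvals)
            fit = fit_clogit(_family_design(design, mvals, spec, adjust))
            rows.append({"knots": tuple(round(k, 3) for k in ks), "aic": fit.aic,
                         "nadir": curve_nadir(fit, spec, lo, hi), "error": ""})
        except Exception as exc:
            rows.append({"knots": tuple(round(k, 3) for k in ks), "aic": np.nan,
                         "nadir": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)
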