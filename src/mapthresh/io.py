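"""Dataset readers/writers, configuration, the baseline table, and the
end-to-end pipeline driver.

The matched dataset interchange format is a plain CSV (comma-separated,
UTF-8, mandatory header, empty field = missing, ``#`` comment lines allowed)
with one row per set member: ``set_id``, ``is_case`` (or ``role`` with
case/control labels), blood pressures and covariates.  MAP, pulse pressure
and the missing HbA1c unit are derived on read when absent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import matching as _matching
from .clogit import DesignMatrix, fit_clogit, vif, c_statistic
from .cohort import CohortConfig, generate_cohort, compute_map, hba1c_pct_to_mmol, hba1c_mmol_to_pct
from .sensitivity import (
    confounder_array,
    dichotomize_hba1c,
    exclude_early_cases,
    fit_interaction,
    restrict_range,
)
from .splines import default_spec, dose_response, fit_family, linearity_test
from .threshold import estimate_threshold

logger = logging.getLogger("mapthresh")

__all__ = [
    "SchemaError",
    "AnalysisConfig",
    "read_dataset",
    "write_dataset",
    "baseline_table",
    "build_design",
    "run_pipeline",
    "ADJUSTMENT_SETS",
]

# Default adjustment follows the figure captions (which add eGFR, smoking and
# pulse pressure to the methods-section list); the narrower methods-section
# set remains available by name.
ADJUSTMENT_SETS = {
    "figure": [
        "chd_history", "cerebrovascular_history", "diabetes_duration", "bmi",
        "tg", "tc", "ldl", "hdl", "egfr", "smoker", "lipid_tx", "aspirin",
        "pulse_pressure",
    ],
    "methods": [
        "bmi", "tg", "tc", "ldl", "hdl", "diabetes_duration", "lipid_tx",
        "aspirin", "chd_history", "cerebrovascular_history",
    ],
    "none": [],
}

CONTINUOUS_VARS = [
    "age", "sbp", "dbp", "map", "pulse_pressure", "hba1c_pct", "bmi", "tc",
    "tg", "hdl", "ldl", "egfr", "diabetes_duration",
]
CATEGORICAL_VARS = [
    "smoker", "lipid_tx", "aspirin", "chd_history", "cerebrovascular_history",
]


class SchemaError(ValueError):
    """Input file violates the documented schema; carries the full error list."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("dataset schema violations:\n  - " + "\n  - ".join(errors))


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce a run: simulation, matching, model and
    scan settings plus the single master seed."""

    seed: int = 0
    # simulation
    n_subjects: int = 20_000
    followup_days: float = 730.0
    cohort: dict = field(default_factory=dict)  # overrides for CohortConfig fields
    # matching
    window_start: float = 0.0
    window_end: float = 730.0
    ratio: int = 5
    age_caliper: float = 2.0
    # model
    adjustment: str = "figure"
    knot_rule: str = "equal_spacing"
    hba1c_cut_pct: float = 7.0
    # threshold scan
    p_lo: float = 5.0
    p_hi: float = 95.0
    scan_step: float = 1.0
    scan_alpha: float = 0.05
    n_boot: int = 1000
    ci_level: float = 95.0
    # sensitivity analyses
    rich_range: tuple[float, float] = (60.0, 120.0)
    narrow_range: tuple[float, float] = (80.0, 120.0)
    early_exclusion_days: float = 90.0
    confounder_prevalence_ratio: float = 1.5
    run_sensitivity: bool = True
    two_level_cstat: bool = True

    def cohort_config(self) -> CohortConfig:
        cfg = CohortConfig(
            n_subjects=self.n_subjects,
            seed=self.seed,
            followup_days=self.followup_days,
            hba1c_cut_pct=self.hba1c_cut_pct,
        )
        for k, v in self.cohort.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown cohort override {k!r}")
            setattr(cfg, k, v)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rich_range"] = list(d["rich_range"])
        d["narrow_range"] = list(d["narrow_range"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("rich_range", "narrow_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_dataset(frame: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a cohort or matched dataset CSV; the seed goes in a header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a matched dataset CSV.

    Validation is exhaustive: every schema violation found is reported in a
    single :class:`SchemaError` rather than failing on the first.  MAP and
    pulse pressure are derived from SBP/DBP when absent, and whichever HbA1c
    unit is missing is derived from the other via the IFCC-NGSP equation.
    """
    df = pd.read_csv(path, comment="#")
    errors: list[str] = []

    if "is_case" not in df.columns:
        if "role" in df.columns:
            roles = df["role"].astype(str).str.lower()
            bad = sorted(set(roles) - {"case", "control"})
            if bad:
                errors.append(f"role column has values other than case/control: {bad}")
            df["is_case"] = (roles == "case").astype(int)
        else:
            errors.append("missing column: is_case (or role)")
    if "set_id" not in df.columns:
        errors.append("missing column: set_id")

    have_bp = {"sbp", "dbp"} <= set(df.columns)
    if "map" not in df.columns and not have_bp:
        errors.append("need either a map column or both sbp and dbp")

    numeric_candidates = [c for c in df.columns if c not in ("sex", "role")]
    for c in numeric_candidates:
        coerced = pd.to_numeric(df[c], errors="coerce")
        n_bad = int((coerced.isna() & df[c].notna()).sum())
        if n_bad:
            errors.append(f"column {c!r}: {n_bad} non-numeric values")
        else:
            df[c] = coerced

    if have_bp and not any(e.startswith("column 'sbp'") or e.startswith("column 'dbp'")
                           for e in errors):
        n_inv = int((df["sbp"] < df["dbp"]).sum())
        if n_inv:
            errors.append(f"{n_inv} rows with SBP < DBP (invalid measurement)")

    if "set_id" in df.columns and "is_case" in df.columns and not errors:
        per_set = df.groupby("set_id")["is_case"].sum()
        bad = per_set[per_set != 1]
        if len(bad):
            errors.append(
                f"{len(bad)} sets without exactly one case (e.g. {bad.index[:5].tolist()})"
            )
        sizes = df.groupby("set_id").size()
        small = sizes[sizes < 2]
        if len(small):
            errors.append(f"{len(small)} sets with fewer than 2 members")

    if not ({"hba1c_pct", "hba1c_mmol"} & set(df.columns)):
        errors.append("missing HbA1c column (hba1c_pct or hba1c_mmol)")

    if errors:
        raise SchemaError(errors)

    if "map" not in df.columns:
        df["map"] = compute_map(df["sbp"].to_numpy(), df["dbp"].to_numpy())
    if "pulse_pressure" not in df.columns and have_bp:
        df["pulse_pressure"] = df["sbp"] - df["dbp"]
    if "hba1c_pct" not in df.columns:
        df["hba1c_pct"] = hba1c_mmol_to_pct(df["hba1c_mmol"].to_numpy())
    if "hba1c_mmol" not in df.columns:
        df["hba1c_mmol"] = hba1c_pct_to_mmol(df["hba1c_pct"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# baseline descriptive table
# ---------------------------------------------------------------------------

def baseline_table(matched: pd.DataFrame,
                   continuous: list[str] | None = None,
                   categorical: list[str] | None = None) -> pd.DataFrame:
    """Case/control descriptive comparisons on the matched dataset.

    Continuous variables: mean +/- SD per group, p-value from a linear model
    with a random intercept per matched set (REML).  Categorical variables:
    per-group %, p-value from a univariate conditional-logistic Wald test.
    Variables that are constant everywhere are flagged rather than tested.
    """
    import statsmodels.api as sm

    continuous = [v for v in (continuous or CONTINUOUS_VARS) if v in matched.columns]
    categorical = [v for v in (categorical or CATEGORICAL_VARS) if v in matched.columns]
    is_case = matched["is_case"].astype(bool)
    rows = []
    for var in continuous:
        x = matched[var].astype(float)
        if x.isna().all():
            rows.append({"variable": var, "type": "continuous", "note": "all missing"})
            continue
        entry = {
            "variable": var, "type": "continuous",
            "cases": f"{x[is_case].mean():.1f} ± {x[is_case].std():.1f}",
            "controls": f"{x[~is_case].mean():.1f} ± {x[~is_case].std():.1f}",
        }
        if x.std() == 0:
            entry["note"] = "constant; comparison undefined"
        else:
            try:
                import warnings as _warnings

                md = sm.MixedLM(
                    x.to_numpy(),
                    sm.add_constant(matched["is_case"].to_numpy(dtype=float)),
                    groups=matched["set_id"].to_numpy(),
                )
                with _warnings.catch_warnings():
                    # matched sets often leave ~zero between-set variance for a
                    # covariate; the boundary fit is fine for the Wald p-value
                    _warnings.simplefilter("ignore")
                    fit = md.fit(reml=True, method="lbfgs", disp=False)
                entry["p"] = float(fit.pvalues[1])
            except Exception as exc:
                entry["note"] = f"mixed model failed: {exc}"
        rows.append(entry)
    for var in categorical:
        x = matched[var].astype(float)
        entry = {
            "variable": var, "type": "categorical",
            "cases": f"{100 * x[is_case].mean():.1f}%",
            "controls": f"{100 * x[~is_case].mean():.1f}%",
        }
        if x.nunique() < 2:
            entry["note"] = "constant; comparison undefined"
        else:
            try:
                d = DesignMatrix(
                    strata=matched["set_id"].to_numpy(),
                    y=matched["is_case"].to_numpy(),
                    X=x.to_numpy()[:, None],
                    names=[var],
                )
                fit = fit_clogit(d)
                se = fit.se[0]
                from scipy import stats as _st
                entry["p"] = float(2 * _st.norm.sf(abs(fit.beta[0] / se))) if se > 0 else np.nan
            except Exception as exc:
                entry["note"] = f"conditional logit failed: {exc}"
        rows.append(entry)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def build_design(matched: pd.DataFrame, adjustment: str | list[str] = "figure",
                 hba1c_cut_pct: float = 7.0) -> DesignMatrix:
    """Design matrix with MAP, the HbA1c group indicator and adjustment columns."""
    adjust = ADJUSTMENT_SETS[adjustment] if isinstance(adjustment, str) else list(adjustment)
    hba1c_high = dichotomize_hba1c(matched["hba1c_pct"].to_numpy(), cut_pct=hba1c_cut_pct,
                                   unit="pct")
    cols = ["map"] + [a for a in adjust if a in matched.columns]
    X = np.column_stack([matched[cols].to_numpy(dtype=float), hba1c_high[:, None]])
    return DesignMatrix(
        strata=matched["set_id"].to_numpy(),
        y=matched["is_case"].to_numpy(),
        X=X,
        names=cols + ["hba1c_high"],
    )


def _analyse_matched(matched: pd.DataFrame, config: AnalysisConfig,
                     n_boot: int | None = None, rng=None) -> dict:
    """Model fitting, linearity, threshold and interaction on one matched frame."""
    adjust_names = [a for a in ADJUSTMENT_SETS[config.adjustment] if a in matched.columns]
    design = build_design(matched, config.adjustment, config.hba1c_cut_pct)
    fam = fit_family(design, families=("linear", "natural_cubic", "quadratic"),
                     adjust=adjust_names, knot_rule=config.knot_rule)
    lin = linearity_test(design, adjust=adjust_names)
    boot = config.n_boot if n_boot is None else n_boot
    est = estimate_threshold(
        design, adjust=adjust_names, n_boot=boot, level=config.ci_level,
        seed=rng if rng is not None else config.seed + 1,
        alpha=config.scan_alpha, p_lo=config.p_lo, p_hi=config.p_hi, step=config.scan_step,
    )
    theta = est.threshold if est.threshold is not None else float(np.median(matched["map"]))
    inter = fit_interaction(design, threshold=theta, adjust=adjust_names)
    spec = fam["specs"][fam["selected"]] if fam["selected"] != "linear" else fam["specs"]["natural_cubic"]
    curve = dose_response(fam["fits"][fam["selected"] if fam["selected"] != "linear"
                                      else "natural_cubic"], spec, matched["map"].to_numpy())
    return {
        "design": design, "family": fam, "linearity": lin, "threshold": est,
        "interaction": inter, "curve": curve, "adjust": adjust_names,
    }


def run_pipeline(config: AnalysisConfig, out_dir=None) -> dict:
    """simulate -> match -> baseline table -> family fit -> linearity ->
    threshold scan + bootstrap -> interaction -> sensitivity analyses.

    Returns the full result bundle; when ``out_dir`` is given every artefact
    is also written there (CSV tables + JSON reports embedding the config
    and its hash).  Stage failures are isolated: a failing sensitivity stage
    is reported without aborting the stages that do not depend on it.
    """
    rng = np.random.default_rng(config.seed)
    cohort = generate_cohort(config.cohort_config())
    cases = _matching.identify_cases(cohort, config.window_start, config.window_end)
    sets, match_report = _matching.risk_set_sample(
        cohort, cases, ratio=config.ratio, age_caliper=config.age_caliper, seed=rng
    )
    matched = _matching.matched_frame(cohort, sets)
    logger.info("matched %d sets (achieved ratio %.2f)",
                match_report["sets_formed"], match_report["achieved_ratio"])

    baseline = baseline_table(matched)
    main = _analyse_matched(matched, config, rng=rng)

    design = main["design"]
    diag = {"vif": vif(design)}
    diag["c_statistic_within_set"] = c_statistic(design, fit_clogit(design),
                                                 method="within_set")
    if config.two_level_cstat:
        diag["c_statistic_two_level"] = c_statistic(design, fit_clogit(design),
                                                    method="two_level")

    # observed IRR for the bias array: contrast 10 mmHg below the threshold vs
    # the threshold, from the pooled (no-interaction) segmented slope
    inter = main["interaction"]
    # simple mean of the two group slopes as the pooled below-threshold slope
    pooled_below = 0.5 * (inter.slope_below_low + inter.slope_below_high)
    observed_irr = float(np.exp(10.0 * pooled_below))
    conf = confounder_array(observed_irr, f=config.confounder_prevalence_ratio)

    results = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "match_report": match_report,
        "design": design,
        "matched": matched,
        "n_sets": int(matched["set_id"].nunique()),
        "baseline_table": baseline,
        "aic_table": main["family"]["aic_table"],
        "selected_family": main["family"]["selected"],
        "linearity_p": main["linearity"]["p"],
        "threshold": main["threshold"],
        "interaction": inter,
        "curve": main["curve"],
        "diagnostics": diag,
        "confounder": conf,
        "sensitivity": {},
        "errors": {},
    }

    if config.run_sensitivity:
        for name, fn in {
            "rich_range": lambda: restrict_range(matched, *config.rich_range),
            "narrow_range": lambda: restrict_range(matched, *config.narrow_range),
            "early_exclusion": lambda: exclude_early_cases(matched,
                                                           config.early_exclusion_days),
        }.items():
            try:
                sub, rep = fn()
                res = _analyse_matched(sub, config, n_boot=0, rng=rng)
                results["sensitivity"][name] = {
                    "report": rep,
                    "linearity_p": res["linearity"]["p"],
                    "threshold": res["threshold"].to_dict(),
                    "interaction": res["interaction"].to_dict(),
                }
            except Exception as exc:
                logger.warning("sensitivity stage %s failed: %s", name, exc)
                results["errors"][name] = str(exc)

    if out_dir is not None:
        _write_bundle(results, matched, out_dir, config)
    return results


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_bundle(results: dict, matched: pd.DataFrame, out_dir, config: AnalysisConfig):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_dataset(matched, out / "matched.csv", seed=config.seed)
    results["baseline_table"].to_csv(out / "baseline_table.csv", index=False)
    results["aic_table"].to_csv(out / "aic_table.csv", index=False)
    est = results["threshold"]
    est.scan.to_csv(out / "threshold_scan.csv", index=False)
    if len(est.bootstrap_thresholds):
        pd.DataFrame({"threshold": est.bootstrap_thresholds}).to_csv(
            out / "bootstrap_thresholds.csv", index=False
        )
    curve = results["curve"]
    cf = curve.to_frame()
    rag = pd.DataFrame({"bin_left": curve.rag_bins, "count": curve.rag_counts})
    cf.to_csv(out / "dose_response.csv", index=False)
    rag.to_csv(out / "rag_counts.csv", index=False)
    results["confounder"].to_frame().to_csv(out / "confounder_grid.csv", index=False)

    report = {
        "config": results["config"],
        "config_hash": results["config_hash"],
        "match_report": results["match_report"],
        "n_sets": results["n_sets"],
        "selected_family": results["selected_family"],
        "linearity_p": results["linearity_p"],
        "threshold": est.to_dict(),
        "interaction": results["interaction"].to_dict(),
        "diagnostics": {
            "vif_mean": results["diagnostics"]["vif"]["mean_vif"],
            "vif_per_column": results["diagnostics"]["vif"]["per_column"],
            "c_statistic_within_set": results["diagnostics"]["c_statistic_within_set"],
            "c_statistic_two_level": results["diagnostics"].get("c_statistic_two_level"),
        },
        "confounder": {
            "observed_irr": results["confounder"].observed_irr,
            "prevalence_ratio": results["confounder"].prevalence_ratio,
            "required_factor_by_p0": dict(
                zip(map(float, results["confounder"].p0_grid),
                    map(float, results["confounder"].required_factor))
            ),
        },
        "sensitivity": results["sensitivity"],
        "errors": results["errors"],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, default=str)
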