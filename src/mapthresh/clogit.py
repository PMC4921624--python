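"""Conditional logistic regression for 1:m matched sets.

The conditional likelihood for a matched set with one case and m controls is

    L_s(beta) = exp(x_case . beta) / sum_{j in set} exp(x_j . beta),

so the stratum-level baseline risk cancels and only within-set covariate
contrasts are informative.  Under risk-set sampling of controls the fitted
odds ratios estimate incidence rate ratios.

The maximiser is Newton-Raphson with analytic gradient and Hessian and
step-halving; all per-set reductions are vectorised with ``np.*.reduceat``
over strata-sorted rows, so fits stay fast even inside bootstrap loops.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("mapthresh")

__all__ = [
    "DesignMatrix",
    "FitResult",
    "ClogitError",
    "SingularHessianError",
    "conditional_loglik",
    "fit_clogit",
    "lrt",
    "wald_test",
    "aic",
    "vif",
    "c_statistic",
]


class ClogitError(ValueError):
    """Invalid design or fit request."""


class SingularHessianError(ClogitError):
    """Hessian is singular; names the offending (collinear) columns."""


@dataclass
class DesignMatrix:
    """Strata + case indicator + named covariate columns for the conditional likelihood.

    Rows are re-ordered on construction so each stratum is contiguous
    (required by the reduceat-based likelihood).  Validation enforces exactly
    one case per stratum and at least two rows per stratum; columns that are
    constant within every stratum carry no information under conditioning and
    are dropped with a warning.
    """

    strata: np.ndarray
    y: np.ndarray
    X: np.ndarray
    names: list[str]
    # row offsets of each stratum after sorting, for reduceat
    starts: np.ndarray = field(init=False, repr=False)
    counts: np.ndarray = field(init=False, repr=False)
    set_index: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.strata = np.asarray(self.strata)
        self.y = np.asarray(self.y, dtype=np.int8)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.strata.shape[0] or self.y.shape[0] != self.strata.shape[0]:
            raise ClogitError("strata, y and X must have the same number of rows")
        if not np.all(np.isfinite(self.X)):
            raise ClogitError("non-finite covariate values in design matrix")
        if len(self.names) != self.X.shape[1]:
            raise ClogitError("number of column names must match X")

        # stable sort by stratum so sets are contiguous
        order = np.argsort(self.strata, kind="stable")
        self.strata = self.strata[order]
        self.y = self.y[order]
        self.X = self.X[order]

        uniq, self.set_index, self.counts = np.unique(
            self.strata, return_inverse=True, return_counts=True
        )
        self.starts = np.concatenate([[0], np.cumsum(self.counts)[:-1]])

        cases_per_set = np.bincount(self.set_index, weights=self.y)
        if np.any(cases_per_set != 1):
            bad = uniq[cases_per_set != 1]
            raise ClogitError(
                f"each stratum must contain exactly one case; violated by strata {bad[:10].tolist()}"
            )
        if np.any(self.counts < 2):
            bad = uniq[self.counts < 2]
            raise ClogitError(
                f"each stratum needs at least 2 rows (1 case + >=1 control); violated by {bad[:10].tolist()}"
            )

        keep = [j for j in range(self.X.shape[1]) if not self._constant_within_strata(j)]
        if len(keep) < self.X.shape[1]:
            dropped = [self.names[j] for j in range(self.X.shape[1]) if j not in keep]
            warnings.warn(
                f"columns constant within every stratum carry no information and were dropped: {dropped}",
                UserWarning,
                stacklevel=2,
            )
            self.X = self.X[:, keep]
            self.names = [self.names[j] for j in keep]

    def _constant_within_strata(self, j: int) -> bool:
        col = self.X[:, j]
        mins = np.minimum.reduceat(col, self.starts)
        maxs = np.maximum.reduceat(col, self.starts)
        return bool(np.all(maxs - mins == 0))

    # ---- convenience -------------------------------------------------
    @property
    def n_sets(self) -> int:
        return len(self.starts)

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        strata: str = "set_id",
        outcome: str = "is_case",
        columns: list[str] | None = None,
    ) -> "DesignMatrix":
        if columns is None:
            columns = [c for c in df.columns if c not in (strata, outcome)]
        return cls(
            strata=df[strata].to_numpy(),
            y=df[outcome].to_numpy(),
            X=df[columns].to_numpy(dtype=float),
            names=list(columns),
        )

    def with_columns(self, extra: np.ndarray, extra_names: list[str]) -> "DesignMatrix":
        """New design with additional columns (rows already in this design's order)."""
        extra = np.atleast_2d(np.asarray(extra, dtype=float))
        if extra.shape[0] != self.X.shape[0]:
            extra = extra.T
        return DesignMatrix(
            strata=self.strata.copy(),
            y=self.y.copy(),
            X=np.column_stack([self.X, extra]),
            names=self.names + list(extra_names),
        )

    @classmethod
    def _prevalidated(cls, strata, y, X, names, starts, counts, set_index) -> "DesignMatrix":
        """Construct without re-sorting/validation; internal fast path for
        hot loops (threshold scan, bootstrap) where the invariants are
        inherited from an already-validated design."""
        obj = object.__new__(cls)
        obj.strata, obj.y, obj.X, obj.names = strata, y, X, names
        obj.starts, obj.counts, obj.set_index = starts, counts, set_index
        return obj

    def with_column_fast(self, col: np.ndarray, name: str) -> "DesignMatrix":
        """Append one column without revalidating (rows must match this design)."""
        return DesignMatrix._prevalidated(
            self.strata, self.y, np.column_stack([self.X, col]),
            self.names + [name], self.starts, self.counts, self.set_index,
        )

    def subset_sets(self, set_positions: np.ndarray) -> "DesignMatrix":
        """Design restricted to the given stratum positions (with multiplicity).

        Used by the set-level bootstrap: positions may repeat; each draw
        becomes a fresh stratum label so duplicated sets stay distinct.
        """
        pos = np.asarray(set_positions)
        counts = self.counts[pos]
        total = int(counts.sum())
        new_starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        within = np.arange(total) - np.repeat(new_starts, counts)
        rows = np.repeat(self.starts[pos], counts) + within
        strata = np.repeat(np.arange(len(pos)), counts)
        return DesignMatrix._prevalidated(
            strata, self.y[rows], self.X[rows], list(self.names),
            new_starts, counts, strata,
        )


@dataclass
class FitResult:
    """Maximum conditional likelihood estimate with covariance and fit metadata."""

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    aic: float
    n_sets: int
    n_iter: int
    converged: bool
    names: list[str]
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def summary(self) -> pd.DataFrame:
        se = self.se
        z = np.divide(self.beta, se, out=np.full_like(self.beta, np.nan), where=se > 0)
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": se,
                "z": z,
                "p": p,
                "or": np.exp(self.beta),
                "or_ci_low": np.exp(self.beta - 1.959963984540054 * se),
                "or_ci_high": np.exp(self.beta + 1.959963984540054 * se),
            },
            index=self.names,
        )


# ---------------------------------------------------------------------------
# likelihood, score, information
# ---------------------------------------------------------------------------

def _eta_parts(beta: np.ndarray, design: DesignMatrix):
    """Per-row conditional probabilities and per-set log-denominators."""
    eta = design.X @ beta
    set_max = np.maximum.reduceat(eta, design.starts)
    z = np.exp(eta - set_max[design.set_index])
    denom = np.add.reduceat(z, design.starts)
    p = z / denom[design.set_index]
    log_denom = np.log(denom) + set_max
    return eta, p, log_denom


def conditional_loglik(beta: np.ndarray, design: DesignMatrix) -> float:
    """Conditional log-likelihood sum_s [x_case.beta - log sum_j exp(x_j.beta)].

    A per-set maximum is subtracted before exponentiation for overflow safety.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != design.n_params:
        raise ClogitError(
            f"beta has length {beta.shape[0]}, design has {design.n_params} columns"
        )
    eta, _, log_denom = _eta_parts(beta, design)
    return float(eta[design.y == 1].sum() - log_denom.sum())


def _score_hessian(beta: np.ndarray, design: DesignMatrix, with_ll: bool = False):
    eta, p, log_denom = _eta_parts(beta, design)
    pX = p[:, None] * design.X
    mu = np.add.reduceat(pX, design.starts, axis=0)  # per-set E[x]
    score = design.X[design.y == 1].sum(axis=0) - mu.sum(axis=0)
    # observed information: sum_s (E[xx'] - E[x]E[x]')
    info = pX.T @ design.X - mu.T @ mu
    if with_ll:
        return float(eta[design.y == 1].sum() - log_denom.sum()), score, info
    return score, info


def fit_clogit(
    design: DesignMatrix,
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 50,
    beta0: np.ndarray | None = None,
) -> FitResult:
    """Newton-Raphson maximiser of the conditional likelihood.

    Convergence: max |score| < ``tol``.  ``cov`` is the inverse observed
    information at the optimum.  Monotone likelihood (separation) is detected
    via a diverging coefficient norm and flagged ``converged=False`` rather
    than raised; a singular information matrix raises
    :class:`SingularHessianError` naming the collinear columns.
    """
    k = design.n_params
    if k == 0:
        raise ClogitError(
            "zero information: no columns vary within strata (all-concordant sets)"
        )
    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float).copy()

    # within-stratum spread per column; |beta_j| * spread_j is the log-odds
    # range the column can span inside a set, so a huge value flags monotone
    # likelihood (separation) rather than a genuine optimum
    set_means = np.add.reduceat(design.X, design.starts, axis=0) / design.counts[:, None]
    Xc = design.X - set_means[design.set_index]
    col_scale = np.sqrt((Xc**2).mean(axis=0))
    col_scale[col_scale == 0] = 1.0
    diverged = False
    n_iter = 0
    ll = -np.inf
    for n_iter in range(1, max_iter + 1):
        ll, score, info = _score_hessian(beta, design, with_ll=True)
        ll -= 0.5 * ridge * beta @ beta
        if ridge > 0:
            score = score - ridge * beta
            info = info + ridge * np.eye(k)
        if np.max(np.abs(score)) < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = None
        if step is None or not np.all(np.isfinite(step)):
            _raise_singular(design, info)
        # step-halving on likelihood decrease
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            ll_new = conditional_loglik(cand, design) - 0.5 * ridge * cand @ cand
            if ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        beta, ll = beta + lam * step, ll_new
        if np.max(np.abs(beta) * col_scale) > 10.0:
            diverged = True
            break
    else:
        n_iter = max_iter

    score, info = _score_hessian(beta, design)
    if ridge > 0:
        info = info + ridge * np.eye(k)
    converged = (np.max(np.abs(score)) < max(tol, 1e-6)) and not diverged
    message = ""
    if diverged:
        message = (
            "coefficients diverging: monotone likelihood (separation) suspected; "
            "consider a ridge penalty or collapsing the separating covariate"
        )
    elif not converged:
        # fall back to quasi-Newton from the current point
        res = optimize.minimize(
            lambda b: -conditional_loglik(b, design) + 0.5 * ridge * b @ b,
            beta,
            jac=lambda b: -(_score_hessian(b, design)[0] - ridge * b),
            method="BFGS",
            options={"gtol": max(tol, 1e-8), "maxiter": 200},
        )
        beta = res.x
        score, info = _score_hessian(beta, design)
        if ridge > 0:
            info = info + ridge * np.eye(k)
        converged = np.max(np.abs(score)) < max(tol, 1e-6)
        message = "" if converged else "quasi-Newton fallback did not reach score tolerance"

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        if converged:
            _raise_singular(design, info)
        cov = np.linalg.pinv(info)

    ll = conditional_loglik(beta, design)
    return FitResult(
        beta=beta,
        cov=cov,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        n_sets=design.n_sets,
        n_iter=n_iter,
        converged=converged,
        names=list(design.names),
        message=message,
    )


def _raise_singular(design: DesignMatrix, info: np.ndarray):
    # name the columns in the (near-)null space of the information matrix
    w, v = np.linalg.eigh((info + info.T) / 2.0)
    thresh = max(w.max(), 1.0) * 1e-10
    bad = set()
    for i in np.where(w <= thresh)[0]:
        for j in np.argsort(-np.abs(v[:, i]))[:2]:
            bad.add(design.names[j])
    raise SingularHessianError(
        f"singular information matrix; collinear or empty columns: {sorted(bad)}"
    )


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------

def lrt(full: FitResult, reduced: FitResult) -> dict:
    """Likelihood-ratio test of a reduced model nested in a full model."""
    if not set(reduced.names) <= set(full.names):
        raise ClogitError(
            f"models are not nested: {set(reduced.names) - set(full.names)} not in full model"
        )
    df = len(full.names) - len(reduced.names)
    statistic = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(statistic, df))
    return {"statistic": statistic, "df": df, "p": p}


def wald_test(fit: FitResult, column: str) -> dict:
    """Wald z-test for a single coefficient."""
    j = fit.names.index(column)
    se = fit.se[j]
    z = fit.beta[j] / se if se > 0 else np.nan
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan}


def wald_joint(fit: FitResult, columns: list[str]) -> dict:
    """Joint Wald chi-square test that a set of coefficients is zero."""
    idx = [fit.names.index(c) for c in columns]
    b = fit.beta[idx]
    V = fit.cov[np.ix_(idx, idx)]
    statistic = float(b @ np.linalg.solve(V, b))
    return {"statistic": statistic, "df": len(idx), "p": float(stats.chi2.sf(statistic, len(idx)))}


def aic(fit: FitResult) -> float:
    """Akaike information criterion, -2*loglik + 2*k."""
    return -2.0 * fit.loglik + 2.0 * len(fit.names)


def vif(design: DesignMatrix) -> dict:
    """Variance inflation factors after within-stratum centring.

    Each covariate is regressed on the others on the pooled, within-set
    centred data; VIF_j = 1/(1 - R^2_j).  A perfectly collinear column gets
    VIF = inf and is named in the report.
    """
    if design.n_params < 2:
        raise ClogitError("VIF needs at least two columns")
    X = design.X
    means = np.add.reduceat(X, design.starts, axis=0) / design.counts[:, None]
    Xc = X - means[design.set_index]
    out = {}
    for j, name in enumerate(design.names):
        yj = Xc[:, j]
        Zj = Xc[:, [i for i in range(X.shape[1]) if i != j]]
        ss_tot = float(yj @ yj)
        if ss_tot == 0:
            out[name] = np.inf
            continue
        coef, _, _, _ = np.linalg.lstsq(Zj, yj, rcond=None)
        resid = yj - Zj @ coef
        r2 = 1.0 - float(resid @ resid) / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    finite = [v for v in out.values() if np.isfinite(v)]
    infinite = sorted(n for n, v in out.items() if not np.isfinite(v))
    if infinite:
        logger.warning("perfectly collinear columns with infinite VIF: %s", infinite)
    return {
        "per_column": out,
        "mean_vif": float(np.mean(finite)) if finite else np.inf,
        "infinite": infinite,
    }


# ---------------------------------------------------------------------------
# discrimination (C-statistic)
# ---------------------------------------------------------------------------

def _pairwise_auc(scores_case: np.ndarray, scores_ctrl: np.ndarray) -> float:
    """Mann-Whitney AUC over all case x control pairs; ties count 0.5."""
    diff = scores_case[:, None] - scores_ctrl[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def _within_set_auc(design: DesignMatrix, eta: np.ndarray) -> float:
    """Concordance over within-stratum case-control pairs only."""
    conc = 0.0
    total = 0
    for s, c in zip(design.starts, design.counts):
        rows = slice(s, s + c)
        e = eta[rows]
        y = design.y[rows]
        ec = e[y == 1][0]
        ectrl = e[y == 0]
        conc += np.sum(ec > ectrl) + 0.5 * np.sum(ec == ectrl)
        total += ectrl.size
    return float(conc / total)


def _fit_random_intercept_logit(design: DesignMatrix, n_nodes: int = 15):
    """ML fit of a two-level logistic model (random intercept per matched set)
    by adaptive-free Gauss-Hermite quadrature of the integrated likelihood."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    b_scale = np.sqrt(2.0) * nodes  # integration abscissae for N(0,1)
    w = weights / np.sqrt(np.pi)

    X = design.X
    y01 = design.y.astype(float)
    starts, set_index = design.starts, design.set_index

    def negll(theta):
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        eta = X @ beta
        # per-row log bernoulli at each node: (n, q)
        lin = eta[:, None] + sigma * b_scale[None, :]
        logp = y01[:, None] * lin - np.logaddexp(0.0, lin)
        set_logp = np.add.reduceat(logp, starts, axis=0)  # (S, q)
        m = set_logp.max(axis=1, keepdims=True)
        lik = np.log((np.exp(set_logp - m) * w[None, :]).sum(axis=1)) + m[:, 0]
        return -float(lik.sum())

    k = design.n_params
    start_beta = fit_clogit(design).beta
    theta0 = np.concatenate([start_beta, [np.log(0.5)]])
    res = optimize.minimize(negll, theta0, method="Nelder-Mead" if k <= 2 else "Powell",
                            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8}
                            if k <= 2 else {"maxiter": 8000})
    if not res.success:
        res2 = optimize.minimize(negll, theta0, method="BFGS", options={"maxiter": 500})
        if res2.fun < res.fun:
            res = res2
    beta, sigma = res.x[:-1], float(np.exp(res.x[-1]))
    # marginal predicted probability integrates the random intercept out
    lin = (X @ beta)[:, None] + sigma * b_scale[None, :]
    marg_p = (w[None, :] / (1.0 + np.exp(-lin))).sum(axis=1)
    return marg_p, beta, sigma, bool(res.success)


def c_statistic(design: DesignMatrix, fit: FitResult, method: str = "two_level") -> dict:
    """C-statistic (area under the ROC curve) for the matched analysis.

    ``two_level``: refit a random-intercept (per matched set) logistic model by
    Gauss-Hermite quadrature and compute the AUC of the marginal predicted
    probabilities against case status over all case-control pairs.  If the
    quadrature fit fails, falls back to ``within_set`` with a logged warning.

    ``within_set``: concordance of the conditional-logistic linear predictor
    over within-stratum case-control pairs.
    """
    eta = design.X @ fit.beta
    if method == "within_set":
        return {"auc": _within_set_auc(design, eta), "method": "within_set"}
    if method != "two_level":
        raise ClogitError(f"unknown C-statistic method {method!r}")
    try:
        marg_p, beta2, sigma, ok = _fit_random_intercept_logit(design)
        if not ok:
            raise RuntimeError("quadrature optimiser did not converge")
    except Exception as exc:  # pragma: no cover - defensive fallback
        logger.warning("two-level C-statistic failed (%s); falling back to within-set", exc)
        return {"auc": _within_set_auc(design, eta), "method": "within_set_fallback"}
    auc = _pairwise_auc(marg_p[design.y == 1], marg_p[design.y == 0])
    return {"auc": auc, "method": "two_level", "sigma_u": sigma}
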