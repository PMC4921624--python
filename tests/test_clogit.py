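"""Conditional-likelihood core: closed forms, oracle equivalence, inference."""

import numpy as np
import pytest
from scipy import stats

import mapthresh as mt
from mapthresh.clogit import (
    ClogitError,
    SingularHessianError,
    _pairwise_auc,
    wald_joint,
)
from .conftest import design_from_frame


def brute_force_loglik(beta, design):
    """Term-by-term enumeration of each set's denominator (independent oracle)."""
    total = 0.0
    for s in np.unique(design.strata):
        rows = np.where(design.strata == s)[0]
        case = rows[design.y[rows] == 1][0]
        num = np.exp(design.X[case] @ beta)
        den = sum(np.exp(design.X[r] @ beta) for r in rows)
        total += np.log(num / den)
    return total


class TestConditionalLoglik:
    def test_uniform_probabilities_at_zero_beta(self):
        strata = np.repeat(np.arange(4), 6)
        y = np.tile([1, 0, 0, 0, 0, 0], 4)
        d = mt.DesignMatrix(strata=strata, y=y, X=np.random.default_rng(0).normal(size=(24, 2)),
                            names=["a", "b"])
        assert mt.conditional_loglik(np.zeros(2), d) == pytest.approx(-4 * np.log(6))

    def test_single_pair_closed_form(self):
        d = mt.DesignMatrix(strata=[0, 0], y=[1, 0], X=np.array([[1.0], [0.0]]), names=["x"])
        beta = np.log(2.0)
        assert mt.conditional_loglik(np.array([beta]), d) == pytest.approx(np.log(2 / 3))

    def test_matches_brute_force_on_random_designs(self):
        """Oracle equivalence on all small designs (<=5 sets x <=6 members)."""
        rng = np.random.default_rng(7)
        for trial in range(25):
            n_sets = rng.integers(1, 6)
            sizes = rng.integers(2, 7, size=n_sets)
            strata = np.repeat(np.arange(n_sets), sizes)
            y = np.concatenate([np.eye(1, s, rng.integers(0, s)).ravel() for s in sizes])
            k = rng.integers(1, 4)
            X = rng.normal(size=(len(strata), k))
            d = mt.DesignMatrix(strata=strata, y=y, X=X, names=[f"c{i}" for i in range(k)])
            beta = rng.normal(size=d.n_params)
            assert mt.conditional_loglik(beta, d) == pytest.approx(
                brute_force_loglik(beta, d), abs=1e-10
            )

    def test_rejects_bad_inputs(self):
        d = mt.DesignMatrix(strata=[0, 0], y=[1, 0], X=np.array([[1.0], [0.0]]), names=["x"])
        with pytest.raises(ClogitError):
            mt.conditional_loglik(np.zeros(2), d)
        with pytest.raises(ClogitError, match="non-finite"):
            mt.DesignMatrix(strata=[0, 0], y=[1, 0], X=np.array([[np.inf], [0.0]]), names=["x"])

    def test_design_validation(self):
        with pytest.raises(ClogitError, match="exactly one case"):
            mt.DesignMatrix(strata=[0, 0, 1, 1], y=[1, 1, 1, 0],
                            X=np.ones((4, 1)), names=["x"])
        with pytest.raises(ClogitError, match="at least 2 rows"):
            mt.DesignMatrix(strata=[0, 1, 1], y=[1, 1, 0], X=np.ones((3, 1)), names=["x"])


class TestFitClogit:
    def test_matched_pair_closed_form(self, pairs_design):
        """beta-hat = ln(n10/n01) for 1:1 pairs with a binary exposure."""
        fit = mt.fit_clogit(pairs_design)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(np.log(10 / 5), abs=1e-8)
        # grid search on the likelihood confirms the optimum
        grid = np.linspace(0.3, 1.1, 401)
        lls = [mt.conditional_loglik(np.array([b]), pairs_design) for b in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(np.log(2.0), abs=2e-3)

    def test_all_concordant_zero_information(self):
        strata = np.repeat(np.arange(5), 2)
        y = np.tile([1, 0], 5)
        x = np.repeat(np.arange(5.0), 2)  # same value within each pair
        with pytest.warns(UserWarning, match="dropped"):
            d = mt.DesignMatrix(strata=strata, y=y, X=x[:, None], names=["x"])
        with pytest.raises(ClogitError, match="zero information"):
            mt.fit_clogit(d)

    def test_separation_flagged(self):
        strata = np.repeat(np.arange(8), 2)
        y = np.tile([1, 0], 8)
        x = np.tile([1.0, 0.0], 8)  # every case exposed, no control exposed
        fit = mt.fit_clogit(mt.DesignMatrix(strata=strata, y=y, X=x[:, None], names=["x"]))
        assert not fit.converged
        assert "separation" in fit.message

    def test_collinear_columns_named(self, small_random_design):
        d = small_random_design.with_columns(small_random_design.X[:, [0]], ["a_copy"])
        with pytest.raises(SingularHessianError, match="a"):
            mt.fit_clogit(d)

    def test_stratum_shift_invariance(self, hinge_sets):
        """Adding a per-stratum constant to any covariate leaves the
        conditional fit unchanged."""
        df = hinge_sets.iloc[: 6 * 200].copy()
        d = design_from_frame(df, cols=("map", "hba1c_high"))
        fit = mt.fit_clogit(d)
        shifts = np.random.default_rng(3).normal(scale=30.0, size=d.n_sets)
        X2 = d.X.copy()
        X2[:, 0] = X2[:, 0] + shifts[d.set_index]
        d2 = mt.DesignMatrix(strata=d.strata, y=d.y, X=X2, names=d.names)
        fit2 = mt.fit_clogit(d2)
        assert fit2.beta == pytest.approx(fit.beta, abs=1e-8)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-8)

    def test_agrees_with_statsmodels(self, hinge_sets):
        """Independent cross-check against statsmodels' conditional logit."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        df = hinge_sets.iloc[: 6 * 150]
        d = design_from_frame(df, cols=("map", "hba1c_high"))
        fit = mt.fit_clogit(d)
        sm_fit = ConditionalLogit(d.y, d.X, groups=d.strata).fit(method="newton", disp=False)
        assert fit.beta == pytest.approx(np.asarray(sm_fit.params), abs=1e-5)
        assert fit.se == pytest.approx(np.asarray(sm_fit.bse), rel=1e-3)
        assert fit.loglik == pytest.approx(float(sm_fit.llf), abs=1e-6)

    def test_consistency_linear_regime(self):
        """Known log-RR 0.03/mmHg: mean estimate over 100 replicates within
        2 Monte-Carlo SE."""
        cfg = mt.CohortConfig(effect_shape="linear", linear_slope=0.03)
        betas = []
        for r in range(100):
            df = mt.simulate_matched_sets(300, 5, config=cfg, seed=r)
            betas.append(mt.fit_clogit(design_from_frame(df)).beta[0])
        betas = np.asarray(betas)
        mcse = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - 0.03) < 2 * mcse


class TestInference:
    def test_aic_formula(self):
        fit = mt.FitResult(beta=np.zeros(3), cov=np.eye(3), loglik=-100.0,
                           aic=206.0, n_sets=10, n_iter=1, converged=True,
                           names=["a", "b", "c"])
        assert mt.aic(fit) == 206.0

    def test_lrt_identical_models(self, pairs_design):
        fit = mt.fit_clogit(pairs_design)
        res = mt.lrt(fit, fit)
        assert res["statistic"] == 0.0 and res["p"] == 1.0

    def test_lrt_rejects_non_nested(self, pairs_design):
        fit = mt.fit_clogit(pairs_design)
        other = mt.FitResult(beta=np.zeros(1), cov=np.eye(1), loglik=-1.0, aic=4.0,
                             n_sets=15, n_iter=1, converged=True, names=["elsewhere"])
        with pytest.raises(ClogitError, match="not nested"):
            mt.lrt(fit, other)

    def test_wald_and_lrt_agree_large_n(self):
        cfg = mt.CohortConfig(effect_shape="linear", linear_slope=0.02)
        df = mt.simulate_matched_sets(1000, 5, config=cfg, seed=5)
        d = design_from_frame(df)
        full = mt.fit_clogit(d)
        p_wald = mt.wald_test(full, "map")["p"]
        null_ll = mt.conditional_loglik(np.zeros(1), d)
        stat = 2 * (full.loglik - null_ll)
        p_lrt = stats.chi2.sf(stat, 1)
        assert abs(p_wald - p_lrt) < 0.01

    def test_wald_z_centred_under_null(self):
        cfg = mt.CohortConfig(
            slope_below_low_hba1c=0, slope_below_high_hba1c=0,
            slope_above_low_hba1c=0, slope_above_high_hba1c=0,
        )
        zs = []
        for r in range(60):
            df = mt.simulate_matched_sets(150, 5, config=cfg, seed=100 + r)
            fit = mt.fit_clogit(design_from_frame(df))
            zs.append(fit.beta[0] / fit.se[0])
        assert abs(np.median(zs)) < 0.35

    def test_wald_joint_matches_single(self, hinge_sets):
        d = design_from_frame(hinge_sets.iloc[: 6 * 100], cols=("map", "hba1c_high"))
        fit = mt.fit_clogit(d)
        single = mt.wald_test(fit, "map")
        joint = wald_joint(fit, ["map"])
        assert joint["statistic"] == pytest.approx(single["z"] ** 2, rel=1e-9)


class TestVif:
    def test_orthogonal_columns(self):
        n_sets = 200
        strata = np.repeat(np.arange(n_sets), 2)
        y = np.tile([1, 0], n_sets)
        # within-set contrasts with exactly zero cross-product after centring
        a = np.tile([1.0, -1.0], n_sets)
        b = a * np.repeat(np.resize([1.0, -1.0], n_sets), 2)
        d = mt.DesignMatrix(strata=strata, y=y, X=np.column_stack([a, b]), names=["a", "b"])
        res = mt.vif(d)
        assert res["per_column"]["a"] == pytest.approx(1.0, abs=1e-9)
        assert res["per_column"]["b"] == pytest.approx(1.0, abs=1e-9)
        assert res["mean_vif"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_column_infinite(self, small_random_design):
        d = small_random_design.with_columns(small_random_design.X[:, [0]], ["a_copy"])
        res = mt.vif(d)
        assert res["infinite"] == ["a", "a_copy"]
        assert np.isinf(res["per_column"]["a"])

    def test_known_correlation(self):
        """Columns with correlation 0.8 give VIF near 1/(1-0.64) = 2.78."""
        rng = np.random.default_rng(42)
        n_sets, m = 800, 3
        strata = np.repeat(np.arange(n_sets), m)
        y = np.tile([1, 0, 0], n_sets)
        z = rng.normal(size=n_sets * m)
        a = z
        b = 0.8 * z + np.sqrt(1 - 0.64) * rng.normal(size=n_sets * m)
        d = mt.DesignMatrix(strata=strata, y=y, X=np.column_stack([a, b]), names=["a", "b"])
        res = mt.vif(d)
        assert res["per_column"]["a"] == pytest.approx(1 / (1 - 0.64), rel=0.15)

    def test_needs_two_columns(self, pairs_design):
        with pytest.raises(ClogitError):
            mt.vif(pairs_design)


class TestCStatistic:
    def _design(self, eta, n_sets, m):
        strata = np.repeat(np.arange(n_sets), m)
        y = np.zeros(n_sets * m, dtype=int)
        y[::m] = 1
        return mt.DesignMatrix(strata=strata, y=y, X=np.asarray(eta)[:, None], names=["x"])

    def test_perfect_separation_auc_one(self):
        # cases always carry the larger predictor value
        eta = np.tile([5.0, 0.0, -1.0], 40)
        d = self._design(eta, 40, 3)
        fit = mt.FitResult(beta=np.ones(1), cov=np.eye(1), loglik=0.0, aic=2.0,
                           n_sets=40, n_iter=1, converged=True, names=["x"])
        assert mt.c_statistic(d, fit, method="within_set")["auc"] == 1.0

    def test_noise_predictor_near_half(self):
        rng = np.random.default_rng(1)
        eta = rng.normal(size=3000)
        d = self._design(eta, 1000, 3)
        fit = mt.FitResult(beta=np.ones(1), cov=np.eye(1), loglik=0.0, aic=2.0,
                           n_sets=1000, n_iter=1, converged=True, names=["x"])
        auc = mt.c_statistic(d, fit, method="within_set")["auc"]
        assert abs(auc - 0.5) < 0.02

    def test_antisymmetry(self, hinge_sets):
        d = design_from_frame(hinge_sets.iloc[: 6 * 100])
        fit = mt.fit_clogit(d)
        auc = mt.c_statistic(d, fit, method="within_set")["auc"]
        neg = mt.FitResult(beta=-fit.beta, cov=fit.cov, loglik=fit.loglik, aic=fit.aic,
                           n_sets=fit.n_sets, n_iter=fit.n_iter, converged=True,
                           names=fit.names)
        auc_neg = mt.c_statistic(d, neg, method="within_set")["auc"]
        assert auc + auc_neg == pytest.approx(1.0, abs=1e-12)

    def test_pairwise_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        cases = rng.normal(0.5, 1.0, size=80)
        ctrls = rng.normal(0.0, 1.0, size=300)
        ours = _pairwise_auc(cases, ctrls)
        ref = roc_auc_score(np.r_[np.ones(80), np.zeros(300)], np.r_[cases, ctrls])
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_two_level_recovers_discrimination(self, hinge_sets):
        """Random-intercept refit gives AUC > 0.5 on informative data and a
        finite variance estimate."""
        df = hinge_sets.iloc[: 6 * 120]
        d = design_from_frame(df)
        fit = mt.fit_clogit(d)
        res = mt.c_statistic(d, fit, method="two_level")
        assert res["method"] == "two_level"
        assert 0.5 < res["auc"] <= 1.0
        assert res["sigma_u"] >= 0.0

    def test_unknown_method(self, pairs_design):
        fit = mt.fit_clogit(pairs_design)
        with pytest.raises(ClogitError):
            mt.c_statistic(pairs_design, fit, method="nope")
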