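import numpy as np
import pytest
from scipy import optimize, stats
from scipy.special import expit

from mocca.evaluate import (
    association_test,
    compare_methods_over_seeds,
    cumulative_r2_curve,
    pc_baseline,
    variance_explained,
)

# fixed 6-point fixture for the linear oracle
Y6 = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0])
P6 = np.array([0.2, 0.8, 0.4, 1.4, 1.0, 1.9])
C6 = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])


def _r2_normal_equations(y, design):
    X = np.column_stack([np.ones(len(y)), design])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    return 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))


class TestVarianceExplainedLinear:
    def test_perfect_predictor_gives_unit_r2(self):
        res = variance_explained(Y6, Y6.copy(), mode="marginal")
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_six_point_incremental_matches_normal_equations(self):
        res = variance_explained(Y6, P6, C6, mode="incremental")
        oracle = _r2_normal_equations(Y6, np.column_stack([C6, P6])) - _r2_normal_equations(Y6, C6)
        assert res.r2 == pytest.approx(oracle, abs=1e-10)

    def test_marginal_mode_ignores_covariates(self):
        res = variance_explained(Y6, P6, C6, mode="marginal")
        assert res.r2 == pytest.approx(_r2_normal_equations(Y6, P6), abs=1e-10)

    def test_null_predictors_explain_little_at_large_n(self):
        r2s = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(5000)
            p = rng.standard_normal((5000, 3))
            r2s.append(variance_explained(y, p, mode="marginal").r2)
        assert max(r2s) < 0.01

    def test_incremental_invariant_to_predictor_reparameterization(self, rng):
        y = rng.standard_normal(100)
        P = rng.standard_normal((100, 3))
        C = rng.standard_normal((100, 2))
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)  # invertible
        a = variance_explained(y, P, C).r2
        b = variance_explained(y, P @ A, C).r2
        assert a == pytest.approx(b, abs=1e-10)

    def test_aliased_predictor_dropped_with_warning(self, rng):
        y = rng.standard_normal(50)
        p = rng.standard_normal(50)
        with pytest.warns(RuntimeWarning, match="aliased"):
            res = variance_explained(y, np.column_stack([p, 2 * p]), mode="marginal")
        assert res.r2 == pytest.approx(
            variance_explained(y, p, mode="marginal").r2, abs=1e-10
        )


class TestVarianceExplainedLogistic:
    # fixed 12-point fixture
    YB = np.array([0, 0, 0, 1, 0, 1, 1, 0, 1, 1, 1, 1], dtype=float)
    PB = np.array([-1.5, -1.0, -0.8, -0.4, -0.2, 0.0, 0.2, 0.4, 0.8, 1.0, 1.2, 1.5])
    CB = np.array([0.3, -0.1, 0.4, 0.2, -0.5, 0.1, -0.2, 0.6, -0.3, 0.0, 0.5, -0.4])

    @staticmethod
    def _max_loglik(y, design):
        """Direct likelihood maximization, independent of the model-fitting path."""
        X = np.column_stack([np.ones(len(y)), design]) if design.size else np.ones((len(y), 1))

        def nll(beta):
            eta = X @ beta
            return -np.sum(y * eta - np.logaddexp(0.0, eta))

        res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS")
        return -res.fun

    def test_mcfadden_matches_direct_likelihood_oracle(self):
        full = self._max_loglik(self.YB, np.column_stack([self.CB, self.PB]))
        null = self._max_loglik(self.YB, self.CB[:, None])
        oracle = 1 - full / null
        res = variance_explained(self.YB, self.PB, self.CB, family="logistic")
        assert res.r2 == pytest.approx(oracle, abs=1e-6)

    def test_marginal_null_is_intercept_only(self):
        full = self._max_loglik(self.YB, self.PB[:, None])
        null = self._max_loglik(self.YB, np.empty((12, 0)))
        oracle = 1 - full / null
        res = variance_explained(self.YB, self.PB, self.CB, family="logistic", mode="marginal")
        assert res.r2 == pytest.approx(oracle, abs=1e-6)

    def test_perfect_separation_reports_one_with_warning(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        x = np.array([-4.0, -3.0, -2.0, -1.0, 1.0, 2.0, 3.0, 4.0])
        res = variance_explained(y, x, family="logistic", mode="marginal")
        assert res.r2 == 1.0
        assert any("separation" in w for w in res.warnings)


class TestPCBaseline:
    def test_rank_one_data_recovers_single_factor(self, rng):
        z = rng.standard_normal(80)
        x = np.outer(z, rng.standard_normal(10))
        pc1 = pc_baseline(x, 1)[:, 0]
        assert abs(np.corrcoef(pc1, z)[0, 1]) > 1 - 1e-10

    def test_scores_mutually_uncorrelated(self, rng):
        scores = pc_baseline(rng.standard_normal((60, 20)), 5)
        corr = np.corrcoef(scores, rowvar=False)
        assert np.abs(corr - np.eye(5)).max() < 1e-10

    def test_matches_eigendecomposition_oracle(self, rng):
        x = rng.standard_normal((50, 30))
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        order = np.argsort(evals)[::-1][:4]
        oracle = xc @ evecs[:, order]
        scores = pc_baseline(x, 4)
        for j in range(4):
            cos = abs(scores[:, j] @ oracle[:, j]) / (
                np.linalg.norm(scores[:, j]) * np.linalg.norm(oracle[:, j])
            )
            assert cos == pytest.approx(1.0, abs=1e-10)

    def test_deterministic_sign_convention(self, rng):
        x = rng.standard_normal((40, 6))
        a = pc_baseline(x, 3)
        b = pc_baseline(x.copy(), 3)
        np.testing.assert_array_equal(a, b)

    def test_k_too_large_errors(self, rng):
        with pytest.raises(ValueError):
            pc_baseline(rng.standard_normal((10, 4)), 5)


class TestCumulativeCurve:
    def test_first_element_is_single_predictor_r2(self, rng):
        y = rng.standard_normal(60)
        comp = rng.standard_normal((60, 4))
        curve = cumulative_r2_curve(y, comp, mode="marginal")
        assert curve[0] == pytest.approx(
            variance_explained(y, comp[:, 0], mode="marginal").r2, abs=1e-12
        )

    def test_linear_curve_is_monotone_nondecreasing(self, rng):
        y = rng.standard_normal(80)
        comp = rng.standard_normal((80, 6))
        cov = rng.standard_normal((80, 2))
        curve = cumulative_r2_curve(y, comp, cov)
        assert np.all(np.diff(curve) >= -1e-12)

    def test_matches_per_k_refit(self, rng):
        y = rng.standard_normal(70)
        comp = rng.standard_normal((70, 3))
        curve = cumulative_r2_curve(y, comp, mode="marginal")
        for k in range(3):
            assert curve[k] == pytest.approx(
                variance_explained(y, comp[:, : k + 1], mode="marginal").r2, abs=1e-12
            )


class TestAssociationTest:
    def test_hand_regression_matches_t_distribution_oracle(self):
        y = np.array([2.1, 2.9, 3.8, 5.2, 5.9, 7.1, 8.2, 8.8])
        x = np.arange(8.0)
        sign, p = association_test(x, y)
        # classical simple-regression t-test computed from first principles
        xc, yc = x - x.mean(), y - y.mean()
        beta = (xc @ yc) / (xc @ xc)
        resid = yc - beta * xc
        se = np.sqrt((resid @ resid) / 6 / (xc @ xc))
        t = beta / se
        p_oracle = 2 * stats.t.sf(abs(t), df=6)
        assert sign == np.sign(beta)
        assert p == pytest.approx(p_oracle, rel=1e-10)

    def test_collinear_cv_gives_zero_p_positive_sign(self):
        y = np.arange(10.0)
        sign, p = association_test(y.copy(), y)
        assert sign == 1.0 and p < 1e-30

    def test_null_p_values_roughly_uniform(self):
        pvals = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            y = rng.standard_normal(50)
            cv = rng.standard_normal(50)
            pvals.append(association_test(cv, y)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.001


class TestCompareMethodsOverSeeds:
    def test_method_against_itself_has_zero_difference(self, rng):
        y = rng.standard_normal(40)
        pool = rng.standard_normal((40, 60))

        def fitter(seed):
            return pool[:, seed % 60]

        cmp = compare_methods_over_seeds(fitter, fitter, y, n_seeds=10)
        assert cmp.mean_difference == 0.0
        assert cmp.p_value == 1.0
        assert not cmp.significant

    def test_paired_t_matches_closed_form(self, rng):
        y = rng.standard_normal(50)
        strong = y + 0.3 * rng.standard_normal(50)
        weak_pool = rng.standard_normal((50, 20))

        def fa(seed):
            return strong + 0.01 * seed * weak_pool[:, seed % 20]

        def fb(seed):
            return weak_pool[:, seed % 20]

        cmp = compare_methods_over_seeds(fa, fb, y, n_seeds=12)
        d = cmp.r2_a - cmp.r2_b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_oracle = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        assert cmp.mean_difference == pytest.approx(d.mean())
        assert cmp.p_value == pytest.approx(p_oracle, rel=1e-10)
        assert cmp.significant

    def test_too_few_seeds_errors(self, rng):
        with pytest.raises(ValueError):
            compare_methods_over_seeds(
                lambda s: np.ones(5), lambda s: np.ones(5), rng.standard_normal(5), n_seeds=1
            )
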