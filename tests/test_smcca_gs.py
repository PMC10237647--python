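import numpy as np
import pandas as pd
import pytest

from mocca import RunConfig, SMCCAGS, fit_smcca_gs, transform_assay
from mocca.dataio import intersect_features
from mocca.smcca_core import PenalizedProblem, fit_single_component
from mocca.smcca_gs import deflate
from mocca.synthetic import SyntheticSpec, generate_cohort_pair


def _standardized(rng, n, p):
    x = rng.standard_normal((n, p))
    x -= x.mean(axis=0)
    return x / x.std(axis=0, ddof=1)


class TestDeflate:
    def test_projection_leaves_orthogonal_columns_unchanged(self, rng):
        x = _standardized(rng, 30, 5)
        cv = rng.standard_normal(30)
        cv -= x @ np.linalg.lstsq(x, cv, rcond=None)[0]  # orthogonal to all columns
        out = deflate(x, cv, np.zeros(5), "projection")
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_projection_annihilates_column_equal_to_cv(self, rng):
        x = _standardized(rng, 30, 4)
        cv = x[:, 2].copy()
        out = deflate(x, cv, np.zeros(4), "projection")
        np.testing.assert_allclose(out[:, 2], 0.0, atol=1e-12)

    def test_projection_matches_dense_projector_oracle(self, rng):
        x = rng.standard_normal((25, 7))
        cv = rng.standard_normal(25)
        oracle = (np.eye(25) - np.outer(cv, cv) / (cv @ cv)) @ x
        np.testing.assert_allclose(deflate(x, cv, np.zeros(7), "projection"), oracle, atol=1e-12)

    def test_rank_one_subtracts_outer_product(self, rng):
        x = rng.standard_normal((10, 4))
        cv, w = rng.standard_normal(10), rng.standard_normal(4)
        np.testing.assert_allclose(
            deflate(x, cv, w, "rank_one"), x - np.outer(cv, w), atol=1e-14
        )

    def test_zero_cv_projection_errors(self):
        with pytest.raises(ValueError, match="zero-norm"):
            deflate(np.ones((3, 2)), np.zeros(3), np.ones(2), "projection")


class TestSMCCAGS:
    def test_single_component_matches_core_solver(self, rng):
        xs = [_standardized(rng, 60, 8), _standardized(rng, 60, 12)]
        est = SMCCAGS(n_components=1, penalties=[2.0, 2.5], standardize=False).fit(xs)
        comp = fit_single_component(PenalizedProblem(xs, [2.0, 2.5]))
        for i in range(2):
            np.testing.assert_allclose(est.weights_[i][:, 0], comp.weights[i], atol=1e-12)
            np.testing.assert_allclose(est.cvs_[i][:, 0], comp.cvs[i], atol=1e-12)

    def test_projection_mode_cvs_are_uncorrelated(self, planted_three_factor):
        (assays, _, _), _ = planted_three_factor
        est = SMCCAGS(n_components=6).fit([a.to_numpy() for a in assays])
        for i in range(2):
            corr = est.cv_correlation_matrix(i)
            off = np.abs(corr - np.eye(corr.shape[0])).max()
            assert off <= 1e-6

    def test_planted_factors_recovered_in_strength_order(self, planted_three_factor):
        (assays, _, truth), _ = planted_three_factor
        est = SMCCAGS(n_components=3).fit([a.to_numpy() for a in assays])
        for i in range(2):
            for k in range(3):
                r = np.corrcoef(est.cvs_[i][:, k], truth.factors[:, k])[0, 1]
                assert abs(r) >= 0.9, (i, k, r)

    def test_rank_one_mode_leaves_residual_correlation(self, rng):
        # correlated features: dense overlapping loadings across 4 factors
        spec = SyntheticSpec(
            n=150, p=(120, 150), k_true=4, sparsity=0.4,
            loading_scale=(5.0, 4.0, 3.0, 2.0), noise_sd=1.0, seed=11,
        )
        from mocca.synthetic import generate_multiomics

        assays, _, _ = generate_multiomics(spec)
        est = SMCCAGS(n_components=6, deflation="rank_one").fit(
            [a.to_numpy() for a in assays]
        )
        corr = est.cv_correlation_matrix(0)
        off = np.abs(corr - np.diag(np.diag(corr))).max()
        assert off > 0.1

    def test_cv_correlation_matrix_single_component(self, rng):
        xs = [_standardized(rng, 40, 5), _standardized(rng, 40, 6)]
        est = SMCCAGS(n_components=1, standardize=False).fit(xs)
        np.testing.assert_array_equal(est.cv_correlation_matrix(0), [[1.0]])

    def test_sample_permutation_equivariance(self, rng):
        xs = [_standardized(rng, 50, 7), _standardized(rng, 50, 9)]
        perm = rng.permutation(50)
        a = SMCCAGS(n_components=2, standardize=False).fit(xs)
        b = SMCCAGS(n_components=2, standardize=False).fit([x[perm] for x in xs])
        for i in range(2):
            np.testing.assert_allclose(a.cvs_[i][perm], b.cvs_[i], atol=1e-8)

    def test_energy_decomposition_projection_mode(self, rng):
        """Each deflation removes exactly the projected energy (Pythagoras),
        and every CV's squared norm is bounded by its step's removed energy."""
        xs = [_standardized(rng, 40, 6), _standardized(rng, 40, 8)]
        est = SMCCAGS(
            n_components=4, penalties=[np.sqrt(6), np.sqrt(8)],
            standardize=False, max_iter=500,
        ).fit(xs)
        for i, x in enumerate(xs):
            current = x.copy()
            removed_total = 0.0
            for k in range(est.n_components_):
                cv = est.component_fits_[k].cvs[i]
                proj = np.outer(cv, cv @ current) / (cv @ cv)
                removed = np.linalg.norm(proj) ** 2
                assert cv @ cv <= removed + 1e-8
                removed_total += removed
                current -= proj
            total = np.linalg.norm(x) ** 2
            assert total == pytest.approx(
                removed_total + np.linalg.norm(current) ** 2, abs=1e-8
            )

    def test_transform_source_reproduces_fitted_cv1(self, planted_three_factor):
        (assays, _, _), _ = planted_three_factor
        xs = [a.to_numpy() for a in assays]
        est = SMCCAGS(n_components=3).fit(xs)
        out = est.transform(xs, standardization="source")
        for i in range(2):
            np.testing.assert_allclose(out[i][:, 0], est.cvs_[i][:, 0], atol=1e-10)

    def test_zero_weight_column_gives_zero_cv(self, rng):
        xs = [_standardized(rng, 30, 5), _standardized(rng, 30, 6)]
        est = SMCCAGS(n_components=1, standardize=False).fit(xs)
        est.weights_[0] = np.zeros_like(est.weights_[0])
        out = est.transform(xs)
        np.testing.assert_array_equal(out[0], 0.0)

    def test_rejects_single_matrix_and_misaligned_views(self, rng):
        with pytest.raises(ValueError, match="list of assay"):
            SMCCAGS().fit(rng.standard_normal((10, 4)))
        with pytest.raises(ValueError, match="sample"):
            SMCCAGS().fit([rng.standard_normal((10, 4)), rng.standard_normal((9, 4))])


class TestDataFrameWrappers:
    def test_fit_smcca_gs_labels_artifacts(self, planted_three_factor):
        (assays, _, _), _ = planted_three_factor
        config = RunConfig(n_components=2, seed=3)
        result = fit_smcca_gs(assays, config, names=["prot", "meth"])
        assert result.assay_names == ["prot", "meth"]
        assert list(result.weights["prot"].columns) == ["CV1", "CV2"]
        assert list(result.weights["meth"].index) == list(assays[1].columns)
        assert result.cvs["prot"].index.equals(assays[0].index)
        assert all(c["converged"] for c in result.components)

    def test_cross_cohort_transfer_tracks_native_fit(self):
        spec = SyntheticSpec(
            n=400, p=(150, 200), k_true=1, sparsity=0.1, loading_scale=3.0,
            noise_sd=1.0, outcome_r2=0.5, seed=21, n_cohorts=2,
        )
        (A, _, _), (B, _, truth_b) = generate_cohort_pair(spec)
        config = RunConfig(n_components=1, seed=0)
        fit_a = fit_smcca_gs(A, config, names=["a1", "a2"])
        fit_b = fit_smcca_gs(B, config, names=["a1", "a2"])
        w, assay = intersect_features(fit_a.weights["a1"], B[0])
        transferred = transform_assay(assay, w)
        native_r = abs(np.corrcoef(fit_b.cvs["a1"]["CV1"], truth_b.factors[:, 0])[0, 1])
        transfer_r = abs(np.corrcoef(transferred["CV1"], truth_b.factors[:, 0])[0, 1])
        assert abs(native_r - transfer_r) <= 0.05
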