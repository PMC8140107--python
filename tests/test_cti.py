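import numpy as np
import pytest
from scipy.stats import skew

from neuropm.cti import (
    CPCAModel,
    adjust_covariates,
    assign_subtrajectories,
    boxcox_standardize,
    compute_pseudotimes,
    cpca_decompose,
    feature_contributions,
    preselect_features,
)
from neuropm.io import FeatureTable


def _table(values, covariates=None, **kw):
    n = values.shape[0]
    return FeatureTable(values=values, subject_ids=[str(i + 1) for i in range(n)],
                        feature_names=[f"f{j}" for j in range(values.shape[1])],
                        covariates=covariates, **kw)


class TestAdjustCovariates:
    def test_exact_linear_confound_removed(self, rng):
        c = rng.normal(size=(100, 1))
        y = 2.0 * c[:, 0]
        t = _table(np.column_stack([y, rng.normal(size=100)]), covariates=c)
        adj = adjust_covariates(t)
        assert adj.values[:, 0].var() < 1e-10 * y.var()

    def test_null_covariates_leave_data_unchanged(self, rng):
        X = rng.normal(size=(500, 3))
        c = rng.normal(size=(500, 2))  # independent of X
        adj = adjust_covariates(_table(X, covariates=c))
        assert np.max(np.abs(adj.values - X)) < 0.5 * X.std()

    def test_binary_covariate_group_difference_removed(self, rng):
        g = rng.integers(0, 2, size=200).astype(float)
        y = 5.0 * g + rng.normal(0, 0.1, size=200)
        adj = adjust_covariates(_table(y[:, None], covariates=g[:, None]))
        grp_gap = abs(adj.values[g == 1, 0].mean() - adj.values[g == 0, 0].mean())
        assert grp_gap < 0.1  # indicator expansion captured both levels

    def test_residuals_recentered_to_feature_mean(self, rng):
        c = rng.normal(size=(80, 1))
        y = 3.0 + 1.5 * c[:, 0] + rng.normal(0, 0.1, 80)
        adj = adjust_covariates(_table(y[:, None], covariates=c))
        assert adj.values[:, 0].mean() == pytest.approx(y.mean(), abs=1e-6)


class TestPreselect:
    def test_constant_feature_ranked_last(self, rng):
        X = rng.normal(size=(50, 4))
        X[:, 2] = 1.0
        order = preselect_features(_table(X), keep_fraction=1.0, k_neighbors=5)
        assert order[-1] == 2

    def test_structured_features_beat_noise(self, rng):
        # several features driven by a latent 1-D ordering vs pure noise
        # with the same marginal variance: neighborhoods follow the latent
        # ordering, so structured features have low neighborhood variance
        stage = rng.uniform(0, 1, 200)
        structured = np.column_stack(
            [3 * stage + rng.normal(0, 0.1, 200) for _ in range(4)])
        structured = (structured - structured.mean(0)) / structured.std(0)
        noise = rng.normal(size=(200, 4))
        X = np.column_stack([structured, noise])
        order = preselect_features(_table(X), keep_fraction=1.0, k_neighbors=10)
        assert set(order[:4].tolist()) == {0, 1, 2, 3}

    def test_keep_fraction_one_returns_all(self, rng):
        X = rng.normal(size=(30, 6))
        assert preselect_features(_table(X), 1.0, 5).size == 6

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ValueError, match="keep_fraction"):
            preselect_features(_table(rng.normal(size=(30, 4))), 0.0, 5)


class TestBoxCox:
    def test_output_standardized(self, rng):
        X = rng.lognormal(size=(300, 3))
        out = boxcox_standardize(X)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-10)

    def test_skew_reduced_for_lognormal(self, rng):
        x = rng.lognormal(size=(1000, 1))
        out = boxcox_standardize(x)
        assert abs(skew(out[:, 0])) < abs(skew(x[:, 0]))

    def test_nonpositive_values_handled(self, rng):
        x = rng.normal(-5, 1, size=(200, 1))
        out = boxcox_standardize(x)
        assert np.isfinite(out).all()

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = boxcox_standardize(np.ones((10, 1)))
        np.testing.assert_array_equal(out, 0.0)


class TestCPCA:
    def test_alpha_zero_matches_plain_pca(self, rng):
        T = rng.normal(size=(100, 5)) @ np.diag([3, 2, 1, 0.5, 0.1])
        Bg = rng.normal(size=(60, 5))
        model = cpca_decompose(T, Bg, alphas=np.array([0.0]))
        evals, evecs = np.linalg.eigh(np.cov(T, rowvar=False))
        order = np.argsort(-evals)
        for j in range(5):
            cos = abs(model.loadings[:, j] @ evecs[:, order[j]])
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_large_alpha_suppresses_background_axis(self, rng):
        # background varies along axis 0 only; target equally on both axes
        Bg = np.column_stack([rng.normal(0, 2, 500), rng.normal(0, 0.01, 500)])
        T = np.column_stack([rng.normal(0, 1, 500), rng.normal(0, 1, 500)])
        model = cpca_decompose(T, Bg, alphas=np.array([50.0]))
        assert abs(model.loadings[1, 0]) > 0.99  # top component on axis 1

    def test_identical_populations_reduce_to_pca(self, rng):
        X = rng.normal(size=(200, 4)) @ np.diag([2, 1.5, 1, 0.2])
        model = cpca_decompose(X, X.copy(), alphas=np.array([0.5]))
        # C - 0.5 C = 0.5 C shares eigenvectors with C
        evals, evecs = np.linalg.eigh(np.cov(X, rowvar=False))
        order = np.argsort(-evals)
        for j in range(4):
            assert abs(model.loadings[:, j] @ evecs[:, order[j]]) == pytest.approx(1, abs=1e-8)

    def test_normalized_eigenvalues_sum_to_one(self, rng):
        model = cpca_decompose(rng.normal(size=(50, 6)), rng.normal(size=(40, 6)),
                               n_alphas=10)
        assert model.normalized_eigenvalues.sum() == pytest.approx(1.0)
        assert model.normalized_eigenvalues.min() >= 0

    def test_max_components_clipped_with_warning(self, rng):
        with pytest.warns(UserWarning, match="clipped"):
            cpca_decompose(rng.normal(size=(30, 3)), rng.normal(size=(30, 3)),
                           n_alphas=4, max_components=10)


class TestPseudotimes:
    def test_centroid_zero_farthest_one(self, rng):
        X = np.vstack([np.zeros((3, 2)), rng.normal(2, 0.3, size=(10, 2))])
        pt = compute_pseudotimes(X, np.arange(3))
        assert pt[:3].max() == pytest.approx(0.0, abs=1e-6)
        assert pt.max() == pytest.approx(1.0)
        assert (pt >= 0).all() and (pt <= 1).all()

    def test_collinear_chain_orders_by_position(self):
        x = np.array([[0.0], [1.0], [2.5], [4.0], [6.0]])
        pt = compute_pseudotimes(x, np.array([0]))
        assert np.all(np.diff(pt) > 0)
        np.testing.assert_allclose(pt, x[:, 0] / 6.0, atol=1e-6)

    def test_duplicate_points_jittered_deterministically(self):
        X = np.array([[0.0, 0], [1, 1], [1, 1], [2, 2]])
        with pytest.warns(UserWarning, match="duplicate"):
            p1 = compute_pseudotimes(X, np.array([0]))
        with pytest.warns(UserWarning, match="duplicate"):
            p2 = compute_pseudotimes(X, np.array([0]))
        np.testing.assert_array_equal(p1, p2)


class TestSubtrajectories:
    def test_two_blobs_recovered(self, rng):
        A = rng.normal(0, 0.5, size=(100, 2)) + [4, 0]
        B = rng.normal(0, 0.5, size=(100, 2)) - [4, 0]
        X = np.vstack([A, B])
        mem, k, probs = assign_subtrajectories(X, max_subtrajectories=5, seed=0)
        assert k == 2
        primary = np.array([m[0] for m in mem])
        # label permutation-invariant accuracy
        acc = max(np.mean(primary[:100] == c) + np.mean(primary[100:] == 1 - c)
                  for c in (0, 1)) / 2
        assert acc >= 0.95

    def test_equidistant_point_joins_both_clusters(self, rng):
        # overlapping blobs: a subject at the midpoint has genuinely mixed
        # posterior probability and must be assigned to both subtrajectories
        A = rng.normal(0, 0.6, size=(80, 2)) + [1.2, 0]
        B = rng.normal(0, 0.6, size=(80, 2)) - [1.2, 0]
        X = np.vstack([A, B, [[0.0, 0.0]]])
        mem, k, probs = assign_subtrajectories(X, max_subtrajectories=3,
                                               membership_tolerance=0.4, seed=0)
        assert len(mem[-1]) >= 2

    def test_max_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            assign_subtrajectories(rng.normal(size=(10, 2)), max_subtrajectories=1)


class TestContributions:
    def _model(self, loadings, lam_norm, cutoff=0.025):
        loadings = np.asarray(loadings, float)
        return CPCAModel(alphas=np.array([1.0]), selected_alpha=1.0,
                         loadings=loadings, eigenvalues=np.asarray(lam_norm),
                         normalized_eigenvalues=np.asarray(lam_norm),
                         eigenvalue_cutoff=cutoff)

    def test_single_loading_concentrates_contribution(self):
        W = np.zeros((6, 1))
        W[4, 0] = 1.0
        C = feature_contributions(self._model(W, [1.0]))
        assert C[4] == pytest.approx(100.0)
        assert np.delete(C, 4).max() == 0.0

    def test_all_components_retained_sums_to_100(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        lam = np.array([0.4, 0.3, 0.15, 0.1, 0.05])
        C = feature_contributions(self._model(q, lam))
        assert C.sum() == pytest.approx(100.0, abs=1e-9)

    def test_hand_computed_two_feature_case(self):
        W = np.array([[1.0, np.sqrt(0.5)], [0.0, np.sqrt(0.5)]])
        C = feature_contributions(self._model(W, [0.7, 0.3]))
        np.testing.assert_allclose(C, [85.0, 15.0], atol=1e-9)

    def test_no_component_above_cutoff_rejected(self):
        W = np.eye(3)
        with pytest.raises(ValueError, match="cutoff"):
            feature_contributions(self._model(W, [0.02, 0.01, 0.97], cutoff=0.99))
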