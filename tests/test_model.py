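"""Feature selection, QDA fitting and the exhaustive subset search."""

import numpy as np
import pytest
from scipy import stats
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)

from retirr.model import (
    ClassifierModel,
    cross_validate,
    n_subsets,
    search_qda_combinations,
    select_features,
    train_qda,
)


def gaussian_two_class(rng, n=150, d=3, delta=2.0):
    Xa = rng.normal(0, 1, (n, d))
    Xb = rng.normal(delta, 1, (n, d))
    X = np.vstack([Xa, Xb])
    y = np.array([1] * n + [2] * n)
    return X, y


class TestSelectFeatures:
    def test_recovers_planted_support(self):
        """Mean-shifted columns 3, 82, 85 are found among the candidates."""
        rng = np.random.default_rng(0)
        for rep in range(5):
            X = rng.normal(0, 1, (240, 126))
            y = np.array([1] * 120 + [2] * 120)
            X[y == 2][:, [3, 82, 85]] += 0.0  # no-op guard for fancy indexing
            X[120:, 3] += 0.8
            X[120:, 82] += 0.8
            X[120:, 85] += 0.8
            res = select_features(X, y, seed=rep)
            assert {3, 82, 85} <= set(res.candidate_indices.tolist())
            assert res.cv_mse < 0.25

    def test_pure_noise_selects_few(self):
        """At the minimum-CV-MSE penalty, noise-only data yields small candidate
        sets (median <= 2 over replicates)."""
        rng = np.random.default_rng(1)
        counts = []
        for rep in range(15):
            X = rng.normal(0, 1, (200, 126))
            y = np.array([1] * 100 + [2] * 100)
            res = select_features(X, y, seed=rep)
            counts.append(len(res.candidate_indices))
        assert np.median(counts) <= 2

    def test_elastic_net_grouping_vs_lasso(self):
        """Two nearly collinear informative columns: the elastic net keeps both
        with comparable weight; the LASSO concentrates on one."""
        rng = np.random.default_rng(2)
        n = 300
        base = rng.normal(0, 1, n)
        X = rng.normal(0, 1, (n, 20))
        X[:, 0] = base
        X[:, 1] = base + rng.normal(0, 0.05, n)
        y = np.where(base + rng.normal(0, 1.0, n) > 0, 2, 1)
        enet = select_features(X, y, method="enet", seed=0)
        lasso = select_features(X, y, method="lasso", seed=0)
        c_enet = dict(zip(enet.candidate_indices.tolist(), np.abs(enet.coefficients)))
        assert 0 in c_enet and 1 in c_enet
        ratio_enet = min(c_enet[0], c_enet[1]) / max(c_enet[0], c_enet[1])
        c_lasso = dict(zip(lasso.candidate_indices.tolist(), np.abs(lasso.coefficients)))
        ratio_lasso = min(c_lasso.get(0, 0.0), c_lasso.get(1, 0.0)) / max(
            c_lasso.get(0, 1e-12), c_lasso.get(1, 1e-12)
        )
        assert ratio_enet > ratio_lasso
        assert ratio_enet > 0.5

    def test_single_class_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError):
            select_features(X, np.ones(10))


class TestTrainQda:
    def test_matches_sklearn_predictions_and_posteriors(self):
        rng = np.random.default_rng(3)
        X, y = gaussian_two_class(rng, n=200, d=4, delta=1.0)
        model = train_qda(X, y, [0, 1, 2, 3])
        sk = QuadraticDiscriminantAnalysis(store_covariance=True, reg_param=0.0)
        sk.fit(X, y)
        grid = rng.normal(0.5, 2.0, (500, 4))
        assert np.array_equal(model.predict(grid), sk.predict(grid))
        # small conditioning ridge => posteriors agree to ~1e-5, labels exactly
        np.testing.assert_allclose(
            model.posterior(grid), sk.predict_proba(grid)[:, 1], atol=1e-4
        )

    def test_equal_covariance_matches_analytic_lda_boundary(self):
        """Known 1-D Gaussians with equal variance: the decision threshold is
        the prior-adjusted midpoint."""
        rng = np.random.default_rng(4)
        n = 4000
        X = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])[:, None]
        y = np.array([1] * n + [2] * n)
        model = train_qda(X, y, [0])
        grid = np.linspace(-3, 5, 801)[:, None]
        pred = model.predict(grid)
        crossing = grid[np.argmax(pred == 2), 0]
        assert crossing == pytest.approx(1.0, abs=0.1)

    def test_unequal_variance_gives_two_sided_acceptance_region(self):
        """Class A ~ N(0,1) vs B ~ N(0,9): A is accepted only inside a central
        band whose edges match the analytic quadratic roots."""
        rng = np.random.default_rng(5)
        n = 5000
        X = np.concatenate([rng.normal(0, 1, n), rng.normal(0, 3, n)])[:, None]
        y = np.array([1] * n + [2] * n)
        model = train_qda(X, y, [0])
        grid = np.linspace(-8, 8, 1601)[:, None]
        pred = model.predict(grid)
        inside = grid[pred == 1, 0]
        assert inside.min() < -1 and inside.max() > 1
        # analytic root from the fitted standardized parameters
        s1 = np.sqrt(model.covariances[1][0, 0])
        s2 = np.sqrt(model.covariances[2][0, 0])
        m1, m2 = model.means[1][0], model.means[2][0]
        pri = np.log(model.priors[1] / model.priors[2])
        # solve 0.5*(x-m2)^2/s2^2 - 0.5*(x-m1)^2/s1^2 + log(s2/s1) + pri = 0
        a = 0.5 / s2**2 - 0.5 / s1**2
        b = -m2 / s2**2 + m1 / s1**2
        c = 0.5 * m2**2 / s2**2 - 0.5 * m1**2 / s1**2 + np.log(s2 / s1) + pri
        roots = np.sort(np.roots([a, b, c]))
        scale = model.scaler_sd[0]
        edges_mm = np.sort([inside.min(), inside.max()])
        analytic = roots * scale + model.scaler_mean[0]
        np.testing.assert_allclose(edges_mm, analytic, atol=0.05)

    def test_too_few_samples_per_class_rejected(self):
        X = np.random.default_rng(0).normal(0, 1, (8, 5))
        y = np.array([1, 1, 1, 2, 2, 2, 2, 2])
        with pytest.raises(ValueError, match="fewer features"):
            train_qda(X, y, [0, 1, 2, 3])

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(6)
        X, y = gaussian_two_class(rng, n=60, d=2)
        model = train_qda(X, y, [0, 1])
        clone = ClassifierModel.from_json(model.to_json())
        grid = rng.normal(0, 2, (50, 2))
        assert np.array_equal(model.predict(grid), clone.predict(grid))

    def test_shared_covariance_reduces_to_lda(self):
        """Forcing one pooled covariance into both classes reproduces sklearn
        LDA's predictions exactly."""
        rng = np.random.default_rng(7)
        X, y = gaussian_two_class(rng, n=150, d=3, delta=0.8)
        model = train_qda(X, y, [0, 1, 2])
        Z = (X - model.scaler_mean) / model.scaler_sd
        n1, n2 = np.sum(y == 1), np.sum(y == 2)
        pooled = (
            (n1 - 1) * np.cov(Z[y == 1], rowvar=False)
            + (n2 - 1) * np.cov(Z[y == 2], rowvar=False)
        ) / (n1 + n2 - 2)
        model.covariances = {1: pooled, 2: pooled}
        lda = LinearDiscriminantAnalysis()
        lda.fit(Z, y)
        grid = rng.normal(0, 2, (400, 3))
        assert np.array_equal(model.predict(grid * model.scaler_sd + model.scaler_mean),
                              lda.predict(grid))


class TestSearch:
    def test_exhaustive_counts(self):
        assert n_subsets(6, 6) == 63
        assert n_subsets(6, 3) == 41
        rng = np.random.default_rng(8)
        X, y = gaussian_two_class(rng, n=50, d=6, delta=1.0)
        ranked = search_qda_combinations(X, y, list(range(6)), max_size=6)
        assert len(ranked) == 63
        ranked3 = search_qda_combinations(X, y, list(range(6)), max_size=3)
        assert len(ranked3) == 41

    def test_separable_data_top_model_is_perfect(self):
        rng = np.random.default_rng(9)
        X, y = gaussian_two_class(rng, n=60, d=4, delta=8.0)
        ranked = search_qda_combinations(X, y, [0, 1, 2, 3], max_size=3)
        assert ranked[0].sensitivity == 1.0
        assert ranked[0].specificity == 1.0
        assert ranked[0].meets_threshold
        # parsimony tie-break: perfect separation already at one feature
        assert len(ranked[0].feature_indices) == 1

    def test_signal_beats_permutation_null(self):
        """Best training Youden index on real labels exceeds the 95th percentile
        of the permutation-null distribution."""
        rng = np.random.default_rng(10)
        X, y = gaussian_two_class(rng, n=80, d=4, delta=1.2)
        def best_youden(labels):
            ranked = search_qda_combinations(X, labels, [0, 1, 2, 3], max_size=2)
            return max(r.sensitivity + r.specificity - 1.0 for r in ranked)
        observed = best_youden(y)
        null = [best_youden(rng.permutation(y)) for _ in range(20)]
        assert observed > np.quantile(null, 0.95)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            search_qda_combinations(np.zeros((10, 2)), np.array([1, 2] * 5), [])


class TestCrossValidate:
    def test_separable_data_perfect_and_deterministic(self):
        rng = np.random.default_rng(11)
        X, y = gaussian_two_class(rng, n=50, d=2, delta=10.0)
        mean, sd = cross_validate(X, y, [0, 1], k=5, repeats=5, seed=0)
        assert mean == 1.0 and sd == 0.0
        again = cross_validate(X, y, [0, 1], k=5, repeats=5, seed=0)
        assert again == (mean, sd)

    def test_chance_level_on_permuted_labels(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (200, 3))
        y = rng.permutation([1] * 120 + [2] * 80)
        mean, _ = cross_validate(X, y, [0, 1, 2], k=5, repeats=10, seed=1)
        prevalence = 0.6
        se = np.sqrt(prevalence * (1 - prevalence) / 200)
        assert abs(mean - prevalence) < 4 * se + 0.05

    def test_k_larger_than_class_rejected(self):
        X = np.zeros((6, 2))
        y = np.array([1, 1, 1, 1, 2, 2])
        with pytest.raises(ValueError):
            cross_validate(X, y, [0], k=5)
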