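"""SPD-manifold math and linear classifiers, checked against closed forms
and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fatiguebci.riemann import (
    LinearClassifier,
    ShrinkageLDA,
    airm_distance,
    fit_classifier,
    kfold_scores,
    sample_covariance,
    spd_mean,
    tangent_inverse,
    tangent_map,
    xdawn_filters,
)
from fatiguebci.signals import DegenerateInputError


def _random_spd(rng, n=4, scale=1.0):
    A = rng.standard_normal((n, n))
    return A @ A.T + scale * np.eye(n)


class TestSampleCovariance:
    def test_uncorrelated_unit_channels_give_identity(self, rng):
        X = rng.standard_normal((2, 100_000))
        C = sample_covariance(X)
        np.testing.assert_allclose(C, np.eye(2), atol=0.02)

    def test_bilinearity_under_scaling(self, rng):
        X = rng.standard_normal((3, 500))
        np.testing.assert_allclose(sample_covariance(2 * X), 4 * sample_covariance(X))

    def test_duplicated_channel_still_spd(self, rng):
        x = rng.standard_normal(500)
        C = sample_covariance(np.stack([x, x, rng.standard_normal(500)]))
        assert np.linalg.eigvalsh(C)[0] > 0

    def test_constant_epoch_signals_degenerate(self):
        with pytest.raises(DegenerateInputError):
            sample_covariance(np.ones((3, 100)))


class TestSpdMean:
    def test_idempotent_on_repeated_matrix(self, rng):
        P = _random_spd(rng)
        np.testing.assert_allclose(spd_mean(np.stack([P, P])), P, atol=1e-7)

    def test_mean_of_p_and_inverse_is_identity(self, rng):
        """Geodesic midpoint of {P, P⁻¹} is the identity."""
        P = _random_spd(rng, 5, scale=3.0)
        M = spd_mean(np.stack([P, np.linalg.inv(P)]))
        assert airm_distance(M, np.eye(5)) < 1e-7

    def test_commuting_diagonals_give_geometric_mean(self):
        D1 = np.diag([1.0, 4.0, 9.0])
        D2 = np.diag([4.0, 1.0, 1.0])
        M = spd_mean(np.stack([D1, D2]))
        np.testing.assert_allclose(np.diag(M), np.sqrt(np.diag(D1) * np.diag(D2)),
                                   rtol=1e-7)

    def test_congruence_equivariance(self, rng):
        """mean(AᵀPᵢA) = Aᵀ mean(Pᵢ) A for invertible A."""
        Ps = np.stack([_random_spd(rng) for _ in range(5)])
        A = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        M = spd_mean(Ps, tol=1e-6)
        M_cong = spd_mean(np.stack([A.T @ P @ A for P in Ps]), tol=1e-6)
        np.testing.assert_allclose(M_cong, A.T @ M @ A, rtol=1e-4, atol=1e-6)

    def test_nonconvergence_raises_with_iteration_count(self, rng):
        Ps = np.stack([_random_spd(rng, scale=0.01) for _ in range(4)])
        with pytest.raises(RuntimeError, match="2 iterations"):
            spd_mean(Ps, tol=1e-15, max_iter=2)


class TestTangentSpace:
    def test_map_at_own_reference_is_zero(self, rng):
        P = _random_spd(rng)
        assert np.allclose(tangent_map(P, P), 0, atol=1e-10)

    def test_scalar_matrix_closed_form(self):
        """At reference I, P = e·I maps to diag entries 1 and off-diag 0."""
        v = tangent_map(np.e * np.eye(2), np.eye(2))
        # upper-triangle order: (0,0), (0,1), (1,1)
        np.testing.assert_allclose(v, [1.0, 0.0, 1.0], atol=1e-12)

    def test_norm_equals_affine_invariant_distance(self, rng):
        P, R = _random_spd(rng), _random_spd(rng)
        assert np.linalg.norm(tangent_map(P, R)) == pytest.approx(
            airm_distance(P, R), abs=1e-8
        )

    def test_exp_log_round_trip(self, rng):
        P, R = _random_spd(rng), _random_spd(rng)
        back = tangent_inverse(tangent_map(P, R), R)
        np.testing.assert_allclose(back, P, rtol=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            tangent_map(_random_spd(rng, 3), _random_spd(rng, 4))


class TestXdawn:
    @staticmethod
    def _planted_erp(rng, n_epochs=60, n_channels=8, n_times=120, snr=10.0):
        pattern = rng.standard_normal(n_channels)
        pattern /= np.linalg.norm(pattern)
        bump = np.sin(np.pi * np.arange(40) / 40)
        labels = np.array(["target" if i % 3 == 0 else "nontarget"
                           for i in range(n_epochs)])
        X = rng.standard_normal((n_epochs, n_channels, n_times))
        for i in range(n_epochs):
            if labels[i] == "target":
                X[i, :, 40:80] += snr * pattern[:, None] * bump[None, :]
        return X, labels, pattern

    def test_recovers_planted_spatial_pattern(self, rng):
        X, y, pattern = self._planted_erp(rng)
        filters, template, _ = xdawn_filters(X, y, n_filters=2)
        # the leading filter's response to the planted pattern dominates:
        # correlate the template's dominant spatial direction with truth
        u, _, _ = np.linalg.svd(template - template.mean(axis=1, keepdims=True))
        corr = abs(u[:, 0] @ pattern)
        assert corr >= 0.95

    def test_filters_invariant_to_epoch_rescaling(self, rng):
        X, y, _ = self._planted_erp(rng)
        f1, _, _ = xdawn_filters(X, y, n_filters=2)
        f2, _, _ = xdawn_filters(5.0 * X, y, n_filters=2)
        for a, b in zip(f1, f2):
            assert abs(abs(a @ b) - 1.0) < 1e-6  # unit filters equal up to sign

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 4, 50))
        with pytest.raises(ValueError, match="target"):
            xdawn_filters(X, np.array(["nontarget"] * 10))


class TestClassifiers:
    @staticmethod
    def _two_gaussians(rng, n=200, sep=8.0, d=5):
        X0 = rng.standard_normal((n, d))
        X1 = rng.standard_normal((n, d)) + sep / np.sqrt(d)
        X = np.vstack([X0, X1])
        y = np.array(["a"] * n + ["b"] * n)
        return X, y

    @pytest.mark.parametrize("kind", ["logistic", "slda"])
    def test_separable_classes_perfect_resubstitution(self, rng, kind):
        X, y = self._two_gaussians(rng)
        clf = fit_classifier(X, y, kind=kind)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_identical_distributions_near_chance(self, rng):
        X = rng.standard_normal((2000, 4))
        y = np.array(["a", "b"] * 1000)
        clf = fit_classifier(X, y, kind="logistic")
        assert abs(np.mean(clf.predict(X) == y) - 0.5) < 0.06

    def test_slda_zero_shrinkage_matches_brute_force_lda(self, rng):
        """At shrinkage 0, weights equal Σ⁻¹(μ₁-μ₀) computed directly."""
        X, y = self._two_gaussians(rng, n=300, sep=3.0)
        clf = fit_classifier(X, y, kind="slda", shrinkage=0.0)
        # independent oracle: pooled covariance and mean difference by hand
        X0, X1 = X[y == "a"], X[y == "b"]
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        S = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / (len(X) - 2)
        w_oracle = np.linalg.solve(S, mu1 - mu0)
        np.testing.assert_allclose(clf.weights, w_oracle, atol=1e-8)

    def test_slda_matches_sklearn_lda_direction(self, rng):
        """Cross-check against sklearn's LSQR LDA solver as an independent
        implementation (collinear weight vectors)."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = self._two_gaussians(rng, n=300, sep=3.0)
        clf = fit_classifier(X, y, kind="slda", shrinkage=0.0)
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None).fit(X, y)
        w1 = clf.weights / np.linalg.norm(clf.weights)
        w2 = sk.coef_.ravel() / np.linalg.norm(sk.coef_)
        np.testing.assert_allclose(abs(w1 @ w2), 1.0, atol=1e-8)

    def test_posteriors_are_probabilities(self, rng):
        X, y = self._two_gaussians(rng, sep=2.0)
        for kind in ("logistic", "slda"):
            p = fit_classifier(X, y, kind=kind).predict_proba(X)
            assert np.all(p >= 0) and np.all(p <= 1)
            assert np.any((p > 0.05) & (p < 0.95))  # interior mass, not saturated
            np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_slda_invariant_to_feature_translation(self, rng):
        """Translating all features leaves sLDA decisions unchanged."""
        X, y = self._two_gaussians(rng, sep=3.0)
        pred = fit_classifier(X, y, "slda", shrinkage=0.1).predict(X)
        pred_shift = fit_classifier(X + 100.0, y, "slda", shrinkage=0.1).predict(X + 100.0)
        assert np.array_equal(pred, pred_shift)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            fit_classifier(X, np.array(["a"] * 10))

    def test_invalid_shrinkage_rejected(self, rng):
        X, y = self._two_gaussians(rng, n=20)
        with pytest.raises(ValueError, match="shrinkage"):
            fit_classifier(X, y, kind="slda", shrinkage=1.5)


class TestKfold:
    def test_separable_data_scores_one(self, rng):
        X, y = TestClassifiers._two_gaussians(rng, n=50)
        m = kfold_scores(X, y, k=5)
        assert m.accuracy == m.precision == m.recall == 1.0

    def test_confusion_counts_all_validation_predictions(self, rng):
        X, y = TestClassifiers._two_gaussians(rng, n=50, sep=1.0)
        m = kfold_scores(X, y, k=5)
        assert m.confusion.sum() == 100

    def test_permuted_labels_near_chance(self, rng):
        X, _ = TestClassifiers._two_gaussians(rng, n=200, sep=5.0)
        accs = []
        for s in range(5):
            y_perm = np.random.default_rng(s).permutation(["a", "b"] * 200)
            accs.append(kfold_scores(X, y_perm, k=5, seed=s).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.08

    def test_k_exceeding_class_count_rejected(self, rng):
        X = rng.standard_normal((6, 3))
        y = np.array(["a", "a", "a", "a", "b", "b"])
        with pytest.raises(ValueError, match="smallest class"):
            kfold_scores(X, y, k=3)


class TestSklearnCompat:
    def test_shrinkage_lda_estimator_roundtrip(self, rng):
        from sklearn.base import clone

        X, y = TestClassifiers._two_gaussians(rng, n=50)
        est = ShrinkageLDA(shrinkage=0.2)
        assert clone(est).get_params()["shrinkage"] == 0.2
        est.fit(X, y)
        assert est.predict(X).shape == (100,)
        assert est.score(X, y) == 1.0
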