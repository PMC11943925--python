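import numpy as np
import pytest

from uromet.io import ValidationError
from uromet.plsda import (
    cross_validate_q2,
    encode_labels,
    fit_plsda,
    scale_matrix,
    vip_scores,
    PlsdaModel,
)


def labels_of(n_control, n_study):
    return ["control"] * n_control + ["study"] * n_study


def random_two_group(rng, n_per_group=10, k=10, effect=0.0, n_affected=0):
    X = rng.normal(size=(2 * n_per_group, k))
    if n_affected:
        X[n_per_group:, :n_affected] += effect
    return X, labels_of(n_per_group, n_per_group)


class TestScaleMatrix:
    def test_centering_and_uv(self):
        xs, centers, scales = scale_matrix(np.array([[1.0], [3.0]]), "uv")
        np.testing.assert_allclose(centers, [2.0])
        # SD with n-1 denominator is sqrt(2)
        np.testing.assert_allclose(xs[:, 0], [-0.70710678, 0.70710678])

    def test_mode_none_centers_only(self, rng):
        X = rng.normal(5, 2, size=(6, 3))
        xs, _, scales = scale_matrix(X, "none")
        np.testing.assert_allclose(xs.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_array_equal(scales, 1.0)

    def test_pareto_divides_by_root_sd(self):
        col = np.array([0.0, 4.0, 8.0, 12.0])  # sd using n-1 is ~5.164
        xs, _, scales = scale_matrix(col[:, None], "pareto")
        np.testing.assert_allclose(scales, np.sqrt(col.std(ddof=1)))

    def test_zero_variance_column_warns_and_keeps_scale_one(self):
        X = np.array([[1.0, 2.0], [1.0, 3.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            _, _, scales = scale_matrix(X, "uv")
        assert scales[0] == 1.0

    def test_single_row_is_error(self):
        with pytest.raises(ValidationError):
            scale_matrix(np.ones((1, 3)), "uv")


class TestFitPlsda:
    def test_perfect_single_predictor_explains_everything(self):
        y = np.array([-1.0, -1, -1, 1, 1, 1])
        model = fit_plsda(y[:, None], labels_of(3, 3), n_components=1)
        assert model.r2y_cum == pytest.approx(1.0, abs=1e-12)

    def test_first_weight_proportional_to_xty(self, rng):
        X, labels = random_two_group(rng, n_per_group=3, k=4)
        model = fit_plsda(X, labels, n_components=1)
        xs, _, _ = scale_matrix(X, "uv")
        y = encode_labels(labels)
        w_direct = xs.T @ (y - y.mean())
        w_direct /= np.linalg.norm(w_direct)
        if w_direct[np.argmax(np.abs(w_direct))] < 0:
            w_direct = -w_direct
        np.testing.assert_allclose(model.x_weights[:, 0], w_direct, atol=1e-12)

    def test_scores_match_reference_implementation(self, rng):
        """Cross-check NIPALS scores against scikit-learn's PLS on 20x10."""
        from sklearn.cross_decomposition import PLSRegression

        X, labels = random_two_group(rng, n_per_group=10, k=10, effect=1.0,
                                     n_affected=3)
        model = fit_plsda(X, labels, n_components=2)
        ref = PLSRegression(n_components=2, scale=True)
        ref.fit(X, encode_labels(labels))
        for a in range(2):
            ours = model.x_scores[:, a]
            theirs = ref.x_scores_[:, a]
            sign = np.sign(ours @ theirs)
            np.testing.assert_allclose(ours, sign * theirs, atol=1e-8)

    def test_score_orthogonality(self, rng):
        X, labels = random_two_group(rng, n_per_group=12, k=20, effect=0.5,
                                     n_affected=5)
        model = fit_plsda(X, labels, n_components=4)
        T = model.x_scores
        gram = T.T @ T
        norms = np.sqrt(np.diag(gram))
        off = gram - np.diag(np.diag(gram))
        assert np.all(np.abs(off) <= 1e-8 * np.outer(norms, norms))

    def test_deflation_exhausts_rank(self, rng):
        X = rng.normal(size=(8, 5))
        labels = labels_of(4, 4)
        model = fit_plsda(X, labels, n_components=5, scaling="uv")
        xs, _, _ = scale_matrix(X, "uv")
        residual = xs - model.x_scores @ model.x_loadings.T
        assert np.linalg.norm(residual) <= 1e-8

    def test_components_beyond_rank_rejected(self, rng):
        X = rng.normal(size=(4, 10))
        with pytest.raises(ValidationError, match="rank"):
            fit_plsda(X, labels_of(2, 2), n_components=4)

    def test_reproducible_bit_for_bit(self, rng):
        X, labels = random_two_group(rng, n_per_group=8, k=12, effect=1.0,
                                     n_affected=2)
        a = fit_plsda(X, labels, n_components=2)
        b = fit_plsda(X.copy(), list(labels), n_components=2)
        assert a.to_json() == b.to_json()

    def test_serialization_roundtrip(self, rng):
        X, labels = random_two_group(rng, n_per_group=5, k=6)
        model = fit_plsda(X, labels, n_components=2)
        back = PlsdaModel.from_dict(model.to_dict())
        np.testing.assert_array_equal(back.x_scores, model.x_scores)
        np.testing.assert_array_equal(back.vip, model.vip)


class TestVip:
    def test_equal_weights_give_unit_vips(self):
        # X columns identical copies of the class vector -> equal weights
        y = np.array([-1.0, -1, 1, 1])
        X = np.tile(y[:, None], (1, 3)) + 1e-9 * np.arange(12).reshape(4, 3)
        model = fit_plsda(X, labels_of(2, 2), n_components=1)
        np.testing.assert_allclose(model.vip, 1.0, atol=1e-4)

    def test_mean_square_is_one(self, rng):
        for _ in range(5):
            X, labels = random_two_group(rng, n_per_group=9, k=17, effect=0.7,
                                         n_affected=4)
            model = fit_plsda(X, labels, n_components=3)
            assert np.mean(model.vip**2) == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_computed_formula(self, rng):
        X, labels = random_two_group(rng, n_per_group=4, k=3, effect=1.0,
                                     n_affected=1)
        model = fit_plsda(X, labels, n_components=2)
        k = 3
        ss = np.array([
            model.y_loadings[a] ** 2 * model.x_scores[:, a] @ model.x_scores[:, a]
            for a in range(2)
        ])
        expected = np.empty(k)
        for j in range(k):
            acc = 0.0
            for a in range(2):
                w = model.x_weights[:, a]
                acc += ss[a] * (w[j] / np.linalg.norm(w)) ** 2
            expected[j] = np.sqrt(k * acc / ss.sum())
        np.testing.assert_allclose(vip_scores(model), expected, atol=1e-12)

    def test_vip_ranking_recovers_affected_buckets(self, rng):
        """Top-|S| VIPs recover >=90% of a 10-bucket effect at 2 pooled SD."""
        recovered = 0
        total = 0
        for _ in range(5):
            X, labels = random_two_group(rng, n_per_group=15, k=114,
                                         effect=2.0, n_affected=10)
            model = fit_plsda(X, labels, n_components=2)
            top = np.argsort(-model.vip)[:10]
            recovered += np.sum(top < 10)
            total += 10
        assert recovered / total >= 0.9


class TestCrossValidation:
    def test_strong_effect_gives_high_q2(self, rng):
        X, labels = random_two_group(rng, n_per_group=14, k=10, effect=10.0,
                                     n_affected=3)
        assert cross_validate_q2(X, labels, n_components=2) > 0.9

    def test_permuted_labels_give_no_predictive_power(self, rng):
        X = rng.normal(size=(40, 20))
        labels = np.array(labels_of(20, 20))
        low = 0
        for _ in range(100):
            perm = rng.permutation(40)
            low += cross_validate_q2(X, list(labels[perm]), n_components=2) <= 0.05
        assert low >= 95  # >= 95% of permutations

    def test_q2_does_not_exceed_r2y(self, rng):
        wins = 0
        for _ in range(20):
            X, labels = random_two_group(rng, n_per_group=10, k=15, effect=1.0,
                                         n_affected=3)
            model = fit_plsda(X, labels, n_components=2)
            q2 = cross_validate_q2(X, labels, n_components=2)
            wins += q2 <= model.r2y_cum
        assert wins >= 18  # soft, statistical property

    def test_small_classes_still_balanced(self, rng):
        # class counts below the fold count: training folds keep both classes
        X, labels = random_two_group(rng, n_per_group=4, k=5, effect=5.0,
                                     n_affected=2)
        q2 = cross_validate_q2(X, labels, n_components=1, n_folds=7)
        assert np.isfinite(q2)

    def test_singleton_class_is_error(self, rng):
        X = rng.normal(size=(8, 4))
        labels = ["control"] + ["study"] * 7
        with pytest.raises(ValidationError, match="cross-validation"):
            cross_validate_q2(X, labels, n_components=1)
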