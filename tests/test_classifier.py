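import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ewhk import (
    EWHKClassifier,
    NotFittedError,
    ValidationError,
    entropy_weights,
    hyperplane_distance,
    weighted_distance,
)
from ewhk.classifier import fit as fit_model

from .oracles import brute_force_hknn, numeric_jc

matrices = arrays(
    float,
    st.tuples(st.integers(2, 8), st.integers(1, 6)),
    elements=st.floats(-5.0, 5.0, allow_nan=False, width=32),
)


class TestEntropyWeights:
    def test_uniform_feature_gets_zero_weight(self):
        ew = entropy_weights(np.array([[1.0, 2.0], [3.0, 2.0]]))
        np.testing.assert_allclose(ew.w, [1.0, 0.0], atol=1e-9)

    def test_equal_multiset_columns_get_equal_weights(self):
        ew = entropy_weights(np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 3.0]]))
        np.testing.assert_allclose(ew.w, [0.5, 0.5], atol=1e-12)

    def test_worked_positive_matrix(self):
        # direct evaluation of the weight formula with z-columns
        # (1/8, 2/8, 5/8) and (2/8, 4/8, 2/8)
        ew = entropy_weights(np.array([[1.0, 2.0], [2.0, 4.0], [5.0, 2.0]]))
        np.testing.assert_allclose(ew.w, [0.7710708, 0.2289292], atol=1e-6)
        assert ew.beta == pytest.approx(1 / np.log(3))

    @given(matrices)
    def test_weights_normalized_and_entropies_bounded(self, x):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate draws fall back to uniform
            ew = entropy_weights(x)
        assert abs(ew.w.sum() - 1.0) < 1e-12
        assert np.all(ew.w >= -1e-15)
        assert np.all((ew.h >= 0) & (ew.h <= 1 + 1e-12))

    def test_constant_column_zero_weight_even_when_signed(self):
        x = np.array([[-1.0, 4.0], [0.5, 4.0], [2.0, 4.0]])
        assert entropy_weights(x).w[1] == pytest.approx(0.0, abs=1e-9)

    def test_maximal_entropy_fallback_is_uniform(self):
        with pytest.warns(UserWarning, match="uniform"):
            ew = entropy_weights(np.array([[2.0, 3.0], [2.0, 3.0]]))
        np.testing.assert_allclose(ew.w, [0.5, 0.5])

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            entropy_weights(np.array([[1.0, 2.0]]))


class TestWeightedDistance:
    def test_identity_of_indiscernibles(self):
        x = np.array([0.3, -1.2, 4.0])
        assert weighted_distance(x, x, np.array([0.2, 0.3, 0.5])) == 0.0

    def test_uniform_weights_scale_euclidean(self):
        rng = np.random.default_rng(0)
        x, q = rng.standard_normal((2, 6))
        d = weighted_distance(x, q, np.full(6, 1 / 6))
        assert d == pytest.approx(np.linalg.norm(x - q) / np.sqrt(6))

    def test_hand_example(self):
        d = weighted_distance(np.array([1.0, 0.0]), np.zeros(2), np.array([0.25, 0.75]))
        assert d == pytest.approx(0.5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            weighted_distance(np.zeros(3), np.zeros(2), np.ones(3))


class TestHyperplaneDistance:
    def test_query_at_centroid_gives_zero(self):
        protos = np.array([[0.0, 0.0], [2.0, 2.0]])
        fit = hyperplane_distance(protos.mean(0), protos, np.array([0.5, 0.5]), lam=0.5)
        np.testing.assert_allclose(fit.alpha, 0.0, atol=1e-12)
        assert fit.jc == pytest.approx(0.0, abs=1e-14)

    def test_residual_orthogonal_to_degenerate_hyperplane(self):
        # hyperplane = x-axis through (1, 0); query (1, 1); singular basis
        fit = hyperplane_distance(
            np.array([1.0, 1.0]), np.array([[0.0, 0.0], [2.0, 0.0]]),
            np.array([0.5, 0.5]), lam=0.0,
        )
        assert fit.jc == pytest.approx(0.5)
        np.testing.assert_allclose(fit.alpha, 0.0, atol=1e-12)  # minimum norm

    def test_huge_ridge_collapses_to_centroid_distance(self):
        rng = np.random.default_rng(1)
        protos = rng.standard_normal((3, 4))
        q = rng.standard_normal(4)
        w = np.full(4, 0.25)
        fit = hyperplane_distance(q, protos, w, lam=1e12)
        centroid_dist = float(np.sum(w * (protos.mean(0) - q) ** 2))
        assert fit.jc == pytest.approx(centroid_dist, rel=1e-4)

    def test_ridge_monotone_in_lambda(self):
        rng = np.random.default_rng(2)
        protos = rng.standard_normal((4, 5))
        q = rng.standard_normal(5)
        w = np.full(5, 0.2)
        jcs = [hyperplane_distance(q, protos, w, lam=lam).jc
               for lam in (0.0, 0.01, 0.1, 1.0, 10.0)]
        assert all(a <= b + 1e-12 for a, b in zip(jcs, jcs[1:]))

    def test_matches_numeric_minimizer(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k, n = rng.integers(1, 5), rng.integers(2, 7)
            protos = rng.standard_normal((k, n))
            q = rng.standard_normal(n)
            w = rng.uniform(0.05, 1.0, n)
            w /= w.sum()
            lam = float(rng.choice([0.0, 0.1, 1.0]))
            fit = hyperplane_distance(q, protos, w, lam)
            expected = numeric_jc(q, protos, w, lam)
            assert fit.jc == pytest.approx(expected, rel=1e-6, abs=1e-9)

    def test_nan_inputs_rejected(self):
        with pytest.raises(ValidationError):
            hyperplane_distance(np.array([np.nan, 0.0]), np.zeros((1, 2)), np.ones(2), 0.0)


def _two_class_data(seed=0, m=20, n=4, shift=3.0):
    rng = np.random.default_rng(seed)
    xa = rng.standard_normal((m // 2, n))
    xb = rng.standard_normal((m - m // 2, n)) + shift
    x = np.vstack([xa, xb])
    y = np.array(["a"] * (m // 2) + ["b"] * (m - m // 2), dtype=object)
    return x, y


class TestClassifier:
    def test_training_row_recovered_with_k1(self):
        x, y = _two_class_data(seed=4)
        clf = EWHKClassifier(k=1, lam=0.0).fit(x, y)
        label, scores = clf.classify(x[3])
        assert label == y[3]
        assert scores[y[3]] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_tie_breaks_lexicographically(self):
        x = np.array([[-1.0, 0.0], [-2.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        y = np.array(["left", "left", "right", "right"], dtype=object)
        clf = EWHKClassifier(k=2, lam=0.0, mode="hknn").fit(x, y)
        label, scores = clf.classify(np.array([0.0, 1.0]))
        assert scores["left"] == pytest.approx(scores["right"])
        assert label == "left"

    def test_prototype_selection_matches_exhaustive_sort(self):
        x, y = _two_class_data(seed=5, m=12)
        clf = EWHKClassifier(k=3, lam=0.0).fit(x, y)
        q = np.zeros(x.shape[1])
        idx = clf.select_prototypes(q, "a")
        rows = np.flatnonzero(y == "a")
        d = [np.sqrt(np.sum(clf.feature_weights_ * (x[r] - q) ** 2)) for r in rows]
        expected = rows[np.argsort(d, kind="stable")][:3]
        np.testing.assert_array_equal(idx, expected)

    def test_k_saturates_at_class_size(self):
        x, y = _two_class_data(seed=6, m=8)
        clf = EWHKClassifier(k=50, lam=1.0).fit(x, y)
        assert clf.select_prototypes(np.zeros(x.shape[1]), "a").size == 4

    def test_uniform_mode_agrees_with_brute_force_hknn(self):
        x, y = _two_class_data(seed=7, m=16, shift=1.5)
        rng = np.random.default_rng(8)
        for lam in (0.0, 1.0):
            clf = EWHKClassifier(k=3, lam=lam, mode="hknn").fit(x, y)
            for _ in range(10):
                q = rng.standard_normal(x.shape[1]) + 0.75
                label, scores = clf.classify(q)
                expected_label, expected_scores = brute_force_hknn(x, y, q, k=3, lam=lam)
                assert label == expected_label
                for c in scores:
                    assert scores[c] == pytest.approx(expected_scores[c], rel=1e-5, abs=1e-8)

    def test_k1_reduces_to_weighted_nearest_neighbor(self):
        x, y = _two_class_data(seed=9)
        clf = EWHKClassifier(k=1, lam=0.0).fit(x, y)
        rng = np.random.default_rng(10)
        for _ in range(10):
            q = rng.standard_normal(x.shape[1]) * 2
            _, scores = clf.classify(q)
            for c in ("a", "b"):
                rows = x[y == c]
                d2 = np.min(np.sum(clf.feature_weights_ * (rows - q) ** 2, axis=1))
                assert scores[c] == pytest.approx(d2, rel=1e-12)

    def test_predictions_invariant_to_row_permutation(self):
        x, y = _two_class_data(seed=11, shift=1.0)
        queries = np.random.default_rng(12).standard_normal((15, x.shape[1]))
        base = EWHKClassifier(k=4, lam=0.5).fit(x, y).predict(queries)
        perm = np.random.default_rng(13).permutation(len(y))
        permuted = EWHKClassifier(k=4, lam=0.5).fit(x[perm], y[perm]).predict(queries)
        np.testing.assert_array_equal(base, permuted)

    def test_fit_is_deterministic(self):
        x, y = _two_class_data(seed=14)
        a = EWHKClassifier().fit(x, y)
        b = EWHKClassifier().fit(x, y)
        np.testing.assert_array_equal(a.feature_weights_, b.feature_weights_)
        q = np.zeros(x.shape[1])
        assert a.classify(q) == b.classify(q)

    def test_uniform_mode_forces_unit_weights(self):
        x, y = _two_class_data(seed=15)
        clf = EWHKClassifier(mode="hknn").fit(x, y)
        np.testing.assert_array_equal(clf.feature_weights_, np.ones(x.shape[1]))

    def test_constant_feature_gets_zero_weight_after_fit(self):
        x, y = _two_class_data(seed=16)
        x = np.hstack([x, np.full((len(y), 1), 2.5)])
        clf = EWHKClassifier().fit(x, y)
        assert clf.feature_weights_[-1] == pytest.approx(0.0, abs=1e-9)

    def test_single_class_training_warns_and_degenerates(self):
        x = np.random.default_rng(17).standard_normal((5, 3))
        with pytest.warns(UserWarning, match="single-class"):
            clf = EWHKClassifier(k=2, lam=0.1).fit(x, ["only"] * 5)
        assert clf.classify(np.zeros(3))[0] == "only"

    def test_unfitted_model_raises(self):
        with pytest.raises(NotFittedError):
            EWHKClassifier().classify(np.zeros(3))

    def test_fit_convenience_wrapper(self, synth_ds):
        model = fit_model(synth_ds, k=3, lam=0.5, mode="hknn")
        assert model.classes_ == ["cancer", "colitis"]

    @pytest.mark.parametrize("kwargs", [{"k": 0}, {"lam": -1.0}, {"mode": "knn"}])
    def test_invalid_hyperparameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            EWHKClassifier(**kwargs)
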