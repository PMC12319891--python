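import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import speechtrf as st
from speechtrf.inventory import PhonemeInventory


@pytest.fixture
def one_hot_inventory():
    """Each phoneme carries exactly one unique feature: rotation should
    reduce to selecting that feature's weights."""
    labels = ("P1", "P2", "P3", "P4")
    mat = np.zeros((4, 19))
    mat[np.arange(4), [0, 3, 7, 12]] = 1.0
    return PhonemeInventory(labels, mat)


def _feature_model(weights, fs=100.0):
    from speechtrf.inventory import FEATURE_LABELS

    n_lags, _, n_ch = weights.shape
    window = (0.0, (n_lags - 1) * 1000.0 / fs)
    return st.TRFModel(weights, np.zeros(n_ch), 1.0, window, fs, FEATURE_LABELS)


class TestRotation:
    def test_one_hot_rotation_is_a_permutation(self, one_hot_inventory, rng):
        w = rng.normal(size=(11, 19, 3))
        pw = st.rotate_to_phonemes(_feature_model(w), one_hot_inventory)
        np.testing.assert_allclose(pw.weights[:, 0], w[:, 0])
        np.testing.assert_allclose(pw.weights[:, 1], w[:, 3])
        np.testing.assert_allclose(pw.weights[:, 2], w[:, 7])
        np.testing.assert_allclose(pw.weights[:, 3], w[:, 12])

    def test_zero_weights_stay_zero(self, inventory):
        pw = st.rotate_to_phonemes(_feature_model(np.zeros((11, 19, 2))), inventory)
        assert not pw.weights.any()

    def test_normalized_variant_averages(self, inventory, rng):
        w = rng.normal(size=(5, 19, 2))
        raw = st.rotate_to_phonemes(_feature_model(w), inventory)
        norm = st.rotate_to_phonemes(_feature_model(w), inventory, normalize=True)
        counts = inventory.feature_matrix.sum(axis=1)
        np.testing.assert_allclose(
            norm.weights, raw.weights / counts[None, :, None]
        )

    def test_missing_feature_columns_rejected(self, inventory, rng):
        m = st.TRFModel(rng.normal(size=(5, 2, 2)), np.zeros(2), 1.0,
                        (0.0, 40.0), 100.0, ("env", "surprisal"))
        with pytest.raises(ValueError, match="phonetic-feature"):
            st.rotate_to_phonemes(m, inventory)


class TestDistanceMatrix:
    def _pw(self, w, fs=100.0):
        labels = tuple(f"p{i}" for i in range(w.shape[1]))
        return st.PhonemeWeights(w, labels, (0.0, (w.shape[0] - 1) * 10.0), fs)

    def test_identical_weights_zero_distance(self, rng):
        w = rng.normal(size=(6, 3, 2))
        w[:, 1] = w[:, 0]
        D = st.phoneme_distance_matrix(self._pw(w))
        assert D[0, 1] == 0.0

    def test_single_entry_difference(self):
        w = np.zeros((6, 2, 2))
        w[3, 1, 0] = 0.75
        D = st.phoneme_distance_matrix(self._pw(w))
        assert D[0, 1] == pytest.approx(0.75)

    def test_matches_double_loop_oracle(self, rng):
        w = rng.normal(size=(8, 5, 4))
        D = st.phoneme_distance_matrix(self._pw(w))
        for p in range(5):
            for q in range(5):
                expect = np.linalg.norm(w[:, p, :] - w[:, q, :])
                assert D[p, q] == pytest.approx(expect)

    def test_invariant_to_channel_order_and_rotation(self, rng):
        w = rng.normal(size=(8, 5, 4))
        D = st.phoneme_distance_matrix(self._pw(w))
        perm = self._pw(w[:, :, [2, 0, 3, 1]])
        np.testing.assert_allclose(st.phoneme_distance_matrix(perm), D)
        # orthogonal mix applied jointly over the flattened vectors
        flat = w.transpose(1, 0, 2).reshape(5, -1)
        Q = np.linalg.qr(rng.normal(size=(32, 32)))[0]
        mixed = (flat @ Q).reshape(5, 8, 4).transpose(1, 0, 2)
        np.testing.assert_allclose(
            st.phoneme_distance_matrix(self._pw(mixed)), D, atol=1e-9
        )

    def test_empty_selection_rejected(self, rng):
        pw = self._pw(rng.normal(size=(8, 3, 2)))
        with pytest.raises(ValueError):
            st.phoneme_distance_matrix(pw, channels=[])


class TestClassicalMDS:
    def test_colinear_points_recover_spacing(self):
        x = np.array([[0.0], [1.0], [3.0]])
        D = squareform(pdist(x))
        y = st.classical_mds(D, 1)[:, 0]
        gaps = np.abs(np.diff(y))
        np.testing.assert_allclose(sorted(gaps), [1.0, 2.0], atol=1e-9)

    def test_planar_round_trip_through_procrustes(self, rng):
        X = rng.normal(size=(12, 2))
        D = squareform(pdist(X))
        Y = st.classical_mds(D, 2)
        res = st.procrustes_align(Y, X)
        assert res.per_phoneme_residual.max() < 1e-8

    def test_equilateral_three_points(self):
        D = np.ones((3, 3)) - np.eye(3)
        Y = st.classical_mds(D, 2)
        d = pdist(Y)
        np.testing.assert_allclose(d, d[0], rtol=1e-9)

    def test_k_truncated_with_warning(self):
        x = np.array([[0.0], [1.0], [2.5]])
        D = squareform(pdist(x))
        with pytest.warns(UserWarning, match="truncated"):
            Y = st.classical_mds(D, 3)
        assert Y.shape == (3, 3)
        assert np.allclose(Y[:, 1:], 0.0, atol=1e-8)


class TestProcrustes:
    def test_fixed_point(self, rng):
        X = rng.normal(size=(10, 2))
        res = st.procrustes_align(X, X)
        assert res.per_phoneme_residual.max() < 1e-12
        assert res.dissimilarity == pytest.approx(0.0, abs=1e-12)

    def test_similarity_transform_removed(self, rng):
        X = rng.normal(size=(10, 2))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        Y = 2.3 * X @ R + np.array([5.0, -1.0])
        res = st.procrustes_align(Y, X)
        assert res.per_phoneme_residual.max() < 1e-10

    def test_reflection_permitted(self, rng):
        X = rng.normal(size=(8, 2))
        Y = X @ np.diag([1.0, -1.0])
        res = st.procrustes_align(Y, X)
        assert res.per_phoneme_residual.max() < 1e-10

    def test_perturbed_point_carries_largest_residual(self, rng):
        X = rng.normal(size=(10, 2))
        Xp = X.copy()
        Xp[4] += 2.0
        res = st.procrustes_align(X, Xp)
        assert int(np.argmax(res.per_phoneme_residual)) == 4

    def test_residuals_invariant_to_source_similarity_transform(self, rng):
        S = rng.normal(size=(9, 2))
        R = rng.normal(size=(9, 2))
        base = st.procrustes_align(S, R).per_phoneme_residual
        th = -1.1
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = 0.4 * S @ Q + np.array([-2.0, 7.0])
        np.testing.assert_allclose(
            st.procrustes_align(moved, R).per_phoneme_residual, base, atol=1e-9
        )

    def test_degenerate_source_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            st.procrustes_align(np.ones((5, 2)), np.random.default_rng(0).normal(size=(5, 2)))


class TestResidualTable:
    def _map(self, coords, labels):
        D = squareform(pdist(coords))
        return st.PhonemeMap(coords, D, labels, coords.shape[1])

    def test_copies_of_reference_have_zero_residuals(self, rng):
        labels = tuple("abcde")
        ref = self._map(rng.normal(size=(5, 2)), labels)
        cohort = {(p, c): ref for p in range(3) for c in ("A", "B")}
        tab = st.residual_distance_table(cohort, ref)
        assert np.allclose(tab["residual"], 0.0, atol=1e-10)

    def test_row_count_bookkeeping(self, rng):
        labels = tuple("abcd")
        ref = self._map(rng.normal(size=(4, 2)), labels)
        cohort = {
            (p, c): self._map(rng.normal(size=(4, 2)), labels)
            for p in range(3)
            for c in ("A", "B")
        }
        tab = st.residual_distance_table(cohort, ref)
        assert len(tab) == 3 * 2 * 4

    def test_inventory_mismatch_rejected(self, rng):
        ref = self._map(rng.normal(size=(4, 2)), tuple("abcd"))
        other = self._map(rng.normal(size=(4, 2)), tuple("wxyz"))
        with pytest.raises(ValueError, match="mismatch"):
            st.residual_distance_table({(0, "A"): other}, ref)
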