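"""Seizure distances: reconstructions, distance matrices, DTW."""

import numpy as np
import pytest

from seizmod.memd import IMFSet
from seizmod.seizdist import (
    SeizureTable,
    distance_stack,
    dtw_dissimilarity,
    dtw_pair,
    imf_seizure_distance,
    reconstruct_imf_space,
    temporal_distance,
)


def _toy_imfset(k=1, T=6):
    rng = np.random.default_rng(0)
    imfs = rng.standard_normal((3, k, T))
    residue = rng.standard_normal((k, T))
    return IMFSet(imfs=imfs, residue=residue)


class TestSeizureTable:
    def test_onset_epochs_are_floor_division(self):
        st = SeizureTable([10.0, 61.0, 95.0], 30.0, 10)
        assert np.array_equal(st.onset_epochs, [0, 2, 3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SeizureTable([10.0, 400.0], 30.0, 10)

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SeizureTable([50.0, 40.0], 30.0, 10)

    def test_shared_epoch_warns(self):
        with pytest.warns(UserWarning, match="share"):
            SeizureTable([10.0, 20.0], 30.0, 10)


class TestReconstruction:
    def test_hand_example_k1(self):
        s = IMFSet(imfs=np.array([[[0.3, -0.1]]]), residue=np.zeros((1, 2)))
        recons, _ = reconstruct_imf_space(np.array([[1.0], [1.0]]), s)
        assert np.allclose(recons[0], [[0.3, -0.1], [0.3, -0.1]])

    def test_zero_imf_zero_reconstruction(self):
        s = IMFSet(imfs=np.zeros((2, 2, 5)), residue=np.zeros((2, 5)))
        recons, resid = reconstruct_imf_space(np.ones((6, 2)), s)
        assert all(np.all(r == 0) for r in recons)
        assert np.all(resid == 0)

    def test_additivity_matches_full_reconstruction(self):
        s = _toy_imfset(k=2, T=8)
        W = np.random.default_rng(1).random((10, 2))
        recons, resid = reconstruct_imf_space(W, s)
        total = sum(recons) + resid
        H = s.reconstruct()
        assert np.allclose(total, W @ H, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_imf_space(np.ones((4, 3)), _toy_imfset(k=2))


class TestImfDistance:
    def test_symmetric_zero_diagonal(self):
        s = _toy_imfset(k=2, T=20)
        X = np.random.default_rng(2).random((8, 20))
        st = SeizureTable([35.0, 200.0, 411.0], 30.0, 20)
        D = imf_seizure_distance(X, st)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)
        assert D.min() >= 0

    def test_hand_computed_distance(self):
        # columns (0.3, 0.3) and (-0.1, -0.1): distance sqrt(2 * 0.4^2)
        X = np.array([[0.3, -0.1], [0.3, -0.1]])
        st = SeizureTable([10.0, 40.0], 30.0, 2)
        D = imf_seizure_distance(X, st)
        assert D[0, 1] == pytest.approx(np.sqrt(2 * 0.4**2))

    def test_duplicated_rows_scale_by_sqrt2(self):
        rng = np.random.default_rng(3)
        X = rng.random((5, 10))
        st = SeizureTable([35.0, 125.0, 275.0], 30.0, 10)
        D1 = imf_seizure_distance(X, st)
        D2 = imf_seizure_distance(np.vstack([X, X]), st)
        assert np.allclose(D2, np.sqrt(2) * D1)

    def test_lag_reads_previous_epoch(self):
        X = np.arange(12.0).reshape(2, 6)
        st = SeizureTable([65.0, 155.0], 30.0, 6)
        D0 = imf_seizure_distance(X, st, lag=0)
        D1 = imf_seizure_distance(X, st, lag=1)
        assert D0[0, 1] == pytest.approx(np.linalg.norm(X[:, 2] - X[:, 5]))
        assert D1[0, 1] == pytest.approx(np.linalg.norm(X[:, 1] - X[:, 4]))

    def test_lag_underflow_rejected(self):
        X = np.zeros((2, 6))
        st = SeizureTable([10.0, 155.0], 30.0, 6)
        with pytest.raises(ValueError):
            imf_seizure_distance(X, st, lag=1)


class TestTemporalDistance:
    def test_hand_example(self):
        st = SeizureTable([100.0, 400.0], 30.0, 100)
        D = temporal_distance(st)
        assert D[0, 1] == 300.0 and D[1, 0] == 300.0 and D[0, 0] == 0.0

    def test_rows_increase_away_from_diagonal(self):
        st = SeizureTable([100.0, 700.0, 1500.0, 2900.0], 30.0, 100)
        D = temporal_distance(st)
        for i in range(4):
            row = D[i]
            assert (np.diff(row[i:]) > 0).all() and (np.diff(row[: i + 1]) < 0).all()

    def test_triangle_inequality(self):
        st = SeizureTable([40.0, 500.0, 777.0, 1234.0], 30.0, 100)
        D = temporal_distance(st)
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


def _brute_dtw(a, b):
    """Memoized recursive DTW with the same diagonal-first tie precedence
    (independent oracle for the dynamic program)."""
    from functools import lru_cache

    from scipy.spatial.distance import cdist

    cost = cdist(a, b)

    @lru_cache(maxsize=None)
    def acc(i, j):
        if i == 0 and j == 0:
            return cost[0, 0]
        best = np.inf
        if i and j:
            best = min(best, acc(i - 1, j - 1))
        if j:
            best = min(best, acc(i, j - 1))
        if i:
            best = min(best, acc(i - 1, j))
        return cost[i, j] + best

    total = acc(len(a) - 1, len(b) - 1)
    i, j = len(a) - 1, len(b) - 1
    length = 1
    while i or j:
        if i and j:
            options = (acc(i - 1, j - 1), acc(i, j - 1), acc(i - 1, j))
            c = int(np.argmin(options))
            if c == 0:
                i, j = i - 1, j - 1
            elif c == 1:
                j -= 1
            else:
                i -= 1
        elif i:
            i -= 1
        else:
            j -= 1
        length += 1
    return total / length


class TestDTW:
    def test_identical_sequences_give_zero(self):
        a = np.random.default_rng(4).random((7, 2))
        assert dtw_pair(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_time_dilated_copy_gives_zero(self):
        a = np.random.default_rng(5).random((6, 2))
        doubled = np.repeat(a, 2, axis=0)
        assert dtw_pair(a, doubled) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            a = rng.random((rng.integers(3, 9), 2))
            b = rng.random((rng.integers(3, 9), 2))
            assert dtw_pair(a, b) == pytest.approx(_brute_dtw(a, b), abs=1e-12)

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValueError, match="feature"):
            dtw_pair(np.zeros((3, 2)), np.zeros((3, 3)))

    def test_matrix_is_symmetric_nonnegative(self):
        rng = np.random.default_rng(7)
        evos = [rng.random((rng.integers(4, 8), 2)) for _ in range(5)]
        D = dtw_dissimilarity(evos)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0) and D.min() >= 0


def test_distance_stack_labels_and_validity():
    s = _toy_imfset(k=2, T=30)
    W = np.random.default_rng(8).random((10, 2))
    st = SeizureTable([65.0, 300.0, 600.0, 880.0], 30.0, 30)
    stack = distance_stack(W, s, st)
    assert stack.labels == ["IMF1", "IMF2", "IMF3", "residue", "temporal"]
    assert stack.D.shape == (5, 4, 4)
    for sl in stack.D:
        assert np.allclose(sl, sl.T) and np.all(np.diag(sl) == 0) and sl.min() >= 0
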