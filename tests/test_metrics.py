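"""Similarity metrics against brute-force oracles and closed forms."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eeggan import (compare_sets, dtw_distance, frechet_distance, rmse,
                    spectrogram)
from eeggan.preprocess import DataError


# -- brute-force oracles -----------------------------------------------------

def dtw_bruteforce(q, c):
    """Enumerate every monotone warping path through the alignment grid."""
    n, m = len(q), len(c)
    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + abs(q[i] - c[j])
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, acc)

    walk(0, 0, 0.0)
    return best[0]


def frechet_bruteforce(p, q):
    """Enumerate every order-preserving coupling; min over couplings of the
    max pairwise distance."""
    p, q = np.atleast_2d(p), np.atleast_2d(q)
    n, m = len(p), len(q)
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(-1))
    best = [np.inf]

    def walk(i, j, acc):
        acc = max(acc, d[i, j])
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, acc)

    walk(0, 0, 0.0)
    return best[0]


# -- RMSE --------------------------------------------------------------------

class TestRMSE:
    def test_identity_is_zero(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_direct_formula(self):
        assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))

    def test_constant_offset(self, rng):
        x = rng.normal(size=50)
        assert rmse(x, x + 2.5) == pytest.approx(2.5)

    def test_length_mismatch(self):
        with pytest.raises(DataError, match="length mismatch"):
            rmse([1, 2], [1, 2, 3])


# -- DTW ---------------------------------------------------------------------

class TestDTW:
    @pytest.mark.parametrize("q,c,expected", [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 2, 3], [1, 3], 1.0),
        ([0], [0, 0, 0], 0.0),
    ])
    def test_known_values(self, q, c, expected):
        assert dtw_distance(q, c) == pytest.approx(expected)

    def test_symmetric(self, rng):
        q, c = rng.normal(size=6), rng.normal(size=4)
        assert dtw_distance(q, c) == pytest.approx(dtw_distance(c, q))

    def test_shift_invariance(self, rng):
        q, c = rng.normal(size=5), rng.normal(size=5)
        assert dtw_distance(q + 3.0, c + 3.0) == pytest.approx(dtw_distance(q, c))

    @settings(derandomize=True, max_examples=120)
    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=5),
           st.lists(st.integers(-5, 5), min_size=1, max_size=5))
    def test_matches_bruteforce(self, q, c):
        q, c = np.array(q, float), np.array(c, float)
        assert dtw_distance(q, c) == pytest.approx(dtw_bruteforce(q, c))


# -- Fréchet -----------------------------------------------------------------

class TestFrechet:
    def test_identical_curves(self):
        p = [(0, 0), (1, 1), (2, 0)]
        assert frechet_distance(p, p) == 0.0

    def test_parallel_segments(self):
        assert frechet_distance([(0, 0), (1, 0)], [(0, 1), (1, 1)]) == pytest.approx(1.0)

    def test_single_point_couples_to_all(self):
        assert frechet_distance([(0, 0)], [(0, 3), (4, 0)]) == pytest.approx(4.0)

    def test_symmetric(self, rng):
        p, q = rng.normal(size=(4, 2)), rng.normal(size=(6, 2))
        assert frechet_distance(p, q) == pytest.approx(frechet_distance(q, p))

    def test_endpoint_lower_bound(self, rng):
        p, q = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
        lb = max(np.linalg.norm(p[0] - q[0]), np.linalg.norm(p[-1] - q[-1]))
        assert frechet_distance(p, q) >= lb - 1e-12

    def test_rigid_shift_invariance(self, rng):
        p, q = rng.normal(size=(4, 2)), rng.normal(size=(3, 2))
        shift = np.array([2.0, -5.0])
        assert frechet_distance(p + shift, q + shift) == \
            pytest.approx(frechet_distance(p, q))

    @settings(derandomize=True, max_examples=120)
    @given(st.lists(st.tuples(st.integers(-4, 4), st.integers(-4, 4)),
                    min_size=1, max_size=5),
           st.lists(st.tuples(st.integers(-4, 4), st.integers(-4, 4)),
                    min_size=1, max_size=5))
    def test_matches_bruteforce(self, p, q):
        p, q = np.array(p, float), np.array(q, float)
        assert frechet_distance(p, q) == pytest.approx(frechet_bruteforce(p, q))


# -- set-level aggregation ---------------------------------------------------

class TestCompareSets:
    def test_identical_sets_all_zero(self, rng):
        X = rng.normal(size=(4, 12))
        rep = compare_sets(X, X.copy(), "paired_mean")
        assert (rep.rmse, rep.fd, rep.dtw) == (0.0, 0.0, 0.0)
        assert rep.n_pairs == 4

    def test_duplicates_of_single_real_frame(self, rng):
        r = rng.normal(size=(1, 10))
        gen = np.vstack([r, r])
        for agg in ("nearest_real_mean",):
            rep = compare_sets(r, gen, agg)
            assert (rep.rmse, rep.fd, rep.dtw) == (0.0, 0.0, 0.0)

    def test_hand_computed_pairs(self):
        real = np.array([[0.0, 0, 0, 0], [1.0, 1, 1, 1]])
        gen = np.array([[0.0, 0, 0, 2.0], [1.0, 1, 1, 1]])
        rep = compare_sets(real, gen, "paired_mean")
        assert rep.rmse == pytest.approx((np.sqrt(4 / 4) + 0) / 2)
        # warping cannot dodge the mismatched endpoint: per-pair DTW cost is 2
        assert rep.dtw == pytest.approx((2.0 + 0) / 2)
        assert rep.fd == pytest.approx((2.0 + 0) / 2)

    def test_count_mismatch_rejected_in_paired_mode(self, rng):
        with pytest.raises(DataError, match="equal frame counts"):
            compare_sets(rng.normal(size=(3, 5)), rng.normal(size=(2, 5)))


# -- spectrogram -------------------------------------------------------------

class TestSpectrogram:
    def test_pure_sine_peaks_at_its_frequency(self):
        fs = 250.0
        t = np.arange(500) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        freqs, times, S = spectrogram(x, sampling_rate=fs, window=128)
        peak = freqs[np.argmax(S.mean(axis=1))]
        assert abs(peak - 10.0) <= fs / 128  # one bin

    def test_zero_signal_all_zero(self):
        freqs, times, S = spectrogram(np.zeros(300), window=64)
        assert np.all(S == 0)

    def test_parseval_normalization(self, rng):
        x = rng.normal(size=256)
        freqs, times, S = spectrogram(x, window=64, overlap=0, window_fn="boxcar")
        from scipy.signal import get_window
        for k, s in enumerate(range(0, 256 - 64 + 1, 64)):
            seg = x[s:s + 64]
            assert S[:, k].sum() == pytest.approx(np.mean(seg ** 2), rel=1e-10)

    def test_white_noise_roughly_flat(self):
        x = np.random.default_rng(0).normal(size=4096)
        freqs, times, S = spectrogram(x, window=64)
        mean_power = S.mean(axis=1)[1:-1]
        assert mean_power.max() / mean_power.min() < 3.0

    def test_window_larger_than_frame_rejected(self):
        with pytest.raises(DataError, match="window"):
            spectrogram(np.zeros(50), window=64)
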