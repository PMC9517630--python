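"""Entropy estimators vs independent oracles, and feature-matrix assembly."""

import math

import numpy as np
import pytest

from preictal.entropy import (FEATURES, FeatureParams, approximate_entropy,
                              build_feature_matrix, distribution_entropy,
                              feature_names, permutation_entropy,
                              read_feature_csv, sample_entropy,
                              spectral_entropy, wavelet_entropy,
                              write_feature_csv)
from preictal.segmentation import Segment


# ---------------------------------------------------------------------------
# brute-force oracles (vectorized pairwise matrices; an independent path
# from the compiled pair-scan in the package)
# ---------------------------------------------------------------------------

def _cheb_matrix(x, m):
    idx = np.arange(len(x) - m + 1)[:, None] + np.arange(m)[None, :]
    emb = x[idx]
    return np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)


def apen_oracle(x, m, r):
    n = len(x)
    phis = []
    for mm in (m, m + 1):
        d = _cheb_matrix(x, mm)
        c = (d <= r).mean(axis=1)          # self-match included
        phis.append(np.log(c).mean())
    return phis[0] - phis[1]


def sampen_oracle(x, m, r):
    n = len(x)
    nt = n - m                              # templates compared at both dims
    dm = _cheb_matrix(x, m)[:nt, :nt]
    dm1 = _cheb_matrix(x, m + 1)
    iu = np.triu_indices(nt, k=1)
    b = int((dm[iu] <= r).sum())
    a = int((dm1[np.triu_indices(n - m, k=1)] <= r).sum())
    if a == 0 or b == 0:
        return float("inf")
    return -math.log(a / b)


class TestApproximateEntropy:
    def test_constant_series_is_zero(self):
        assert approximate_entropy(np.full(64, 3.0), m=2, r=0.1) == 0.0

    def test_matches_bruteforce_on_random_series(self, rng):
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(50, 201))
            x = rng.standard_normal(n)
            r = 0.2 * x.std()
            worst = max(worst, abs(approximate_entropy(x, 2, r)
                                   - apen_oracle(x, 2, r)))
        assert worst <= 1e-12

    def test_sine_more_regular_than_its_shuffle(self, rng):
        t = np.arange(2560) / 256.0
        sine = np.sin(2 * np.pi * 5 * t)
        shuffled = rng.permutation(sine)
        assert approximate_entropy(sine, 2, 0.2 * sine.std()) < \
            approximate_entropy(shuffled, 2, 0.2 * shuffled.std())

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="N > m"):
            approximate_entropy(np.zeros(3), m=2, r=0.1)


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(64, 1.0), m=2, r=0.1) == 0.0

    def test_matches_bruteforce_on_random_series(self, rng):
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(50, 201))
            x = rng.standard_normal(n)
            r = 0.2 * x.std()
            got = sample_entropy(x, 2, r)
            want = sampen_oracle(x, 2, r)
            if math.isinf(want):
                assert math.isinf(got)
            else:
                worst = max(worst, abs(got - want))
        assert worst <= 1e-12

    def test_no_matches_yields_infinity(self):
        x = np.arange(50, dtype=float)
        assert math.isinf(sample_entropy(x, m=2, r=0.5))


class TestPermutationEntropy:
    def test_monotone_series_is_zero(self):
        assert permutation_entropy(np.arange(100, dtype=float), m=3) == 0.0
        assert permutation_entropy(np.arange(100, dtype=float), m=5) == 0.0

    def test_hand_enumerated_case(self):
        # (3,1,2,4), m=2: patterns down, up, up -> H = 0.6365, PEn = 0.9183
        got = permutation_entropy(np.array([3.0, 1.0, 2.0, 4.0]), m=2, tau=1)
        p = np.array([2 / 3, 1 / 3])
        want = -(p * np.log(p)).sum() / math.log(2)
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(0.9183, abs=1e-4)

    def test_pattern_uniform_series_is_one(self):
        # strict zig-zag of odd length: equal counts of the two m=2 patterns
        x = np.array([0.0, 2.0, 1.0, 3.0, 2.0, 4.0, 3.0], dtype=float)
        assert permutation_entropy(x, m=2, tau=1) == pytest.approx(1.0)

    def test_bounds(self, rng):
        x = rng.standard_normal(500)
        assert 0.0 <= permutation_entropy(x, m=3) <= 1.0


class TestSpectralEntropy:
    def test_single_bin_sine_is_zero(self):
        t = np.arange(2560) / 256.0
        x = np.sin(2 * np.pi * 12.8 * t)   # 12.8 Hz aligns to a 0.1 Hz bin
        assert spectral_entropy(x, 256.0) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_sines_give_ln2(self):
        t = np.arange(2560) / 256.0
        x = np.sin(2 * np.pi * 12.8 * t) + np.sin(2 * np.pi * 25.6 * t)
        assert spectral_entropy(x, 256.0) == pytest.approx(math.log(2),
                                                           abs=1e-10)

    def test_entropy_bounds(self, rng):
        x = rng.standard_normal(1024)
        n_bins = 1024 // 2 + 1
        assert 0.0 <= spectral_entropy(x, 256.0) <= math.log(n_bins)

    def test_zero_signal_flagged_as_zero(self):
        assert spectral_entropy(np.zeros(64), 256.0) == 0.0


class TestWaveletEntropy:
    def test_equal_energy_scales_give_log_count(self):
        assert distribution_entropy(np.ones(5)) == pytest.approx(math.log(5))

    def test_energy_in_one_scale_near_zero(self, rng):
        import pywt
        # build a signal from a single detail band and confirm a degenerate
        # energy distribution
        coeffs = pywt.wavedec(np.zeros(2560), "db4", level=4)
        coeffs[2] = rng.standard_normal(len(coeffs[2]))
        x = pywt.waverec(coeffs, "db4")
        assert wavelet_entropy(x, "db4", 4) < 0.2

    def test_amplitude_invariance(self, rng):
        x = rng.standard_normal(2560)
        assert wavelet_entropy(x) == pytest.approx(wavelet_entropy(17.3 * x),
                                                   rel=1e-9)

    def test_zero_signal_flagged_as_zero(self):
        assert wavelet_entropy(np.zeros(2560)) == 0.0


def _toy_segments(n_ch=23, fs=64, n_win=3, rng=None):
    rng = rng or np.random.default_rng(0)
    segs = []
    for label in (1, 0):
        windows = rng.standard_normal((n_win, n_ch, 10 * fs))
        segs.append(Segment(label=label, start_abs_s=0.0, end_abs_s=n_win * 10.0,
                            data=None, windows=windows))
    return segs


class TestFeatureMatrix:
    def test_shape_and_column_order(self):
        segs = _toy_segments()
        fm = build_feature_matrix(segs, [f"c{i}" for i in range(23)], 64.0)
        assert fm.shape == (6, 116)
        assert list(fm.frame.columns[:5]) == [f"ch01_{f}" for f in FEATURES]
        assert fm.frame.columns[-1] == "label"
        assert fm.y.tolist() == [1, 1, 1, 0, 0, 0]
        assert np.isfinite(fm.X).all()

    def test_empty_input_keeps_columns(self):
        fm = build_feature_matrix([], [f"c{i}" for i in range(23)], 64.0)
        assert fm.shape == (0, 116)

    def test_sampen_sentinel_imputed_with_column_max(self, rng):
        segs = _toy_segments(n_ch=1, fs=64, n_win=2, rng=rng)
        # near-zero tolerance: distinct random values never match -> +inf
        fm = build_feature_matrix(segs, ["c0"], 64.0,
                                  FeatureParams(r_factor=1e-12))
        assert fm.n_imputed > 0
        assert np.isfinite(fm.X).all()
        assert fm.meta["imputed"].sum() > 0

    def test_csv_round_trip(self, tmp_path):
        segs = _toy_segments(n_ch=2)
        fm = build_feature_matrix(segs, ["c0", "c1"], 64.0)
        path = tmp_path / "features.csv"
        write_feature_csv(fm, path)
        back = read_feature_csv(path)
        assert list(back.frame.columns) == list(fm.frame.columns)
        assert np.allclose(back.X, fm.X)
        assert np.array_equal(back.y, fm.y)

    def test_class_separation_on_synthetic_benchmark(self, small_matrix):
        frame = small_matrix.frame
        pen = [c for c in frame.columns if c.endswith("_pen")]
        sampen = [c for c in frame.columns if c.endswith("_sampen")]
        a, b = frame[frame.label == 1], frame[frame.label == 0]
        assert a[pen].to_numpy().mean() < b[pen].to_numpy().mean()
        assert a[sampen].to_numpy().mean() < b[sampen].to_numpy().mean()

    def test_null_generator_classes_indistinguishable(self, null_matrix):
        from scipy.stats import ks_2samp
        frame = null_matrix.frame
        pen = [c for c in frame.columns if c.endswith("_pen")]
        a = frame.loc[frame.label == 1, pen].mean(axis=1)
        b = frame.loc[frame.label == 0, pen].mean(axis=1)
        assert ks_2samp(a, b).pvalue > 0.01
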