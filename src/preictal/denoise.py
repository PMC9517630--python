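"""CEEMD + wavelet-threshold denoising of single-channel EEG windows.

The cleaning procedure, applied independently per 10-s window and channel:

1. decompose the window with complementary ensemble empirical mode
   decomposition (CEEMD): average EMD decompositions of ``x + n_e`` and
   ``x - n_e`` over an ensemble of white-noise realizations ``n_e``, so the
   auxiliary noise cancels in the reconstruction;
2. flag the leading intrinsic mode functions (IMFs) whose spectral centroid
   exceeds a cutoff (30 Hz by default — scalp EEG content lives below it);
3. shrink each flagged IMF with a multilevel DWT, the universal
   ("sqtwolog") threshold lambda = sigma_hat * sqrt(2 ln N) and soft
   thresholding, sigma_hat estimated from the finest detail level via
   MAD / 0.6745;
4. sum the denoised and untouched IMFs plus the residual.

The EMD itself is a standard sifting loop: cubic-spline envelopes through
local extrema (mirror-extended at the ends), stopped by the usual
normalized squared-difference criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import CubicSpline

__all__ = ["DenoiseSpec", "IMFDecomposition", "emd", "ceemd",
           "identify_noise_imfs", "wavelet_denoise", "preprocess_window",
           "universal_threshold"]


@dataclass(frozen=True)
class DenoiseSpec:
    wavelet: str = "db4"
    levels: int = 4
    threshold_rule: str = "sqtwolog"
    threshold_mode: str = "soft"
    noise_freq_cutoff_hz: float = 30.0
    max_imfs: int = 10
    ensemble_size: int = 50          # complementary noise pairs
    noise_scale: float = 0.2         # added-noise std as fraction of signal std
    sd_threshold: float = 0.2        # sifting stop criterion
    max_sift: int = 100
    strict_first_two: bool = False   # hard-code IMF1+IMF2 as the noise set

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels >= 1")
        if self.noise_freq_cutoff_hz < 0:
            raise ValueError("cutoff >= 0")
        if self.threshold_rule != "sqtwolog":
            raise ValueError("only the universal ('sqtwolog') rule is supported")


@dataclass
class IMFDecomposition:
    """Ordered IMFs (high to low frequency) plus trend residual."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    ensemble_size: int
    noise_scale: float

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


# ---------------------------------------------------------------------------
# EMD core
# ---------------------------------------------------------------------------

def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (plateaus collapse to one side)."""
    d = np.diff(x)
    s = np.sign(d)
    nz = s != 0
    if not nz.any():
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    # carry the last nonzero slope forward through plateaus
    idx = np.where(nz, np.arange(len(s)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, s[np.clip(idx, 0, None)], 0)
    turn = np.diff(filled)
    maxima = np.nonzero(turn < 0)[0] + 1
    minima = np.nonzero(turn > 0)[0] + 1
    return maxima, minima


def _envelope(t_ext: np.ndarray, x: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended at both ends."""
    t = t_ext.astype(float)
    v = x[t_ext]
    k = min(2, len(t))
    t_left = -t[k - 1::-1][:k]
    v_left = v[k - 1::-1][:k]
    t_right = 2.0 * (n - 1) - t[: -k - 1: -1]
    v_right = v[: -k - 1: -1]
    tt = np.concatenate([t_left, t, t_right])
    vv = np.concatenate([v_left, v, v_right])
    keep = np.concatenate([[True], np.diff(tt) > 0])
    cs = CubicSpline(tt[keep], vv[keep])
    return cs(np.arange(n))


def _sift(x: np.ndarray, sd_threshold: float, max_sift: int) -> np.ndarray | None:
    n = len(x)
    h = x.copy()
    for _ in range(max_sift):
        maxima, minima = _extrema(h)
        if len(maxima) < 2 or len(minima) < 2:
            return None
        mean = 0.5 * (_envelope(maxima, h, n) + _envelope(minima, h, n))
        denom = float(np.sum(h * h))
        if denom == 0.0:
            return None
        sd = float(np.sum(mean * mean)) / denom
        h = h - mean
        if sd < sd_threshold:
            break
    return h


def emd(x: np.ndarray, max_imfs: int = 10, sd_threshold: float = 0.2,
        max_sift: int = 100) -> tuple[list[np.ndarray], np.ndarray]:
    """Plain EMD: returns (imfs, residual) with exact additivity."""
    x = np.asarray(x, dtype=np.float64)
    imfs: list[np.ndarray] = []
    residual = x.copy()
    while len(imfs) < max_imfs:
        maxima, minima = _extrema(residual)
        if len(maxima) < 2 or len(minima) < 2:
            break
        h = _sift(residual, sd_threshold, max_sift)
        if h is None:
            break
        imfs.append(h)
        residual = residual - h
    return imfs, residual


def ceemd(x: np.ndarray, spec: DenoiseSpec = DenoiseSpec(),
          seed: int = 0) -> IMFDecomposition:
    """Complementary-ensemble EMD, deterministic for a given seed.

    Because every single decomposition satisfies ``sum(imfs) + residual ==
    input`` exactly and the complementary noise pairs sum to zero, the
    ensemble average reconstructs ``x`` to floating-point accuracy.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 64:
        raise ValueError("window too short for CEEMD (need >= 64 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    if np.ptp(x) == 0.0:
        return IMFDecomposition([], x.copy(), spec.ensemble_size, spec.noise_scale)

    rng = np.random.default_rng(seed)
    sigma = spec.noise_scale * float(np.std(x))
    n_dec = 0
    acc_imfs = np.zeros((spec.max_imfs, len(x)))
    acc_res = np.zeros(len(x))
    n_imfs_seen = 0
    for _ in range(spec.ensemble_size):
        noise = rng.standard_normal(len(x)) * sigma
        for signed in (x + noise, x - noise):
            imfs, res = emd(signed, spec.max_imfs, spec.sd_threshold,
                            spec.max_sift)
            for k, imf in enumerate(imfs):
                acc_imfs[k] += imf
            acc_res += res
            n_imfs_seen = max(n_imfs_seen, len(imfs))
            n_dec += 1
    acc_imfs /= n_dec
    acc_res /= n_dec
    return IMFDecomposition([acc_imfs[k] for k in range(n_imfs_seen)],
                            acc_res, spec.ensemble_size, spec.noise_scale)


# ---------------------------------------------------------------------------
# Noise-IMF identification and wavelet shrinkage
# ---------------------------------------------------------------------------

def _spectral_centroid(x: np.ndarray, fs: float) -> float:
    power = np.abs(np.fft.rfft(x)) ** 2
    total = power.sum()
    if total == 0.0:
        return 0.0
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return float((freqs * power).sum() / total)


def identify_noise_imfs(dec: IMFDecomposition, fs: float,
                        cutoff_hz: float = 30.0,
                        strict_first_two: bool = False) -> list[int]:
    """Leading IMFs dominated by super-cutoff content (always a prefix)."""
    if strict_first_two:
        return list(range(min(2, len(dec.imfs))))
    flagged: list[int] = []
    for i, imf in enumerate(dec.imfs):
        if _spectral_centroid(imf, fs) > cutoff_hz:
            flagged.append(i)
        else:
            break
    return flagged


def universal_threshold(sigma_hat: float, n: int) -> float:
    """Donoho-Johnstone universal ('sqtwolog') threshold."""
    return sigma_hat * np.sqrt(2.0 * np.log(n))


def wavelet_denoise(x: np.ndarray, spec: DenoiseSpec = DenoiseSpec()) -> np.ndarray:
    """Multilevel DWT soft shrinkage with one global universal threshold."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2 ** spec.levels:
        raise ValueError(f"input shorter than 2^{spec.levels} samples")
    coeffs = pywt.wavedec(x, spec.wavelet, level=spec.levels, mode="symmetric")
    finest = coeffs[-1]
    sigma_hat = float(np.median(np.abs(finest))) / 0.6745
    lam = universal_threshold(sigma_hat, len(x))
    if lam == 0.0:
        return x.copy()

    def shrink(c: np.ndarray) -> np.ndarray:
        if spec.threshold_mode == "soft":
            return np.sign(c) * np.maximum(np.abs(c) - lam, 0.0)
        return pywt.threshold(c, lam, mode=spec.threshold_mode)

    out = [coeffs[0]] + [shrink(c) for c in coeffs[1:]]
    return pywt.waverec(out, spec.wavelet, mode="symmetric")[: len(x)]


def preprocess_window(x: np.ndarray, spec: DenoiseSpec = DenoiseSpec(),
                      fs: float = 256.0, seed: int = 0) -> np.ndarray:
    """Full per-window cleaning: CEEMD -> shrink noisy IMFs -> reconstruct."""
    dec = ceemd(x, spec, seed=seed)
    if not dec.imfs:
        return dec.residual
    flagged = identify_noise_imfs(dec, fs, spec.noise_freq_cutoff_hz,
                                  spec.strict_first_two)
    parts = []
    for i, imf in enumerate(dec.imfs):
        parts.append(wavelet_denoise(imf, spec) if i in flagged else imf)
    return np.sum(parts, axis=0) + dec.residual


def window_seed(global_seed: int, segment_index: int, window_index: int,
                channel_index: int) -> int:
    """Deterministic per-(segment, window, channel) CEEMD seed (< 2^31)."""
    ss = np.random.SeedSequence(
        entropy=global_seed,
        spawn_key=(segment_index, window_index, channel_index))
    return int(ss.generate_state(1)[0] % (2 ** 31))
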