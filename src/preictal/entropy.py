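"""Five nonlinear (entropy) features per channel per analysis window.

* **ApEn** — approximate entropy ``Phi^m(r) - Phi^(m+1)(r)`` with
  self-matches included, Chebyshev distance, Heaviside comparator
  ``d <= r``; defaults m = 2, r = 0.2 x window standard deviation.
* **SampEn** — sample entropy ``-ln(A/B)`` in the standard
  Richman-Moorman form: template pairs among the first N - m vectors,
  self-matches excluded; ``+inf`` when no matches survive at either
  dimension (flagged and imputed during matrix assembly).
* **PEn** — permutation entropy: Shannon entropy of ordinal-pattern
  frequencies normalized by ``ln(m!)``; ties broken by temporal order
  (stable ascending sort).
* **SpEn** — Shannon entropy (natural log) of the periodogram normalized to
  a discrete probability distribution over frequency bins.
* **WEn** — Shannon entropy of the per-scale wavelet energy distribution
  (detail bands plus the approximation band, so the shares sum to one).

ApEn and SampEn share one O(N^2) pair scan compiled with numba; the tests
hold them to 1e-12 against a plain double-loop oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from numba import njit
from scipy.signal import periodogram

__all__ = ["FeatureParams", "FeatureMatrix", "approximate_entropy",
           "sample_entropy", "permutation_entropy", "spectral_entropy",
           "wavelet_entropy", "distribution_entropy", "build_feature_matrix",
           "feature_names", "write_feature_csv", "read_feature_csv",
           "FEATURES"]

FEATURES = ("apen", "sampen", "pen", "spen", "wen")


@dataclass(frozen=True)
class FeatureParams:
    m: int = 2                  # ApEn/SampEn embedding dimension
    r_factor: float = 0.2       # tolerance as fraction of the window std
    pen_m: int = 3              # ordinal pattern order
    pen_tau: int = 1
    wavelet: str = "db4"
    wen_levels: int = 4


@njit(cache=True)
def _pair_counts(x: np.ndarray, m: int, r: float):
    """One pass over template pairs for both ApEn and SampEn.

    Returns (cm, cm1, B, A):
      cm[i]  : matches of template i at dim m over all N-m+1 templates,
               self included (ApEn numerator);
      cm1[i] : same at dim m+1 over the N-m templates;
      B, A   : SampEn pair counts (i < j among the first N-m templates)
               at dims m and m+1.
    """
    n = x.shape[0]
    nm = n - m              # last dim-m template index; count = nm + 1
    cm = np.ones(nm + 1, dtype=np.int64)
    cm1 = np.ones(nm, dtype=np.int64)
    b_pairs = 0
    a_pairs = 0
    for i in range(nm + 1):
        for j in range(i + 1, nm + 1):
            d = 0.0
            ok = True
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
                if d > r:
                    ok = False
                    break
            if not ok:
                continue
            cm[i] += 1
            cm[j] += 1
            if j <= nm - 1:
                b_pairs += 1
                t = abs(x[i + m] - x[j + m])
                if t > d:
                    d = t
                if d <= r:
                    a_pairs += 1
                    cm1[i] += 1
                    cm1[j] += 1
    return cm, cm1, b_pairs, a_pairs


def _resolve_r(x: np.ndarray, r: float | None, r_factor: float) -> float:
    if r is None:
        return r_factor * float(np.std(x))
    if r < 0:
        raise ValueError("tolerance r must be >= 0")
    return float(r)


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                        r_factor: float = 0.2) -> float:
    """ApEn(m, r, N); ``r=None`` means ``r_factor`` times the series std."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    n = len(x)
    if n <= m + 1:
        raise ValueError(f"need N > m + 1 (got N={n}, m={m})")
    r = _resolve_r(x, r, r_factor)
    cm, cm1, _, _ = _pair_counts(x, m, r)
    phi_m = float(np.mean(np.log(cm / (n - m + 1))))
    phi_m1 = float(np.mean(np.log(cm1 / (n - m))))
    return phi_m - phi_m1


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                   r_factor: float = 0.2) -> float:
    """SampEn(m, r, N); returns ``+inf`` when no template pair matches."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    n = len(x)
    if n <= m + 1:
        raise ValueError(f"need N > m + 1 (got N={n}, m={m})")
    r = _resolve_r(x, r, r_factor)
    _, _, b_pairs, a_pairs = _pair_counts(x, m, r)
    if b_pairs == 0 or a_pairs == 0:
        return float("inf")
    return -math.log(a_pairs / b_pairs)


def permutation_entropy(x: np.ndarray, m: int = 3, tau: int = 1) -> float:
    """Normalized permutation entropy in [0, 1]."""
    x = np.asarray(x, dtype=np.float64)
    n_vec = len(x) - (m - 1) * tau
    if n_vec < 2:
        raise ValueError("series too short for the requested order/delay")
    idx = np.arange(n_vec)[:, None] + tau * np.arange(m)[None, :]
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    codes = patterns @ (m ** np.arange(m))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -float(np.sum(p * np.log(p)))
    return h / math.log(math.factorial(m))


def distribution_entropy(weights: np.ndarray) -> float:
    """Shannon entropy (nats) of nonnegative weights normalized to sum 1.

    Zero-weight terms contribute nothing (0 ln 0 := 0); all-zero weights
    give 0 by convention (degenerate/flagged case).
    """
    w = np.asarray(weights, dtype=np.float64)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0.0:
        return 0.0
    p = w / total
    p = p[p > 0]
    return -float(np.sum(p * np.log(p)))


def spectral_entropy(x: np.ndarray, fs: float) -> float:
    """Shannon entropy (nats) of the normalized periodogram."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 8:
        raise ValueError("need at least 8 samples")
    _, psd = periodogram(x, fs=fs, window="boxcar", detrend=False)
    return distribution_entropy(psd)


def wavelet_entropy(x: np.ndarray, wavelet: str = "db4",
                    levels: int = 4) -> float:
    """Shannon entropy (nats) of the per-scale wavelet energy shares."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2 ** levels:
        raise ValueError(f"need at least 2^{levels} samples")
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="symmetric")
    energies = np.array([float(np.sum(c * c)) for c in coeffs])
    return distribution_entropy(energies)


# ---------------------------------------------------------------------------
# Feature matrix assembly
# ---------------------------------------------------------------------------

def feature_names(n_channels: int) -> list[str]:
    return [f"ch{c + 1:02d}_{f}" for c in range(n_channels) for f in FEATURES]


@dataclass
class FeatureMatrix:
    """Per-window entropy features plus the binary category label.

    ``frame`` holds channel-major feature columns and a final ``label``
    column (channels x 5 + 1 columns); ``meta`` carries one row per window
    with (segment_index, window_index, label, start_abs_s) plus a flag for
    imputed non-finite features.
    """

    frame: pd.DataFrame
    meta: pd.DataFrame
    n_imputed: int = 0

    @property
    def X(self) -> np.ndarray:
        return self.frame.drop(columns="label").to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape


def _window_features(x: np.ndarray, fs: float, params: FeatureParams
                     ) -> tuple[float, float, float, float, float]:
    r = params.r_factor * float(np.std(x))
    xc = np.ascontiguousarray(x, dtype=np.float64)
    n = len(xc)
    cm, cm1, b_pairs, a_pairs = _pair_counts(xc, params.m, r)
    apen = float(np.mean(np.log(cm / (n - params.m + 1)))
                 - np.mean(np.log(cm1 / (n - params.m))))
    sampen = (-math.log(a_pairs / b_pairs)
              if a_pairs > 0 and b_pairs > 0 else float("inf"))
    pen = permutation_entropy(xc, params.pen_m, params.pen_tau)
    spen = spectral_entropy(xc, fs)
    wen = wavelet_entropy(xc, params.wavelet, params.wen_levels)
    return apen, sampen, pen, spen, wen


def build_feature_matrix(segments, channels: list[str], fs: float,
                         params: FeatureParams = FeatureParams()
                         ) -> FeatureMatrix:
    """Assemble the labeled feature matrix from windowed segments.

    Rows follow segment order, then window order.  The similarity tolerance
    ``r`` is recomputed per window per channel.  Non-finite entries (the
    SampEn no-match sentinel) are imputed with the column's maximum finite
    value; tiny negative ApEn values (its known short-series bias) are
    clamped to zero.  Both fixes are counted and flagged in ``meta``.
    """
    n_ch = len(channels)
    cols = feature_names(n_ch)
    rows, meta_rows = [], []
    for si, seg in enumerate(segments):
        if seg.windows is None:
            raise ValueError("segments must be windowed first")
        if seg.windows.shape[1] != n_ch:
            raise ValueError("segment channel count does not match `channels`")
        for wi in range(seg.windows.shape[0]):
            feats = np.empty(n_ch * len(FEATURES))
            for ci in range(n_ch):
                feats[ci * 5:(ci + 1) * 5] = _window_features(
                    seg.windows[wi, ci], fs, params)
            rows.append(feats)
            meta_rows.append((si, wi, seg.label, seg.start_abs_s
                              + wi * seg.windows.shape[2] / fs))

    if rows:
        mat = np.vstack(rows)
    else:
        mat = np.empty((0, len(cols)))
    frame = pd.DataFrame(mat, columns=cols)
    meta = pd.DataFrame(meta_rows, columns=["segment_index", "window_index",
                                            "label", "start_abs_s"])
    if meta.empty:
        meta = pd.DataFrame(columns=["segment_index", "window_index", "label",
                                     "start_abs_s"])

    flagged = ~np.isfinite(frame.to_numpy()).all(axis=1) if len(frame) else \
        np.zeros(0, dtype=bool)
    n_imputed = 0
    apen_cols = [c for c in cols if c.endswith("_apen")]
    for c in apen_cols:
        neg = frame[c] < 0
        if neg.any():
            frame.loc[neg & (frame[c] > -1e-9), c] = 0.0
    for c in cols:
        col = frame[c]
        bad = ~np.isfinite(col)
        if bad.any():
            finite = col[np.isfinite(col)]
            fill = float(finite.max()) if len(finite) else 0.0
            frame.loc[bad, c] = fill
            n_imputed += int(bad.sum())
    frame["label"] = meta["label"].to_numpy(dtype=np.int64) if len(meta) else \
        pd.Series(dtype=np.int64)
    meta["imputed"] = flagged.astype(int)
    return FeatureMatrix(frame=frame, meta=meta, n_imputed=n_imputed)


def write_feature_csv(fm: FeatureMatrix, path) -> None:
    combined = pd.concat([fm.meta.drop(columns="label"), fm.frame], axis=1)
    combined.to_csv(path, index=False)


def read_feature_csv(path) -> FeatureMatrix:
    combined = pd.read_csv(path)
    meta_cols = ["segment_index", "window_index", "start_abs_s", "imputed"]
    meta = combined[meta_cols].copy()
    frame = combined.drop(columns=meta_cols)
    meta["label"] = frame["label"]
    return FeatureMatrix(frame=frame, meta=meta)
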