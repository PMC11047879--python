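"""Similarity metrics between real and generated signal frames.

Three complementary views of "how close is the generated signal to the real
one": pointwise deviation (RMSE), curve-shape agreement that respects point
order (discrete Fréchet distance), and alignment cost under monotone time
warping (DTW).  All three are non-negative and vanish for identical inputs.

For the Fréchet distance a scalar signal is embedded as the planar curve
((0, x_0), (1, x_1), ...) — sample index as abscissa — because the metric is
defined on curves; RMSE and DTW operate on the raw amplitude sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import get_window

from .preprocess import DataError, FrameSet


@dataclass
class MetricReport:
    rmse: float
    fd: float
    dtw: float
    n_pairs: int
    aggregation: str

    def to_dict(self) -> dict:
        return asdict(self)


def rmse(y_true, y_pred) -> float:
    """Root mean square error between two equal-length sequences."""
    a = np.asarray(y_true, dtype=np.float64).ravel()
    b = np.asarray(y_pred, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise DataError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise DataError("empty sequence")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def dtw_distance(q, c) -> float:
    """Dynamic-time-warping cost with absolute point distance.

    gamma(i, j) = d(q_i, c_j) + min(gamma(i-1, j-1), gamma(i-1, j), gamma(i, j-1))
    with the first row/column accumulating; returns gamma(n, m).  Unconstrained
    window (no band), symmetric step pattern.
    """
    q = np.asarray(q, dtype=np.float64).ravel()
    c = np.asarray(c, dtype=np.float64).ravel()
    if q.size == 0 or c.size == 0:
        raise DataError("empty sequence")
    d = np.abs(q[:, None] - c[None, :])
    g = np.empty_like(d)
    g[0, :] = np.cumsum(d[0, :])
    g[:, 0] = np.cumsum(d[:, 0])
    for i in range(1, len(q)):
        row_prev = g[i - 1]
        row = g[i]
        for j in range(1, len(c)):
            row[j] = d[i, j] + min(row_prev[j - 1], row_prev[j], row[j - 1])
    return float(g[-1, -1])


def frechet_distance(p, q) -> float:
    """Discrete Fréchet distance between two point sequences.

    Minimum over order-preserving couplings covering both sequences of the
    maximum pairwise Euclidean distance (the classic dynamic program).
    1-D inputs are treated as amplitude-only point sequences.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.ndim == 1:
        p = p[:, None]
    if q.ndim == 1:
        q = q[:, None]
    if p.ndim != 2 or q.ndim != 2:
        raise DataError("point sequences must be 1-D or (n, dim)")
    if p.shape[1] != q.shape[1]:
        raise DataError(f"point dimension mismatch: {p.shape[1]} vs {q.shape[1]}")
    if p.shape[0] == 0 or q.shape[0] == 0:
        raise DataError("empty sequence")
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(-1))
    g = np.empty_like(d)
    g[0, 0] = d[0, 0]
    for i in range(1, p.shape[0]):
        g[i, 0] = max(g[i - 1, 0], d[i, 0])
    for j in range(1, q.shape[0]):
        g[0, j] = max(g[0, j - 1], d[0, j])
    for i in range(1, p.shape[0]):
        for j in range(1, q.shape[0]):
            g[i, j] = max(d[i, j], min(g[i - 1, j - 1], g[i - 1, j], g[i, j - 1]))
    return float(g[-1, -1])


def _as_curve(x: np.ndarray) -> np.ndarray:
    """Embed a scalar signal as the planar curve (sample index, amplitude)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    return np.column_stack([np.arange(len(x), dtype=np.float64), x])


def _frame_metrics(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    return (rmse(a, b), frechet_distance(_as_curve(a), _as_curve(b)),
            dtw_distance(a, b))


def compare_sets(real: FrameSet | np.ndarray, generated: FrameSet | np.ndarray,
                 aggregation: str = "paired_mean") -> MetricReport:
    """Set-level similarity between real and generated frames.

    ``paired_mean`` averages each metric over index-matched pairs (requires
    equal counts); ``nearest_real_mean`` scores every generated frame against
    its nearest real frame under each metric separately and averages.
    """
    R = real.frames if isinstance(real, FrameSet) else np.atleast_2d(real)
    G = generated.frames if isinstance(generated, FrameSet) else np.atleast_2d(generated)
    if R.shape[0] == 0 or G.shape[0] == 0:
        raise DataError("empty frame set")
    if aggregation == "paired_mean":
        if R.shape[0] != G.shape[0]:
            raise DataError("paired_mean requires equal frame counts")
        vals = np.array([_frame_metrics(r, g) for r, g in zip(R, G)])
        agg = vals.mean(axis=0)
        n_pairs = R.shape[0]
    elif aggregation == "nearest_real_mean":
        best = []
        for g in G:
            per_real = np.array([_frame_metrics(r, g) for r in R])
            best.append(per_real.min(axis=0))
        agg = np.array(best).mean(axis=0)
        n_pairs = G.shape[0]
    else:
        raise DataError(f"unknown aggregation {aggregation!r}")
    return MetricReport(rmse=float(agg[0]), fd=float(agg[1]), dtw=float(agg[2]),
                        n_pairs=int(n_pairs), aggregation=aggregation)


def spectrogram(frame, sampling_rate: float = 250.0, window: int = 128,
                overlap: int | None = None, window_fn: str = "hann"):
    """Short-time power spectrum of a single frame.

    Returns ``(freqs, times, S)`` where column ``S[:, t]`` is the one-sided
    periodogram of the t-th windowed segment, normalized so that
    ``S[:, t].sum()`` equals the mean squared amplitude of that windowed
    segment (Parseval convention).
    """
    x = np.asarray(frame, dtype=np.float64).ravel()
    if window > len(x):
        raise DataError(f"window {window} larger than frame length {len(x)}")
    if overlap is None:
        overlap = window // 2
    if not 0 <= overlap < window:
        raise DataError("overlap must lie in [0, window)")
    hop = window - overlap
    w = get_window(window_fn, window, fftbins=True)
    starts = np.arange(0, len(x) - window + 1, hop)
    n_f = window // 2 + 1
    S = np.empty((n_f, len(starts)))
    for k, s in enumerate(starts):
        seg = x[s:s + window] * w
        X = np.fft.rfft(seg)
        p = np.abs(X) ** 2
        p[1: n_f - 1 if window % 2 == 0 else n_f] *= 2.0  # fold negative freqs
        S[:, k] = p / window ** 2
    freqs = np.fft.rfftfreq(window, d=1.0 / sampling_rate)
    times = (starts + window / 2.0) / sampling_rate
    return freqs, times, S


def band_power_fractions(frames: np.ndarray, sampling_rate: float,
                         bands: list[tuple[float, float]]) -> np.ndarray:
    """Mean fraction of Welch spectral power per band, averaged over frames."""
    from scipy.signal import welch
    X = np.atleast_2d(frames)
    nper = min(X.shape[1], 256)
    f, p = welch(X, fs=sampling_rate, nperseg=nper, axis=1)
    total = p.sum(axis=1)
    fracs = []
    for lo, hi in bands:
        sel = (f >= lo) & (f <= hi)
        fracs.append((p[:, sel].sum(axis=1) / total).mean())
    return np.array(fracs)
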