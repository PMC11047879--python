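"""Loading, cleaning, framing, normalization and splitting of raw signals.

The pipeline mirrors the standard preparation of single-channel EEG for
generative modelling: NaN repair, segmentation into fixed 2 s frames
(500 samples at 250 Hz), pooled z-scoring of the whole frame matrix, and a
seeded random train/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_FRAME_LEN = 500
DEFAULT_SAMPLING_RATE = 250.0


class DataError(ValueError):
    """Raised for invalid or degenerate input data."""


@dataclass
class RawRecording:
    """A single-channel recording in acquisition units (µV)."""

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    channel_id: str = "ch0"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")


@dataclass
class FrameSet:
    """Matrix of fixed-length frames plus the normalization state.

    ``mean``/``std`` are the pooled statistics used (or to be used) for
    z-scoring, stored so the transform can be inverted.
    """

    frames: np.ndarray
    frame_len: int = DEFAULT_FRAME_LEN
    mean: float | None = None
    std: float | None = None
    normalized: bool = False
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.size == 0:
            self.frames = self.frames.reshape(0, self.frame_len)
        if self.frames.ndim != 2:
            raise DataError("frames must be a 2-D matrix")
        if self.frames.shape[1] != self.frame_len:
            raise DataError(
                f"frame length {self.frames.shape[1]} != declared frame_len {self.frame_len}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def validate(self):
        if self.normalized and self.n_frames:
            m = float(self.frames.mean())
            s = float(self.frames.std())
            if abs(m) > 1e-6 or abs(s - 1.0) > 1e-6:
                raise DataError("normalized FrameSet has pooled mean/std off (0, 1)")
        if self.std is not None and self.std <= 0:
            raise DataError("stored std must be positive")
        return self


@dataclass
class SplitConfig:
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise DataError("train_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------

def clean_nans(recording: RawRecording) -> RawRecording:
    """Replace missing samples by the minimum of the valid samples.

    EEG exports occasionally carry NaN gaps; filling with the channel minimum
    keeps the amplitude range intact without inventing new extremes.
    Idempotent; errors if nothing valid remains.
    """
    x = recording.samples
    mask = np.isnan(x)
    if not mask.any():
        return recording
    if mask.all():
        raise DataError("no valid samples")
    fill = np.nanmin(x)
    out = x.copy()
    out[mask] = fill
    return replace(recording, samples=out)


def segment(recording: RawRecording, frame_len: int = DEFAULT_FRAME_LEN) -> FrameSet:
    """Cut the recording into consecutive non-overlapping frames.

    A trailing remainder shorter than ``frame_len`` is discarded; a recording
    shorter than one frame yields an empty FrameSet with a warning.
    """
    if frame_len < 1:
        raise DataError("frame_len must be >= 1")
    x = recording.samples
    n = len(x) // frame_len
    if n == 0:
        warnings.warn(
            f"recording of {len(x)} samples is shorter than one frame ({frame_len}); "
            "returning an empty FrameSet", stacklevel=2)
    frames = x[: n * frame_len].reshape(n, frame_len)
    return FrameSet(frames=frames.copy(), frame_len=frame_len,
                    sampling_rate=recording.sampling_rate)


def normalize(frames: FrameSet) -> FrameSet:
    """Pooled z-score: one global mean and population std over all entries."""
    if frames.n_frames == 0:
        raise DataError("cannot normalize an empty FrameSet")
    m = float(frames.frames.mean())
    s = float(frames.frames.std())  # population std
    if s == 0.0:
        raise DataError("constant signal: zero pooled std")
    out = (frames.frames - m) / s
    return replace(frames, frames=out, mean=m, std=s, normalized=True)


def denormalize(frames: FrameSet) -> FrameSet:
    """Invert :func:`normalize` using the stored pooled statistics."""
    if not frames.normalized:
        return frames
    if frames.mean is None or frames.std is None:
        raise DataError("no stored normalization statistics")
    out = frames.frames * frames.std + frames.mean
    return replace(frames, frames=out, normalized=False)


def split(frames: FrameSet, cfg: SplitConfig) -> tuple[FrameSet, FrameSet]:
    """Seeded random partition into train and test FrameSets.

    The train size is round-half-up of ``train_fraction * n``; the two parts
    are disjoint and exhaustive and the split is reproducible under the seed.
    The smaller part is always drawn from the front of the seeded
    permutation, so fractions f and 1-f with the same seed yield the same
    partition with the roles swapped.
    """
    n = frames.n_frames
    if n < 2:
        raise DataError("need at least 2 frames to split")
    n_train = int(np.floor(cfg.train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(cfg.seed).permutation(n)
    if n_train <= n - n_train:
        tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    else:
        te, tr = np.sort(perm[: n - n_train]), np.sort(perm[n - n_train:])
    mk = lambda idx: replace(frames, frames=frames.frames[idx].copy())
    return mk(tr), mk(te)


class FrameNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style pooled z-scoring of frame matrices.

    Fitted attributes: ``mean_``, ``std_`` (pooled over every entry of the
    training matrix, population convention).
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.size == 0:
            raise DataError("cannot fit on an empty matrix")
        self.mean_ = float(X.mean())
        self.std_ = float(X.std())
        if self.std_ == 0.0:
            raise DataError("constant signal: zero pooled std")
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=np.float64) - self.mean_) / self.std_

    def inverse_transform(self, X):
        return np.asarray(X, dtype=np.float64) * self.std_ + self.mean_


# -- readers / writers -------------------------------------------------------

def load_signals(path) -> np.ndarray:
    """Read signals from CSV (one signal per row, optional header) or NPY.

    Empty cells and any spelling of "nan" become IEEE NaN.  A 1-D array is
    promoted to a single row.
    """
    path = str(path)
    if path.endswith(".npy"):
        arr = np.load(path)
    else:
        df = pd.read_csv(path, header=None, skip_blank_lines=True)
        if df.iloc[0].apply(lambda v: isinstance(v, str)
                            and not _floatable(v)).any():
            df = df.iloc[1:]
        arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise DataError(f"expected 1-D or 2-D signals, got ndim={arr.ndim}")
    return arr


def _floatable(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False


def save_frames(frames: FrameSet, path) -> None:
    path = str(path)
    if path.endswith(".npy"):
        np.save(path, frames.frames)
    else:
        pd.DataFrame(frames.frames).to_csv(path, header=False, index=False)


def load_frames(path, frame_len: int | None = None,
                sampling_rate: float = DEFAULT_SAMPLING_RATE) -> FrameSet:
    arr = load_signals(path)
    return FrameSet(frames=arr, frame_len=frame_len or arr.shape[1],
                    sampling_rate=sampling_rate)


def preprocess_signals(signals: np.ndarray, frame_len: int = DEFAULT_FRAME_LEN,
                       sampling_rate: float = DEFAULT_SAMPLING_RATE) -> FrameSet:
    """Full cleaning path: per-row NaN repair, framing, concatenation.

    Each row of ``signals`` is treated as an independent recording; its NaNs
    are filled from that row's own minimum before framing.
    """
    all_frames = []
    for row in np.atleast_2d(signals):
        rec = clean_nans(RawRecording(row, sampling_rate=sampling_rate))
        fs = segment(rec, frame_len) if len(rec.samples) >= frame_len else None
        if fs is not None and fs.n_frames:
            all_frames.append(fs.frames)
    if not all_frames:
        return FrameSet(frames=np.empty((0, frame_len)), frame_len=frame_len,
                        sampling_rate=sampling_rate)
    return FrameSet(frames=np.vstack(all_frames), frame_len=frame_len,
                    sampling_rate=sampling_rate)
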