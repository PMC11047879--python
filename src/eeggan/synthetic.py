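"""Seeded EEG-like surrogate frames.

Each frame is a sum of one random-phase sinusoid per rhythm band (frequency
drawn uniformly inside the band, amplitude proportional to the square root
of the band's relative power) plus 1/f^alpha broadband noise synthesized in
the frequency domain, with optional per-frame amplitude jitter.  The default
bands are the classic delta/theta/alpha/beta partition.  Everything is
deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import DataError, FrameSet, DEFAULT_FRAME_LEN, DEFAULT_SAMPLING_RATE

DEFAULT_BANDS: tuple[tuple[float, float, float], ...] = (
    (0.5, 4.0, 1.0),   # delta
    (4.0, 8.0, 0.8),   # theta
    (8.0, 13.0, 1.2),  # alpha — typically prominent in resting EEG
    (13.0, 30.0, 0.6),  # beta
)


@dataclass
class SyntheticConfig:
    n_frames: int = 100
    frame_len: int = DEFAULT_FRAME_LEN
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    bands: tuple[tuple[float, float, float], ...] = DEFAULT_BANDS
    noise_exponent: float = 1.0
    noise_power: float = 0.5   # power of the 1/f floor relative to unit band power
    amplitude_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self):
        nyq = self.sampling_rate / 2.0
        for lo, hi, p in self.bands:
            if not (0 <= lo < hi <= nyq):
                raise DataError(f"band ({lo}, {hi}) outside (0, Nyquist={nyq}]")
            if p < 0:
                raise DataError("relative band power must be >= 0")
        if self.bands and all(p == 0 for *_, p in self.bands) and self.noise_power == 0:
            raise DataError("all band powers and noise power are zero")
        if self.n_frames < 0 or self.frame_len < 1:
            raise DataError("invalid n_frames/frame_len")


def _pink_noise(rng: np.random.Generator, n: int, alpha: float, fs: float) -> np.ndarray:
    """1/f^alpha noise via random-phase spectral shaping, unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    phase = rng.uniform(0, 2 * np.pi, size=len(freqs))
    spec = amp * np.exp(1j * phase)
    x = np.fft.irfft(spec, n=n)
    s = x.std()
    return x / s if s > 0 else x


def generate_frames(cfg: SyntheticConfig) -> FrameSet:
    """Draw ``cfg.n_frames`` surrogate frames; bitwise deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n_frames, cfg.frame_len
    t = np.arange(L) / cfg.sampling_rate
    frames = np.zeros((n, L))
    for k in range(n):
        x = np.zeros(L)
        for lo, hi, p in cfg.bands:
            if p == 0:
                continue
            f = rng.uniform(lo, hi)
            phi = rng.uniform(0, 2 * np.pi)
            # a sinusoid of amplitude a has power a^2/2; target power p
            x += np.sqrt(2.0 * p) * np.sin(2 * np.pi * f * t + phi)
        if cfg.noise_power > 0:
            x += np.sqrt(cfg.noise_power) * _pink_noise(rng, L, cfg.noise_exponent,
                                                        cfg.sampling_rate)
        if cfg.amplitude_jitter > 0:
            x *= max(1.0 + cfg.amplitude_jitter * rng.standard_normal(), 0.05)
        frames[k] = x
    return FrameSet(frames=frames, frame_len=L, sampling_rate=cfg.sampling_rate)


def make_noise_batch(batch: int, dim: int = 1000, distribution: str = "uniform01",
                     seed: int = 0) -> np.ndarray:
    """Latent noise for the generator: i.i.d. U[0,1] or standard normal."""
    if batch < 1 or dim < 1:
        raise DataError("batch and dim must be >= 1")
    rng = np.random.default_rng(seed)
    if distribution == "uniform01":
        return rng.random((batch, dim))
    if distribution == "gaussian":
        return rng.standard_normal((batch, dim))
    raise DataError(f"unknown noise distribution: {distribution!r}")
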