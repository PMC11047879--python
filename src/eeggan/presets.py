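"""Desk-scale presets: reduced problem sizes for demos, tests and the
bundled acceptance script.

The full-size architectures (1000-step LSTM, 500-sample frames, 1000-epoch
training) are what the method prescribes for real EEG corpora; the presets
here shrink every axis — 100-sample frames, 100-step LSTM with 16 units,
150 epochs, a few hundred surrogate frames — so the complete adversarial
loop and the compressed-sensing benchmark run end to end on a single CPU in
minutes while exercising exactly the same code paths.
"""

from __future__ import annotations

from .cs import CSResNetSpec
from .models import CriticSpec, GeneratorSpec
from .synthetic import SyntheticConfig
from .training import TrainConfig

SMOKE_FRAME_LEN = 100
SMOKE_N_FRAMES = 320


def smoke_synthetic_config(seed: int = 0, n_frames: int = SMOKE_N_FRAMES,
                           single_band: bool = True) -> SyntheticConfig:
    """Surrogate frames for reduced runs: a single alpha-band oscillation
    (8-13 Hz) without broadband noise keeps the target distribution simple
    enough for a tiny generator to approach."""
    bands = ((8.0, 13.0, 1.0),) if single_band else None
    kw = {} if bands is None else {"bands": bands}
    return SyntheticConfig(n_frames=n_frames, frame_len=SMOKE_FRAME_LEN,
                           noise_power=0.0 if single_band else 0.5,
                           amplitude_jitter=0.1, seed=seed, **kw)


def smoke_generator_spec() -> GeneratorSpec:
    return GeneratorSpec(noise_dim=100, timesteps=100, lstm_units=16,
                         output_len=SMOKE_FRAME_LEN)


def smoke_critic_spec() -> CriticSpec:
    return CriticSpec(input_len=SMOKE_FRAME_LEN, fc_pre=64)


def smoke_train_config(seed: int = 0, epochs: int = 150) -> TrainConfig:
    return TrainConfig(epochs=epochs, seed=seed)


def smoke_cs_spec() -> CSResNetSpec:
    """CS-ResNet shrunk to length-100 signals: same topology (two 6-conv
    dilated residual blocks), smaller channel counts."""
    return CSResNetSpec(signal_len=SMOKE_FRAME_LEN, stem_filters=8,
                        block_filters=(16, 32, 64, 32, 16, 8),
                        block_kernels=(7, 7, 5, 5, 3, 3), dilation=2)
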