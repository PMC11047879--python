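import numpy as np
import pytest

from eeggan import (CriticSpec, GeneratorSpec, SyntheticConfig, build_critic,
                    build_generator, generate_frames, normalize)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_frames():
    """60 normalized multi-band surrogate frames of length 100."""
    fs = generate_frames(SyntheticConfig(n_frames=60, frame_len=100, seed=11))
    return normalize(fs)


@pytest.fixture(scope="session")
def tiny_gen_spec():
    return GeneratorSpec(noise_dim=20, timesteps=20, lstm_units=4, output_len=32)


@pytest.fixture(scope="session")
def tiny_critic_spec():
    return CriticSpec(input_len=32, fc_pre=32)


@pytest.fixture(scope="session")
def full_generator():
    """Full-size generator (1000-step LSTM, 500-sample output); built once
    per session because the parameter tensors are large."""
    return build_generator(GeneratorSpec(), seed=0)


@pytest.fixture(scope="session")
def full_critic():
    return build_critic(CriticSpec(), seed=0)
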