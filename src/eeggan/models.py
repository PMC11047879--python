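"""Declarative LSTM-generator and CNN-critic architectures.

The generator unrolls a two-layer 128-unit LSTM over 1000 time steps, one
latent scalar per step, then collapses the (1000 x 128) sequence through a
fully connected layer, a reshape and a second fully connected layer to a
500-sample frame squashed by tanh.  The critic maps a 500-sample frame
through a 256-unit dense layer, four stride-2 convolutions with 8/16/32/64
filters (kernel 3, pad 1, so 256 -> 128 -> 64 -> 32 -> 16), and a dense head
to a single score — a sigmoid probability for the cross-entropy game, a raw
score for the Wasserstein game.

Batch normalization sits before every activation and dropout (rate 0.5)
after it, in both networks; the leaky-ReLU slope is 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .preprocess import FrameSet


class SpecError(ValueError):
    """An architecture spec violates one of its invariants."""


@dataclass
class GeneratorSpec:
    noise_dim: int = 1000
    lstm_layers: int = 2
    lstm_units: int = 128
    timesteps: int = 1000
    output_len: int = 500
    fc_hidden: int | None = None   # width after flatten; defaults to timesteps
    leaky_slope: float = 1e-4
    dropout: float = 0.5
    batchnorm_before_activation: bool = True
    output_activation: str = "tanh"

    def validate(self) -> "GeneratorSpec":
        if self.timesteps != self.noise_dim:
            raise SpecError("timesteps must equal noise_dim (one latent scalar per step)")
        if self.output_len <= 0:
            raise SpecError("output_len must be positive")
        if self.lstm_layers < 1 or self.lstm_units < 1:
            raise SpecError("lstm_layers and lstm_units must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise SpecError("dropout must lie in [0, 1)")
        if self.output_activation not in ("tanh", "linear"):
            raise SpecError("output_activation must be tanh or linear")
        return self


@dataclass
class CriticSpec:
    input_len: int = 500
    fc_pre: int = 256
    conv_filters: tuple[int, ...] = (8, 16, 32, 64)
    kernel: int = 3
    stride: int = 2
    leaky_slope: float = 1e-4
    dropout: float = 0.5
    batchnorm: bool = True
    final_activation: str = "sigmoid"

    def validate(self) -> "CriticSpec":
        if self.final_activation not in ("sigmoid", "linear"):
            raise SpecError("final_activation must be sigmoid or linear")
        if self.input_len <= 0 or self.fc_pre <= 0:
            raise SpecError("input_len and fc_pre must be positive")
        length = self.fc_pre
        for _ in self.conv_filters:
            if length % self.stride:
                raise SpecError(
                    f"fc_pre={self.fc_pre}: length {length} not divisible by stride "
                    f"{self.stride} through the conv stack")
            length //= self.stride
        if length < 1:
            raise SpecError("conv stack collapses the sequence below length 1")
        return self

    def feature_len(self) -> int:
        return self.fc_pre // self.stride ** len(self.conv_filters)


class Generator(nn.Module):
    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        S = spec
        self.lstms = nn.Sequential()
        in_size = 1
        blocks = []
        for _ in range(S.lstm_layers):
            blocks += [nn.LSTM(in_size, S.lstm_units, rng),
                       nn.BatchNorm(S.lstm_units, feature_axis=2),
                       nn.LeakyReLU(S.leaky_slope),
                       nn.Dropout(S.dropout)]
            in_size = S.lstm_units
        self.lstms = nn.Sequential(*blocks)
        hidden = S.fc_hidden or S.timesteps
        self.head = nn.Sequential(
            nn.Flatten(),
            nn.Dense(S.timesteps * S.lstm_units, hidden, rng),
            nn.BatchNorm(hidden),
            nn.LeakyReLU(S.leaky_slope),
            nn.Dropout(S.dropout),
            nn.Reshape((hidden,)),
            nn.Dense(hidden, S.output_len, rng),
            nn.Tanh() if S.output_activation == "tanh" else nn.Identity(),
        )
        if not S.batchnorm_before_activation:
            for seq in (self.lstms, self.head):
                seq.layers = [l for l in seq.layers if not isinstance(l, nn.BatchNorm)]
                seq._modules = {str(i): l for i, l in enumerate(seq.layers)}
        self.seed_rngs(seed)

    def forward(self, z: Tensor) -> Tensor:
        if z.shape[-1] != self.spec.noise_dim:
            raise SpecError(
                f"noise dim {z.shape[-1]} != spec noise_dim {self.spec.noise_dim}")
        x = ad.reshape(z, (z.shape[0], self.spec.timesteps, 1))
        x = self.lstms(x)                   # (B, T, H)
        return self.head(x)                 # (B, output_len)


class Critic(nn.Module):
    def __init__(self, spec: CriticSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        S = spec
        self.pre = nn.Sequential(
            nn.Dense(S.input_len, S.fc_pre, rng),
            nn.LeakyReLU(S.leaky_slope),
            nn.Reshape((1, S.fc_pre)),
        )
        convs = []
        in_ch = 1
        for f in S.conv_filters:
            convs.append(nn.Conv1d(in_ch, f, S.kernel, rng, stride=S.stride,
                                   padding=(S.kernel - 1) // 2))
            if S.batchnorm:
                convs.append(nn.BatchNorm(f))
            convs += [nn.LeakyReLU(S.leaky_slope), nn.Dropout(S.dropout)]
            in_ch = f
        self.convs = nn.Sequential(*convs)
        feat = S.feature_len() * S.conv_filters[-1]
        self.head = nn.Sequential(
            nn.Flatten(),
            nn.Dense(feat, 1, rng),
            nn.Sigmoid() if S.final_activation == "sigmoid" else nn.Identity(),
        )
        self.seed_rngs(seed)

    def features(self, x: Tensor) -> Tensor:
        """Conv-stack output, shape (batch, channels, length)."""
        if x.shape[-1] != self.spec.input_len:
            raise SpecError(f"input length {x.shape[-1]} != spec input_len {self.spec.input_len}")
        return self.convs(self.pre(x))

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.features(x))


def build_generator(spec: GeneratorSpec | None = None, seed: int = 0) -> Generator:
    return Generator(spec or GeneratorSpec(), seed=seed)


def build_critic(spec: CriticSpec | None = None, seed: int = 0) -> Critic:
    return Critic(spec or CriticSpec(), seed=seed)


def generate(network: Generator, noise: np.ndarray) -> FrameSet:
    """Run the generator in inference mode on a (batch x noise_dim) array.

    Output frames are in normalized units (tanh range) by construction.
    """
    noise = np.atleast_2d(np.asarray(noise, dtype=np.float64))
    was_training = network.training
    network.eval()
    try:
        with ad.no_grad():
            out = network(Tensor(noise)).data
    finally:
        network.train(was_training)
    return FrameSet(frames=out, frame_len=network.spec.output_len, normalized=True,
                    mean=0.0, std=1.0)


def model_summary(module: nn.Module, name: str = "network") -> str:
    lines = [f"{name}: {module.n_parameters()} parameters"]
    for pname, p in module.named_parameters():
        lines.append(f"  {pname:40s} {str(p.shape):20s} {p.size}")
    return "\n".join(lines)
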