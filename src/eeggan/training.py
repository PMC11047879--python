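"""Adversarial objectives and the alternating training loop.

Three loss variants are supported:

* ``bce`` — the original minimax game: the discriminator maximizes
  ``log D(x) + log(1 - D(G(z)))`` with real frames labelled 1 and generated
  frames labelled 0; implemented as binary cross-entropy.
* ``wgan`` — the critic loss ``E[D(fake)] - E[D(real)]`` (an estimate of the
  negated Wasserstein distance) without any Lipschitz enforcement.
* ``wgan_gp`` — the same plus a gradient penalty
  ``lambda * E[(||grad_x D(x_hat)|| - 1)^2]``, by default evaluated at random
  interpolates ``x_hat = eps*real + (1-eps)*fake``; a ``fake``-only penalty
  mode is available for comparison.

The loop alternates ``critic_updates_per_gen`` critic steps (5 by default)
for every generator step, uses Adam, and halves the learning rate every
``lr_step`` epochs.  Everything is reproducible under the run seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor, backward
from .models import (Critic, CriticSpec, Generator, GeneratorSpec,
                     build_critic, build_generator, generate)
from .preprocess import DataError, FrameSet
from sklearn.base import BaseEstimator

_EPS = 1e-7  # log clipping for the cross-entropy variant


class NumericError(RuntimeError):
    """Raised when training hits persistent non-finite losses."""


@dataclass
class TrainConfig:
    loss_variant: str = "wgan_gp"
    gp_lambda: float = 10.0
    gp_mode: str = "interpolate"          # or "fake"
    critic_updates_per_gen: int = 5
    epochs: int = 1000
    batch_size: int = 64
    lr: float = 1e-3
    adam_betas: tuple[float, float] = (0.5, 0.9)
    lr_step: int = 50
    lr_gamma: float = 0.5
    noise_distribution: str = "uniform01"
    seed: int = 0

    def __post_init__(self):
        if self.loss_variant not in ("bce", "wgan", "wgan_gp"):
            raise ValueError(f"unknown loss variant {self.loss_variant!r}")
        if self.gp_lambda < 0:
            raise ValueError("gp_lambda must be >= 0")
        if self.critic_updates_per_gen < 1:
            raise ValueError("critic_updates_per_gen must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.gp_mode not in ("interpolate", "fake"):
            raise ValueError("gp_mode must be 'interpolate' or 'fake'")

    def lr_at(self, epoch: int) -> float:
        return self.lr * self.lr_gamma ** (epoch // self.lr_step)


@dataclass
class LossRecord:
    epoch: int
    d_loss: float
    g_loss: float
    gp_term: float
    lr: float


# -- losses ------------------------------------------------------------------

def gradient_penalty(critic: Critic, real: np.ndarray | Tensor,
                     fake: np.ndarray | Tensor, gp_lambda: float,
                     rng: np.random.Generator | int = 0,
                     mode: str = "interpolate") -> Tensor:
    """``lambda * mean[(||grad_x D(x_hat)||_2 - 1)^2]``.

    ``x_hat`` is a per-sample uniform interpolate between real and fake
    (``mode="interpolate"``) or the fake batch itself (``mode="fake"``).
    The result is a graph node: differentiating it reaches the critic
    parameters through the inner gradient (double backprop).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    real_a = real.data if isinstance(real, Tensor) else np.asarray(real, dtype=np.float64)
    fake_a = fake.data if isinstance(fake, Tensor) else np.asarray(fake, dtype=np.float64)
    if real_a.shape != fake_a.shape:
        raise ValueError("real and fake batches must share a shape")
    if mode == "interpolate":
        eps = rng.random((real_a.shape[0],) + (1,) * (real_a.ndim - 1))
        x_hat = eps * real_a + (1.0 - eps) * fake_a
    else:
        x_hat = fake_a.copy()
    x = Tensor(x_hat, requires_grad=True)
    score = ad.tsum(critic(x))
    (gx,) = backward(score, [x], create_graph=True)
    sq = ad.tsum(ad.power(gx, 2.0), axis=tuple(range(1, real_a.ndim)))
    norm = ad.power(ad.add(sq, 1e-16), 0.5)  # guard keeps d(sqrt)/dsq finite at 0
    return ad.mul(ad.tmean(ad.power(ad.add(norm, -1.0), 2.0)), float(gp_lambda))


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def critic_loss(variant: str, d_real, d_fake, gp=0.0) -> Tensor:
    """Discriminator/critic objective to be minimized."""
    d_real, d_fake = _as_t(d_real), _as_t(d_fake)
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("empty score batch")
    gp_val = gp.item() if isinstance(gp, Tensor) else float(gp)
    if variant in ("bce", "wgan") and gp_val != 0.0:
        raise ValueError(f"gradient penalty must be 0 for variant {variant!r}")
    if variant == "bce":
        pr = ad.tmean(ad.log(ad.add(_clip01(d_real), _EPS)))
        pf = ad.tmean(ad.log(ad.add(ad.add(1.0, ad.mul(_clip01(d_fake), -1.0)), _EPS)))
        return ad.mul(ad.add(pr, pf), -1.0)
    loss = ad.add(ad.tmean(d_fake), ad.mul(ad.tmean(d_real), -1.0))
    if variant == "wgan_gp":
        loss = ad.add(loss, gp if isinstance(gp, Tensor) else Tensor(gp_val))
    return loss


def generator_loss(variant: str, d_fake) -> Tensor:
    d_fake = _as_t(d_fake)
    if d_fake.size == 0:
        raise ValueError("empty score batch")
    if variant == "bce":
        return ad.mul(ad.tmean(ad.log(ad.add(_clip01(d_fake), _EPS))), -1.0)
    return ad.mul(ad.tmean(d_fake), -1.0)


def _clip01(t: Tensor) -> Tensor:
    # clamp into [0,1] without killing gradients away from the clip region
    clipped = np.clip(t.data, 0.0, 1.0)
    if np.array_equal(clipped, t.data):
        return t
    return ad.add(t, Tensor(clipped - t.data))


# -- training loop -----------------------------------------------------------

def train(gen_spec: GeneratorSpec, critic_spec: CriticSpec, train_frames: FrameSet,
          cfg: TrainConfig, callback=None) -> tuple[Generator, Critic, list[LossRecord]]:
    """Alternating WGAN-GP training; see module docstring for the scheme."""
    if train_frames.n_frames == 0:
        raise DataError("empty training set")
    if train_frames.frame_len != gen_spec.output_len:
        raise DataError("frame_len must equal the generator output_len")
    if critic_spec.final_activation == "sigmoid" and cfg.loss_variant != "bce":
        # a bounded critic collapses the Wasserstein gradient
        critic_spec = CriticSpec(**{**critic_spec.__dict__, "final_activation": "linear"})

    root = np.random.SeedSequence(cfg.seed)
    s_gen, s_crit, s_loop = (int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3))
    G = build_generator(gen_spec, seed=s_gen)
    D = build_critic(critic_spec, seed=s_crit)
    rng = np.random.default_rng(s_loop)
    G.seed_rngs(s_gen + 1)
    D.seed_rngs(s_crit + 1)

    optG = nn.Adam(G.parameters(), cfg.lr, cfg.adam_betas)
    optD = nn.Adam(D.parameters(), cfg.lr, cfg.adam_betas)

    X = train_frames.frames
    n = X.shape[0]
    bs = min(cfg.batch_size, n)
    records: list[LossRecord] = []
    critic_steps = gen_steps = 0
    bad_streak = 0

    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        optG.lr = optD.lr = lr
        perm = rng.permutation(n)
        d_losses, g_losses, gps = [], [], []
        for start in range(0, n - bs + 1, bs):
            real = X[perm[start:start + bs]]
            # ---- critic step
            z = _noise(rng, bs, gen_spec.noise_dim, cfg.noise_distribution)
            with ad.no_grad():
                fake = G(Tensor(z)).data
            d_real = D(Tensor(real))
            d_fake = D(Tensor(fake))
            if cfg.loss_variant == "wgan_gp":
                gp = gradient_penalty(D, real, fake, cfg.gp_lambda, rng, cfg.gp_mode)
            else:
                gp = Tensor(0.0)
            loss_d = critic_loss(cfg.loss_variant, d_real, d_fake,
                                 gp if cfg.loss_variant == "wgan_gp" else 0.0)
            optD.zero_grad()
            backward(loss_d, D.parameters(), accumulate=True)
            optD.step()
            critic_steps += 1
            d_losses.append(loss_d.item())
            gps.append(gp.item())
            bad_streak = bad_streak + 1 if not np.isfinite(loss_d.item()) else 0
            if bad_streak >= 3:
                raise NumericError(
                    f"non-finite critic loss for 3 consecutive steps at epoch {epoch}")
            # ---- generator step after every critic_updates_per_gen critic steps
            if critic_steps % cfg.critic_updates_per_gen == 0:
                z = _noise(rng, bs, gen_spec.noise_dim, cfg.noise_distribution)
                fake_t = G(Tensor(z))
                loss_g = generator_loss(cfg.loss_variant, D(fake_t))
                optG.zero_grad()
                backward(loss_g, G.parameters(), accumulate=True)
                optG.step()
                gen_steps += 1
                g_losses.append(loss_g.item())
                if not np.isfinite(loss_g.item()):
                    bad_streak += 1
        records.append(LossRecord(
            epoch=epoch,
            d_loss=float(np.mean(d_losses)) if d_losses else float("nan"),
            g_loss=float(np.mean(g_losses)) if g_losses else float("nan"),
            gp_term=float(np.mean(gps)) if gps else 0.0,
            lr=lr,
        ))
        if callback is not None:
            callback(records[-1])
    G._train_counters = {"critic_steps": critic_steps, "gen_steps": gen_steps}  # type: ignore
    return G, D, records


def _noise(rng: np.random.Generator, batch: int, dim: int, distribution: str) -> np.ndarray:
    if distribution == "uniform01":
        return rng.random((batch, dim))
    if distribution == "gaussian":
        return rng.standard_normal((batch, dim))
    raise ValueError(f"unknown noise distribution {distribution!r}")


class LCWGANGP(BaseEstimator):
    """LSTM-generator / CNN-critic Wasserstein GAN with gradient penalty.

    Sklearn-style estimator: ``fit(X)`` trains on a (n_frames x frame_len)
    matrix of normalized frames; ``sample(n)`` draws generated frames.

    Parameters mirror :class:`TrainConfig`; ``generator_spec`` and
    ``critic_spec`` default to the full-size architectures.

    Fitted attributes: ``generator_``, ``critic_``, ``loss_history_``
    (one :class:`LossRecord` per epoch), ``n_critic_steps_``, ``n_gen_steps_``.
    """

    def __init__(self, generator_spec: GeneratorSpec | None = None,
                 critic_spec: CriticSpec | None = None,
                 loss_variant: str = "wgan_gp", gp_lambda: float = 10.0,
                 gp_mode: str = "interpolate", critic_updates_per_gen: int = 5,
                 epochs: int = 1000, batch_size: int = 64, lr: float = 1e-3,
                 adam_betas: tuple[float, float] = (0.5, 0.9), lr_step: int = 50,
                 lr_gamma: float = 0.5, noise_distribution: str = "uniform01",
                 seed: int = 0):
        self.generator_spec = generator_spec
        self.critic_spec = critic_spec
        self.loss_variant = loss_variant
        self.gp_lambda = gp_lambda
        self.gp_mode = gp_mode
        self.critic_updates_per_gen = critic_updates_per_gen
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.adam_betas = adam_betas
        self.lr_step = lr_step
        self.lr_gamma = lr_gamma
        self.noise_distribution = noise_distribution
        self.seed = seed

    def _config(self) -> TrainConfig:
        return TrainConfig(
            loss_variant=self.loss_variant, gp_lambda=self.gp_lambda,
            gp_mode=self.gp_mode, critic_updates_per_gen=self.critic_updates_per_gen,
            epochs=self.epochs, batch_size=self.batch_size, lr=self.lr,
            adam_betas=tuple(self.adam_betas), lr_step=self.lr_step,
            lr_gamma=self.lr_gamma, noise_distribution=self.noise_distribution,
            seed=self.seed)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] == 0:
            raise DataError("X must be a non-empty (n_frames, frame_len) matrix")
        gspec = self.generator_spec or GeneratorSpec()
        cspec = self.critic_spec or CriticSpec(input_len=X.shape[1])
        frames = FrameSet(frames=X, frame_len=X.shape[1], normalized=True,
                          mean=0.0, std=1.0)
        G, D, records = train(gspec, cspec, frames, self._config())
        self.generator_, self.critic_, self.loss_history_ = G, D, records
        counters = getattr(G, "_train_counters", {})
        self.n_critic_steps_ = counters.get("critic_steps", 0)
        self.n_gen_steps_ = counters.get("gen_steps", 0)
        return self

    def sample(self, n: int, seed: int | None = None) -> np.ndarray:
        """Generate ``n`` frames (inference mode, deterministic per seed)."""
        if not hasattr(self, "generator_"):
            raise RuntimeError("fit the model before sampling")
        rng = np.random.default_rng(self.seed + 104729 if seed is None else seed)
        z = _noise(rng, n, self.generator_.spec.noise_dim, self.noise_distribution)
        return generate(self.generator_, z).frames
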