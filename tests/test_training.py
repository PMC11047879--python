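"""Adversarial losses, gradient penalty and the training schedule."""

import numpy as np
import pytest

from eeggan import (CriticSpec, GeneratorSpec, TrainConfig, critic_loss,
                    generator_loss, gradient_penalty, normalize, train)
from eeggan import nn
from eeggan.autodiff import Tensor
from eeggan.preprocess import DataError, FrameSet
from eeggan.synthetic import SyntheticConfig, generate_frames
from eeggan.training import LCWGANGP


class _LinearCritic(nn.Module):
    """D(x) = x @ w + b with a chosen gradient norm; for closed-form checks."""

    def __init__(self, dim: int, grad_norm: float):
        super().__init__()
        w = np.zeros((dim, 1))
        if grad_norm:
            w[:, 0] = grad_norm / np.sqrt(dim)
        self.lin = nn.Dense(dim, 1, np.random.default_rng(0))
        self.lin.W.data = w
        self.lin.b.data = np.zeros(1)

    def forward(self, x):
        return self.lin(x)


class TestGradientPenalty:
    @pytest.mark.parametrize("grad_norm,expected", [
        (1.0, 0.0), (0.0, 10.0), (2.0, 10.0),
    ])
    def test_closed_form_for_linear_critics(self, rng, grad_norm, expected):
        D = _LinearCritic(8, grad_norm)
        real = rng.normal(size=(16, 8))
        fake = rng.normal(size=(16, 8))
        gp = gradient_penalty(D, real, fake, gp_lambda=10.0, rng=3)
        assert gp.item() == pytest.approx(expected, abs=1e-6)

    def test_nonnegative_for_random_critics(self, rng, tiny_critic_spec):
        from eeggan import build_critic
        D = build_critic(
            CriticSpec(**{**tiny_critic_spec.__dict__, "final_activation": "linear"}),
            seed=2)
        for s in range(3):
            real = rng.normal(size=(8, tiny_critic_spec.input_len))
            fake = rng.normal(size=(8, tiny_critic_spec.input_len))
            assert gradient_penalty(D, real, fake, 10.0, rng=s).item() >= 0.0

    def test_fake_mode_evaluates_at_fake_batch(self):
        D = _LinearCritic(4, 2.0)
        real = np.zeros((5, 4))
        fake = np.ones((5, 4))
        gp = gradient_penalty(D, real, fake, 10.0, rng=0, mode="fake")
        assert gp.item() == pytest.approx(10.0, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        D = _LinearCritic(4, 1.0)
        with pytest.raises(ValueError, match="share a shape"):
            gradient_penalty(D, np.zeros((3, 4)), np.zeros((2, 4)), 10.0)


class TestLosses:
    def test_wgan_gp_symmetric_case_is_zero(self):
        d = np.array([0.3, -0.1, 0.4])
        assert critic_loss("wgan_gp", d, d, 0.0).item() == pytest.approx(0.0)

    def test_wgan_gp_direct_formula(self):
        loss = critic_loss("wgan_gp", d_real=np.array([0.1]),
                           d_fake=np.array([-0.2]), gp=10.0)
        assert loss.item() == pytest.approx(9.7)

    def test_gp_zero_reduces_to_wgan(self, rng):
        dr, df = rng.normal(size=6), rng.normal(size=6)
        assert critic_loss("wgan_gp", dr, df, 0.0).item() == \
            pytest.approx(critic_loss("wgan", dr, df).item())

    def test_gp_with_non_gp_variant_rejected(self):
        with pytest.raises(ValueError, match="must be 0"):
            critic_loss("wgan", np.ones(2), np.zeros(2), gp=1.0)

    @pytest.mark.parametrize("d_fake,expected", [
        (np.array([0.5, 0.5]), -0.5),
        (np.array([0.0, 0.0]), 0.0),
    ])
    def test_wasserstein_generator_loss(self, d_fake, expected):
        assert generator_loss("wgan_gp", d_fake).item() == pytest.approx(expected)

    def test_bce_generator_perfect_fooling(self):
        assert generator_loss("bce", np.array([1.0])).item() == pytest.approx(0.0, abs=1e-6)

    def test_bce_critic_loss_is_cross_entropy(self):
        # D(real)=0.9, D(fake)=0.2 -> -(log .9 + log .8)
        loss = critic_loss("bce", np.array([0.9]), np.array([0.2]))
        assert loss.item() == pytest.approx(-(np.log(0.9) + np.log(0.8)), abs=1e-5)


class TestSchedule:
    def test_lr_halves_every_step(self):
        cfg = TrainConfig(lr=1e-3, lr_step=50, lr_gamma=0.5, epochs=1)
        assert cfg.lr_at(0) == 1e-3
        assert cfg.lr_at(49) == 1e-3
        assert cfg.lr_at(50) == 5e-4
        assert cfg.lr_at(100) == 2.5e-4

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(loss_variant="hinge")
        with pytest.raises(ValueError):
            TrainConfig(gp_lambda=-1)
        with pytest.raises(ValueError):
            TrainConfig(critic_updates_per_gen=0)


def _tiny_run(tiny_gen_spec, tiny_critic_spec, epochs=2, seed=0, **kw):
    fs = generate_frames(SyntheticConfig(
        n_frames=24, frame_len=tiny_gen_spec.output_len, seed=1,
        bands=((8.0, 13.0, 1.0),), noise_power=0.0))
    nf = normalize(fs)
    cfg = TrainConfig(epochs=epochs, batch_size=8, seed=seed, **kw)
    return train(tiny_gen_spec, tiny_critic_spec, nf, cfg)


class TestTrainingLoop:
    def test_five_to_one_update_ratio(self, tiny_gen_spec, tiny_critic_spec):
        G, D, recs = _tiny_run(tiny_gen_spec, tiny_critic_spec, epochs=2)
        counters = G._train_counters
        assert counters["critic_steps"] == 2 * 3  # 24 frames / batch 8 per epoch
        assert counters["gen_steps"] == counters["critic_steps"] // 5
        assert len(recs) == 2

    def test_records_schedule_and_nonnegative_gp(self, tiny_gen_spec, tiny_critic_spec):
        G, D, recs = _tiny_run(tiny_gen_spec, tiny_critic_spec, epochs=3,
                               lr_step=2, lr_gamma=0.5)
        assert [r.lr for r in recs] == [1e-3, 1e-3, 5e-4]
        assert all(r.gp_term >= 0 for r in recs)

    def test_seed_reproducibility(self, tiny_gen_spec, tiny_critic_spec):
        _, _, a = _tiny_run(tiny_gen_spec, tiny_critic_spec, seed=7)
        _, _, b = _tiny_run(tiny_gen_spec, tiny_critic_spec, seed=7)
        np.testing.assert_array_equal(
            np.array([(r.d_loss, r.g_loss, r.gp_term) for r in a]),
            np.array([(r.d_loss, r.g_loss, r.gp_term) for r in b]))
        _, _, c = _tiny_run(tiny_gen_spec, tiny_critic_spec, seed=8)
        assert [r.d_loss for r in a] != [r.d_loss for r in c]

    def test_bce_variant_trains(self, tiny_gen_spec, tiny_critic_spec):
        G, D, recs = _tiny_run(tiny_gen_spec, tiny_critic_spec,
                               loss_variant="bce", gp_lambda=0.0)
        assert np.isfinite([r.d_loss for r in recs]).all()
        # bce keeps the sigmoid head
        assert D.spec.final_activation == "sigmoid"

    def test_wasserstein_switches_to_linear_head(self, tiny_gen_spec, tiny_critic_spec):
        G, D, _ = _tiny_run(tiny_gen_spec, tiny_critic_spec)
        assert D.spec.final_activation == "linear"

    def test_empty_training_set_rejected(self, tiny_gen_spec, tiny_critic_spec):
        empty = FrameSet(np.empty((0, tiny_gen_spec.output_len)),
                         frame_len=tiny_gen_spec.output_len)
        with pytest.raises(DataError, match="empty"):
            train(tiny_gen_spec, tiny_critic_spec, empty, TrainConfig(epochs=1))


class TestEstimator:
    def test_fit_sample_roundtrip(self, tiny_gen_spec, tiny_critic_spec):
        fs = normalize(generate_frames(SyntheticConfig(
            n_frames=16, frame_len=tiny_gen_spec.output_len, seed=2)))
        est = LCWGANGP(generator_spec=tiny_gen_spec, critic_spec=tiny_critic_spec,
                       epochs=1, batch_size=8, seed=0)
        est.fit(fs.frames)
        out = est.sample(5, seed=3)
        assert out.shape == (5, tiny_gen_spec.output_len)
        assert np.array_equal(out, est.sample(5, seed=3))
        assert est.n_critic_steps_ >= 1 and len(est.loss_history_) == 1

    def test_get_params_roundtrip(self):
        est = LCWGANGP(epochs=5, gp_lambda=3.0)
        params = est.get_params()
        assert params["epochs"] == 5 and params["gp_lambda"] == 3.0
        est2 = LCWGANGP(**params)
        assert est2.get_params() == params
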