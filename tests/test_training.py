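"""WGAN-GP loss components and the training loop."""

import numpy as np
import pytest

from sptsr.network import CriticConfig, GeneratorConfig, build_critic
from sptsr.nn import Tensor
from sptsr.nn.autodiff import matmul
from sptsr.observation import TrainingPair
from sptsr.training import (
    TrainConfig,
    critic_loss,
    generator_loss,
    gradient_penalty,
    select_best_epoch,
    shows_overfitting,
    train,
)


class LinearCritic:
    """Critic(x) = <w, x>; gradient norm is exactly ||w||."""

    def __init__(self, w):
        self.w = Tensor(np.asarray(w, dtype=float), requires_grad=True)

    def __call__(self, x):
        flat = x.reshape((x.shape[0], x.size // x.shape[0]))
        return matmul(flat, self.w.reshape((self.w.size, 1))).reshape((x.shape[0],))

    def parameters(self):
        return [self.w]


class TestCriticLoss:
    def test_symmetric_scores_and_zero_penalty(self):
        assert critic_loss(np.array([1.0, 2.0]), np.array([1.0, 2.0]), 0.0, 10.0).item() == 0.0

    def test_arithmetic(self):
        val = critic_loss(np.array([1.0, 1.0]), np.array([0.0, 0.0]), 0.0, 10.0)
        assert val.item() == pytest.approx(-1.0)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            critic_loss(np.array([]), np.array([1.0]), 0.0, 10.0)


class TestGradientPenalty:
    def _batches(self, rng, shape=(4, 1, 3, 5)):
        return rng.normal(size=shape), rng.normal(size=shape)

    def test_unit_norm_linear_critic_has_zero_penalty(self, rng):
        real, fake = self._batches(rng)
        w = rng.normal(size=15)
        gp = gradient_penalty(LinearCritic(w / np.linalg.norm(w)), real, fake, seed=0)
        assert gp.item() == pytest.approx(0.0, abs=1e-10)

    def test_double_norm_critic_penalty_is_one(self, rng):
        real, fake = self._batches(rng)
        w = rng.normal(size=15)
        gp = gradient_penalty(LinearCritic(2 * w / np.linalg.norm(w)), real, fake, seed=0)
        assert gp.item() == pytest.approx(1.0, abs=1e-8)

    def test_constant_critic_penalty_is_one(self, rng):
        real, fake = self._batches(rng)
        gp = gradient_penalty(LinearCritic(np.zeros(15)), real, fake, seed=0)
        assert gp.item() == pytest.approx(1.0, abs=1e-5)  # sqrt(eps) guard

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            gradient_penalty(LinearCritic(np.ones(4)), rng.normal(size=(2, 2)), rng.normal(size=(3, 2)))

    def test_penalty_trains_conv_critic_toward_unit_gradients(self, rng):
        """Second-order path: minimizing the penalty alone drives the conv
        critic's input-gradient norms toward 1."""
        from sptsr.nn import Adam, grad

        critic = build_critic(CriticConfig(base_channels=4, n_conv_blocks=2, seed=3))
        opt = Adam(critic.parameters(), lr=1e-3)
        real, fake = self._batches(rng, (4, 1, 8, 8))
        before = gradient_penalty(critic, real, fake, seed=1).item()
        for i in range(30):
            gp = gradient_penalty(critic, real, fake, seed=1)
            opt.step(grad(gp, critic.parameters()))
        after = gradient_penalty(critic, real, fake, seed=1).item()
        assert after < before


class TestGeneratorLoss:
    def test_perfect_reconstruction_zero_scores(self, rng):
        sr = rng.normal(size=(2, 1, 4, 4))
        val = generator_loss(sr, sr.copy(), np.zeros(2), None, (1e-3, 1.0, 1e-6))
        assert val.item() == pytest.approx(0.0)

    def test_constant_error_mse_arithmetic(self, rng):
        hr = rng.normal(size=(2, 1, 4, 4))
        val = generator_loss(hr + 2.0, hr, None, None, (0.0, 1.0, 0.0))
        assert val.item() == pytest.approx(4.0)

    def test_default_weights_reproduce_component_magnitudes(self, rng):
        # weights (1e-3, 1, 1e-6): the MSE term dominates, adversarial is
        # milli-scale, perceptual micro-scale
        hr = rng.normal(size=(2, 1, 4, 4))
        sr = hr + 1.0
        scores = np.full(2, -1.0)
        w = (1e-3, 1.0, 1e-6)
        total = generator_loss(sr, hr, scores, lambda x: x, w).item()
        assert total == pytest.approx(1e-3 * 1.0 + 1.0 * 1.0 + 1e-6 * 1.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            generator_loss(rng.normal(size=(1, 1, 2, 2)), rng.normal(size=(1, 1, 2, 3)), None)


def tiny_pairs(rng, n, n_lr=8, ns=4, factor=4):
    pairs = []
    for _ in range(n):
        lr = rng.uniform(0.1, 1.0, size=(3, n_lr, ns))
        hr = rng.uniform(0.1, 1.0, size=(1, n_lr, ns * factor))
        pairs.append(TrainingPair(lr, hr))
    return pairs


def tiny_configs(epochs=2, **kw):
    gen = GeneratorConfig(base_channels=4, n_residual_blocks=1, upsample_factor=4.0,
                          head_kernel=3, tail_kernel=3)
    critic = CriticConfig(base_channels=4, n_conv_blocks=2)
    kw.setdefault("batch_size", 8)
    kw.setdefault("learning_rate", 1e-3)
    kw.setdefault("critic_steps_per_gen_step", 1)
    tc = TrainConfig(epochs=epochs, **kw)
    return gen, critic, tc


class TestTrainLoop:
    def test_bookkeeping_tiny_run(self, rng):
        gen, critic, tc = tiny_configs(epochs=2)
        ck = train(tiny_pairs(rng, 32), tiny_pairs(rng, 4), gen, critic, tc)
        assert len(ck.history["val_mse"]) == 2
        assert len(ck.history["critic_loss"]) == 2
        assert 0 <= ck.best_epoch < 2

    def test_overfit_small_set_halves_training_mse(self, rng):
        # 4 pairs, many steps of pure-MSE regression: train MSE must drop by
        # at least half from its first-epoch value
        gen, critic, tc = tiny_configs(epochs=50, batch_size=4, loss_weights=(0.0, 1.0, 0.0),
                                       learning_rate=3e-3)
        pairs = tiny_pairs(rng, 4)
        ck = train(pairs, tiny_pairs(rng, 2), gen, critic, tc)
        tm = ck.history["train_mse"]
        assert min(tm) <= 0.5 * tm[0]

    def test_epoch_selection_is_argmin(self):
        assert select_best_epoch([0.5, 0.2, 0.3]) == 1

    def test_checkpoint_from_best_epoch(self, rng):
        gen, critic, tc = tiny_configs(epochs=3, loss_weights=(0.0, 1.0, 0.0))
        ck = train(tiny_pairs(rng, 16), tiny_pairs(rng, 4), gen, critic, tc)
        assert ck.best_epoch == int(np.argmin(ck.history["val_mse"]))

    def test_deterministic_given_seed(self, rng):
        gen, critic, tc = tiny_configs(epochs=2, seed=11)
        p_train, p_val = tiny_pairs(rng, 16), tiny_pairs(rng, 4)
        a = train(p_train, p_val, gen, critic, tc)
        b = train(p_train, p_val, gen, critic, tc)
        assert a.history == b.history
        for x, y in zip(a.generator_state, b.generator_state):
            np.testing.assert_array_equal(x, y)

    def test_pure_mse_running_minimum_monotone(self, rng):
        gen, critic, tc = tiny_configs(epochs=8, loss_weights=(0.0, 1.0, 0.0))
        ck = train(tiny_pairs(rng, 24), tiny_pairs(rng, 4), gen, critic, tc)
        v = ck.history["val_mse"]
        run_min = np.minimum.accumulate(v)
        assert all(np.diff(run_min) <= 0)

    def test_empty_datasets_rejected(self, rng):
        gen, critic, tc = tiny_configs()
        with pytest.raises(ValueError):
            train([], tiny_pairs(rng, 2), gen, critic, tc)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        gen, critic, tc = tiny_configs(epochs=1)
        ck = train(tiny_pairs(rng, 8), tiny_pairs(rng, 2), gen, critic, tc)
        path = tmp_path / "ck.npz"
        ck.save(path)
        from sptsr.training import Checkpoint

        back = Checkpoint.load(path)
        assert back.best_epoch == ck.best_epoch
        assert back.norm_scale == ck.norm_scale
        x = rng.normal(size=(1, 3, 8, 4))
        np.testing.assert_array_equal(back.build().infer(x), ck.build().infer(x))


class TestOverfitDetection:
    def test_upturned_curve_flagged(self):
        v = list(np.linspace(1.0, 0.2, 10)) + list(np.linspace(0.25, 0.6, 10))
        assert shows_overfitting(v)

    def test_plateau_not_flagged(self):
        v = list(np.linspace(1.0, 0.2, 15)) + [0.2, 0.201, 0.199, 0.2, 0.2]
        assert not shows_overfitting(v)
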