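"""WGAN-GP training of the SR generator with validation-MSE epoch selection.

The critic minimizes  mean(fake) - mean(real) + lambda * GP  where GP is the
gradient penalty  E[(||grad_xhat D(xhat)||_2 - 1)^2]  at random interpolates
xhat between real and generated slices.  The generator minimizes a weighted
sum of the adversarial score, pixel MSE, and a pluggable perceptual feature
MSE:

    L_G = w_adv * (-mean(D(G(x)))) + w_mse * MSE(G(x), y)
          + w_perc * MSE(f(G(x)), f(y)).

Default weights are (1e-3, 1, 1e-6); the perceptual feature extractor ``f``
is pluggable (a pretrained feature network can be supplied) and defaults to
the identity, with ``w_perc = 0`` so the default configuration needs no
external assets.  Training runs a fixed number of epochs and the checkpoint
returned is the one with the lowest validation MSE.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .nn import Adam, Tensor, grad, no_grad
from .nn.layers import Module
from .network import Critic, CriticConfig, Generator, GeneratorConfig, build_critic, build_generator
from .observation import TrainingPair

__all__ = [
    "TrainConfig",
    "Checkpoint",
    "critic_loss",
    "gradient_penalty",
    "generator_loss",
    "train",
    "select_best_epoch",
    "shows_overfitting",
]


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-4
    loss_weights: tuple[float, float, float] = (1e-3, 1.0, 0.0)  # (w_adv, w_mse, w_perc)
    gp_weight: float = 10.0
    critic_steps_per_gen_step: int = 5
    lr_decay: float = 1.0  # multiplicative per-epoch learning-rate factor
    seed: int = 0
    normalize_percentile: float = 99.5

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("epochs and batch size must be >= 1")
        if any(w < 0 for w in self.loss_weights) or self.gp_weight < 0:
            raise ValueError("loss weights must be non-negative")


@dataclasses.dataclass
class Checkpoint:
    """Best-epoch weights plus everything needed to reproduce inference."""

    generator_config: GeneratorConfig
    generator_state: list[np.ndarray]
    critic_config: CriticConfig
    critic_state: list[np.ndarray]
    train_config: TrainConfig
    norm_scale: float
    best_epoch: int
    history: dict[str, list[float]]

    def build(self) -> Generator:
        gen = build_generator(self.generator_config)
        gen.load_state_arrays(self.generator_state)
        return gen

    def save(self, path) -> None:
        meta = {
            "generator_config": dataclasses.asdict(self.generator_config),
            "critic_config": dataclasses.asdict(self.critic_config),
            "train_config": dataclasses.asdict(self.train_config),
            "norm_scale": self.norm_scale,
            "best_epoch": self.best_epoch,
            "history": self.history,
        }
        arrays = {f"g{i}": a for i, a in enumerate(self.generator_state)}
        arrays.update({f"c{i}": a for i, a in enumerate(self.critic_state)})
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as z:
            meta = json.loads(z["meta"].tobytes().decode())
            gstate = [z[f"g{i}"] for i in range(sum(1 for k in z.files if k.startswith("g")))]
            cstate = [z[f"c{i}"] for i in range(sum(1 for k in z.files if k.startswith("c")))]
        tc = dict(meta["train_config"])
        tc["loss_weights"] = tuple(tc["loss_weights"])
        return cls(
            generator_config=GeneratorConfig(**meta["generator_config"]),
            generator_state=gstate,
            critic_config=CriticConfig(**meta["critic_config"]),
            critic_state=cstate,
            train_config=TrainConfig(**tc),
            norm_scale=meta["norm_scale"],
            best_epoch=meta["best_epoch"],
            history=meta["history"],
        )


# ---------------------------------------------------------------------------
# loss components
# ---------------------------------------------------------------------------

def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def critic_loss(real_scores, fake_scores, gradient_penalty_value, gp_weight: float) -> Tensor:
    """Wasserstein critic loss with gradient penalty."""
    real_scores, fake_scores = _t(real_scores), _t(fake_scores)
    if real_scores.size == 0 or fake_scores.size == 0:
        raise ValueError("empty score batch")
    return fake_scores.mean() - real_scores.mean() + gp_weight * _t(gradient_penalty_value)


def gradient_penalty(critic: Module, real_batch, fake_batch, seed: int = 0) -> Tensor:
    """E[(||grad_xhat critic(xhat)|| - 1)^2] at xhat = eps*real + (1-eps)*fake.

    The returned tensor keeps a differentiable graph through the critic's
    weights (second-order), so it can be part of the critic's training loss.
    """
    real = np.asarray(real_batch.data if isinstance(real_batch, Tensor) else real_batch)
    fake = np.asarray(fake_batch.data if isinstance(fake_batch, Tensor) else fake_batch)
    if real.shape != fake.shape:
        raise ValueError(f"shape mismatch between real {real.shape} and fake {fake.shape}")
    rng = np.random.default_rng(seed)
    eps = rng.uniform(size=(real.shape[0],) + (1,) * (real.ndim - 1))
    xhat = Tensor(eps * real + (1.0 - eps) * fake, requires_grad=True)
    score_sum = critic(xhat).sum()
    gx = grad(score_sum, [xhat], create_graph=True)[0]
    sq = (gx * gx).sum(axis=tuple(range(1, real.ndim)))
    norms = (sq + 1e-12).sqrt()
    return ((norms - 1.0) ** 2).mean()


def generator_loss(sr, hr, fake_scores, features_fn=None, weights=(1e-3, 1.0, 0.0)) -> Tensor:
    """Composite generator loss: adversarial + MSE + perceptual-feature MSE."""
    sr, hr = _t(sr), _t(hr)
    if sr.shape != hr.shape:
        raise ValueError(f"shape mismatch between SR {sr.shape} and HR {hr.shape}")
    w_adv, w_mse, w_perc = weights
    loss = _t(0.0)
    if w_adv != 0.0:
        loss = loss + w_adv * (-_t(fake_scores).mean())
    if w_mse != 0.0:
        loss = loss + w_mse * ((sr - hr) ** 2).mean()
    if w_perc != 0.0:
        f = features_fn if features_fn is not None else (lambda x: x)
        fs, fh = f(sr), f(hr)
        loss = loss + w_perc * ((fs - fh) ** 2).mean()
    return loss


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _stack_pairs(pairs: list[TrainingPair]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([p.lr_triplet for p in pairs]).astype(np.float64)
    Y = np.stack([p.hr_target for p in pairs]).astype(np.float64)
    return X, Y


def _check_finite(value: float, what: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"training diverged: {what} became non-finite at epoch {epoch}")


def select_best_epoch(val_mse: list[float]) -> int:
    """0-based index of the epoch with minimal validation MSE."""
    return int(np.argmin(val_mse))


def shows_overfitting(val_mse: list[float], tail_frac: float = 0.25, margin: float = 1.10) -> bool:
    """True when the validation-MSE curve turns upward: the mean over the
    final ``tail_frac`` of epochs exceeds ``margin`` times the curve minimum."""
    v = np.asarray(val_mse, dtype=float)
    tail = v[max(1, int(len(v) * (1 - tail_frac))):]
    return bool(tail.mean() > margin * v.min())


def _val_mse(gen: Generator, X: np.ndarray, Y: np.ndarray, batch: int = 32) -> float:
    se, n = 0.0, 0
    for i in range(0, X.shape[0], batch):
        out = gen.infer(X[i : i + batch])
        se += float(((out - Y[i : i + batch]) ** 2).sum())
        n += Y[i : i + batch].size
    return se / n


def train(
    train_pairs: list[TrainingPair],
    val_pairs: list[TrainingPair],
    gen_cfg: GeneratorConfig | None = None,
    critic_cfg: CriticConfig | None = None,
    train_cfg: TrainConfig | None = None,
    features_fn=None,
    progress=None,
) -> Checkpoint:
    """Run the adversarial training loop and return the best-epoch checkpoint.

    Slices are normalized to [0, 1] by the training set's 99.5th-percentile
    intensity before training; the scale is stored in the checkpoint so
    inference can restore physical units.  With ``w_adv = w_perc = 0`` the
    loop degenerates to pure MSE regression and all critic updates are
    skipped.  Fully seeded and deterministic.
    """
    if len(train_pairs) < 1 or len(val_pairs) < 1:
        raise ValueError("need at least one training and one validation pair")
    cfg = train_cfg or TrainConfig()
    gen_cfg = gen_cfg or GeneratorConfig()
    critic_cfg = critic_cfg or CriticConfig()
    w_adv, w_mse, w_perc = cfg.loss_weights
    adversarial = w_adv != 0.0

    Xtr, Ytr = _stack_pairs(train_pairs)
    Xva, Yva = _stack_pairs(val_pairs)
    scale = float(np.percentile(Ytr, cfg.normalize_percentile))
    if scale <= 0:
        scale = max(float(Ytr.max()), 1.0)
    Xtr, Ytr, Xva, Yva = Xtr / scale, Ytr / scale, Xva / scale, Yva / scale

    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(dataclasses.replace(gen_cfg, seed=int(rng.integers(2**31))))
    critic = build_critic(dataclasses.replace(critic_cfg, seed=int(rng.integers(2**31))))
    opt_g = Adam(gen.parameters(), lr=cfg.learning_rate)
    opt_c = Adam(critic.parameters(), lr=cfg.learning_rate)

    n = Xtr.shape[0]
    history: dict[str, list[float]] = {"critic_loss": [], "generator_loss": [], "train_mse": [], "val_mse": []}
    best: tuple[float, int, list[np.ndarray], list[np.ndarray]] | None = None

    for epoch in range(cfg.epochs):
        if epoch > 0 and cfg.lr_decay != 1.0:
            opt_g.lr *= cfg.lr_decay
            opt_c.lr *= cfg.lr_decay
        order = rng.permutation(n)
        ep_c, ep_g, ep_mse, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]

            if adversarial:
                for _ in range(cfg.critic_steps_per_gen_step):
                    fake = gen.infer(xb)
                    real_s = critic(Tensor(yb))
                    fake_s = critic(Tensor(fake))
                    gp = gradient_penalty(critic, yb, fake, seed=int(rng.integers(2**31)))
                    c_loss = critic_loss(real_s, fake_s, gp, cfg.gp_weight)
                    opt_c.step(grad(c_loss, critic.parameters()))
                ep_c += c_loss.item()

            sr = gen.forward(Tensor(xb))
            fake_scores = critic(sr) if adversarial else None
            g_loss = generator_loss(sr, Tensor(yb), fake_scores, features_fn, cfg.loss_weights)
            opt_g.step(grad(g_loss, gen.parameters()))
            ep_g += g_loss.item()
            with no_grad():
                ep_mse += float(((sr.data - yb) ** 2).mean())
            n_batches += 1

        val = _val_mse(gen, Xva, Yva)
        _check_finite(ep_g, "generator loss", epoch)
        _check_finite(val, "validation MSE", epoch)
        history["critic_loss"].append(ep_c / n_batches if adversarial else 0.0)
        history["generator_loss"].append(ep_g / n_batches)
        history["train_mse"].append(ep_mse / n_batches)
        history["val_mse"].append(val)
        if best is None or val < best[0]:
            best = (val, epoch, [a.copy() for a in gen.state_arrays()], [a.copy() for a in critic.state_arrays()])
        if progress is not None:
            progress(epoch, history)

    assert best is not None
    return Checkpoint(
        generator_config=gen.config,
        generator_state=best[2],
        critic_config=critic.config,
        critic_state=best[3],
        train_config=cfg,
        norm_scale=scale,
        best_epoch=best[1],
        history=history,
    )
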