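"""Generator and critic architectures for through-plane super-resolution.

The generator follows the SRGAN residual-trunk lineage with three changes
suited to anisotropic multi-slice data: (i) three consecutive LR slices
enter as input channels, the middle slice being the SR target; (ii) the
upsampling blocks perform 1D sub-pixel upsampling along the through-plane
(SI) axis only; (iii) non-integer upsampling factors are realized
rationally, e.g. 5.5x = sub-pixel x11 followed by average pooling x2.

The critic maps a slice to an unbounded scalar score and deliberately
contains no normalization layers and no terminal squashing, as required for
Wasserstein training with a gradient penalty.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction

import numpy as np

from .nn import (
    AvgPool1D,
    Conv2d,
    Linear,
    Module,
    ResidualBlock,
    SubPixelUpsample1D,
    Tensor,
    count_parameters,
    leaky_relu,
    no_grad,
)

__all__ = [
    "GeneratorConfig",
    "CriticConfig",
    "Generator",
    "Critic",
    "build_generator",
    "build_critic",
    "count_parameters",
    "describe",
    "LinearResizeStub",
]


@dataclasses.dataclass
class GeneratorConfig:
    in_slices: int = 3
    base_channels: int = 48
    n_residual_blocks: int = 8
    upsample_factor: float = 5.5
    activation: str = "leaky_relu"
    alpha: float = 0.2
    head_kernel: int = 9
    tail_kernel: int = 9
    interp_skip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_slices != 3:
            raise ValueError("the SR mapping takes exactly 3 consecutive LR slices")
        if self.upsample_factor <= 1:
            raise ValueError("upsample factor must exceed 1")

    @property
    def rational_factor(self) -> tuple[int, int]:
        """(p, q) with factor = p/q, q in {1, 2}-style small denominators."""
        frac = Fraction(self.upsample_factor).limit_denominator(16)
        if abs(float(frac) - self.upsample_factor) > 1e-9:
            raise ValueError(
                f"factor {self.upsample_factor} has no small rational realization"
            )
        return frac.numerator, frac.denominator


@dataclasses.dataclass
class CriticConfig:
    base_channels: int = 32
    n_conv_blocks: int = 4
    no_batch_norm: bool = True
    no_output_squash: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        # structural guarantees of the Wasserstein critic are not optional
        if not self.no_batch_norm or not self.no_output_squash:
            raise ValueError("the critic must have no batch norm and no output squashing")


def _upsample_stages(p: int) -> list[int]:
    """Split an integer sub-pixel factor into small stages (2s and 3s)."""
    stages = []
    while p % 2 == 0 and p > 1:
        stages.append(2)
        p //= 2
    while p % 3 == 0 and p > 1:
        stages.append(3)
        p //= 3
    if p > 1:
        stages.append(p)
    return stages


def _linear_resize_last(arr: np.ndarray, n_out: int) -> np.ndarray:
    """Linear resize along the last axis with the voxel-center convention."""
    w = arr.shape[-1]
    factor = n_out / w
    src = (np.arange(n_out) + 0.5) / factor - 0.5
    lo = np.clip(np.floor(src).astype(int), 0, w - 1)
    hi = np.clip(lo + 1, 0, w - 1)
    t = np.clip(src - lo, 0.0, 1.0)
    return arr[..., lo] * (1 - t) + arr[..., hi] * t


class Generator(Module):
    """Residual SR generator: (B, 3, N_LR, NS_SI) -> (B, 1, N_LR, N_SI)."""

    def __init__(self, config: GeneratorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        C = config.base_channels
        p, q = config.rational_factor
        self.head = Conv2d(config.in_slices, C, config.head_kernel, rng=rng)
        self.blocks = [ResidualBlock(C, rng=rng, alpha=config.alpha) for _ in range(config.n_residual_blocks)]
        self.post = Conv2d(C, C, 3, rng=rng)
        self.upsamples = [SubPixelUpsample1D(C, r, rng=rng, alpha=config.alpha) for r in _upsample_stages(p)]
        self.pool = AvgPool1D(q) if q > 1 else None
        self.tail = Conv2d(C, 1, config.tail_kernel, rng=rng)
        if config.interp_skip:
            # zero-init the residual branch output: training starts exactly
            # at the linear-interpolation solution
            self.tail.weight.data[:] = 0.0
        self._pq = (p, q)

    def forward(self, x: Tensor) -> Tensor:
        p, q = self._pq
        W = x.shape[3]
        if (W * p) % q != 0:
            raise ValueError(
                f"input SI extent {W} is incompatible with the rational factor {p}/{q}"
            )
        h0 = leaky_relu(self.head(x), self.config.alpha)
        h = h0
        for blk in self.blocks:
            h = blk(h)
        h = self.post(h) + h0  # global residual skip around the trunk
        for up in self.upsamples:
            h = up(h)
        if self.pool is not None:
            h = self.pool(h)
        out = self.tail(h)
        if self.config.interp_skip:
            # global skip: the trunk learns the residual around a linear
            # upsampling of the center slice (input carries no gradient)
            out = out + Tensor(_linear_resize_last(x.data[:, 1:2], out.shape[3]))
        return out

    def infer(self, x: np.ndarray) -> np.ndarray:
        """Deterministic forward pass on a numpy batch (no graph)."""
        with no_grad():
            return self.forward(Tensor(x)).data


class Critic(Module):
    """Convolutional critic: (B, 1, H, W) -> unbounded score per sample."""

    def __init__(self, config: CriticConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        C = config.base_channels
        convs = []
        c_in = 1
        c_out = C
        for i in range(config.n_conv_blocks):
            stride = 2 if i % 2 == 1 else 1
            convs.append(Conv2d(c_in, c_out, 3, stride=stride, rng=rng))
            c_in = c_out
            if i % 2 == 1:
                c_out = min(c_out * 2, 8 * C)
        self.convs = convs
        self.fc = Linear(c_in, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = leaky_relu(conv(h), 0.2)
        h = h.mean(axis=(2, 3))  # (B, C): global average, size-agnostic
        s = self.fc(h)  # (B, 1)
        return s.reshape((s.shape[0],))


def build_generator(config: GeneratorConfig | None = None) -> Generator:
    return Generator(config or GeneratorConfig())


def build_critic(config: CriticConfig | None = None) -> Critic:
    return Critic(config or CriticConfig())


def describe(module: Module) -> str:
    """Human-readable layer table with the exact trainable-parameter count."""
    lines = [f"{type(module).__name__}"]

    def walk(mod: Module, indent: int) -> None:
        for name, v in mod.__dict__.items():
            items = v if isinstance(v, (list, tuple)) else [v]
            for i, item in enumerate(items):
                if isinstance(item, Module):
                    tag = f"{name}[{i}]" if isinstance(v, (list, tuple)) else name
                    lines.append("  " * indent + f"{tag}: {type(item).__name__} ({count_parameters(item):,} params)")
                    walk(item, indent + 1)

    walk(module, 1)
    lines.append(f"total trainable parameters: {count_parameters(module):,}")
    return "\n".join(lines)


class LinearResizeStub:
    """Identity 'model' for pipeline testing: linearly resizes the center
    slice along the SI axis (voxel-center convention), ignoring neighbors."""

    def __init__(self, factor: float):
        self.factor = factor

    def infer(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        n_out = int(round(self.factor * W))
        src = (np.arange(n_out) + 0.5) / self.factor - 0.5
        center = x[:, 1, :, :]
        lo = np.clip(np.floor(src).astype(int), 0, W - 1)
        hi = np.clip(lo + 1, 0, W - 1)
        t = np.clip(src - lo, 0.0, 1.0)
        out = center[:, :, lo] * (1 - t) + center[:, :, hi] * t
        return out[:, None, :, :]
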