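"""Neural-network building blocks on the autodiff engine.

Convolutions are lowered to gather (im2col) + matmul; the flat-index tables
are cached per (input shape, kernel, stride, padding).  Initialization is
Kaiming fan-in scaling from a seeded generator, recorded so runs are
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, gather, leaky_relu, matmul, reshape, scatter, transpose

__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "LeakyReLU",
    "ResidualBlock",
    "SubPixelUpsample1D",
    "AvgPool1D",
    "Sequential",
    "count_parameters",
]


class Module:
    """Base class: parameter collection and deterministic forward."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.array(a, dtype=np.float64)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape)


_IM2COL_CACHE: dict[tuple, tuple[np.ndarray, tuple]] = {}


def _im2col_indices(shape, kh, kw, stride, pad):
    key = (shape, kh, kw, stride, pad)
    hit = _IM2COL_CACHE.get(key)
    if hit is not None:
        return hit
    B, C, H, W = shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    # rows: (c, kh, kw) patch coordinate; columns: (b, oi, oj) output site —
    # the whole batch folds into one GEMM
    c = np.arange(C)[:, None, None, None, None, None]
    di = np.arange(kh)[None, :, None, None, None, None]
    dj = np.arange(kw)[None, None, :, None, None, None]
    b = np.arange(B)[None, None, None, :, None, None]
    oi = np.arange(OH)[None, None, None, None, :, None] * stride
    oj = np.arange(OW)[None, None, None, None, None, :] * stride
    idx = ((b * C + c) * Hp + (di + oi)) * Wp + (dj + oj)
    idx = np.ascontiguousarray(idx.reshape(C * kh * kw, B * OH * OW))
    out = (idx, (OH, OW, Hp, Wp))
    _IM2COL_CACHE[key] = out
    return out


_PAD_CACHE: dict[tuple, np.ndarray] = {}


def _pad_indices(shape, pad):
    key = (shape, pad)
    hit = _PAD_CACHE.get(key)
    if hit is not None:
        return hit
    B, C, H, W = shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    b = np.arange(B)[:, None, None, None]
    c = np.arange(C)[None, :, None, None]
    i = np.arange(H)[None, None, :, None] + pad
    j = np.arange(W)[None, None, None, :] + pad
    idx = ((b * C + c) * Hp + i) * Wp + j
    _PAD_CACHE[key] = idx
    return idx


class Conv2d(Module):
    """2D convolution with bias, stride and zero padding."""

    def __init__(self, c_in, c_out, kernel, stride=1, pad=None, rng=None):
        if isinstance(kernel, int):
            kernel = (kernel, kernel)
        self.kh, self.kw = kernel
        self.stride = stride
        self.pad = (self.kh // 2) if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * self.kh * self.kw
        self.weight = Tensor(_kaiming(rng, (c_out, c_in, self.kh, self.kw), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if self.pad > 0:
            idx = _pad_indices(x.shape, self.pad)
            Hp, Wp = H + 2 * self.pad, W + 2 * self.pad
            x = reshape(scatter(x, idx, B * C * Hp * Wp), (B, C, Hp, Wp))
        cols_idx, (OH, OW, _, _) = _im2col_indices((B, C, H, W), self.kh, self.kw, self.stride, self.pad)
        cols = gather(x, cols_idx)  # (C*kh*kw, B*OH*OW)
        O = self.weight.shape[0]
        wmat = reshape(self.weight, (O, C * self.kh * self.kw))
        out = matmul(wmat, cols) + reshape(self.bias, (O, 1))  # (O, B*OH*OW)
        out = reshape(out, (O, B, OH, OW))
        return transpose(out, (1, 0, 2, 3))


class Linear(Module):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_kaiming(rng, (n_in, n_out), n_in), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + reshape(self.bias, (1, self.bias.shape[0]))


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x: Tensor) -> Tensor:
        return leaky_relu(x, self.alpha)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ResidualBlock(Module):
    """conv - activation - conv with an identity skip (no normalization)."""

    def __init__(self, channels, rng=None, alpha=0.2):
        self.conv1 = Conv2d(channels, channels, 3, rng=rng)
        self.conv2 = Conv2d(channels, channels, 3, rng=rng)
        self.alpha = alpha

    def forward(self, x: Tensor) -> Tensor:
        h = leaky_relu(self.conv1(x), self.alpha)
        return x + self.conv2(h)


class SubPixelUpsample1D(Module):
    """Learned 1D sub-pixel upsampling: conv to ``r x C`` channels, then a
    1D pixel shuffle that interleaves them along the last (SI) axis."""

    def __init__(self, channels, r, rng=None, alpha=0.2):
        self.r = r
        self.conv = Conv2d(channels, channels * r, 3, rng=rng)
        self.alpha = alpha

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv(x)  # (B, C*r, H, W)
        B, Cr, H, W = h.shape
        C = Cr // self.r
        h = reshape(h, (B, C, self.r, H, W))
        h = transpose(h, (0, 1, 3, 4, 2))  # (B, C, H, W, r)
        h = reshape(h, (B, C, H, W * self.r))
        return leaky_relu(h, self.alpha)


class AvgPool1D(Module):
    """Average pooling by an integer factor along the last axis."""

    def __init__(self, q: int):
        self.q = q

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if W % self.q != 0:
            raise ValueError(f"extent {W} not divisible by pool factor {self.q}")
        h = reshape(x, (B, C, H, W // self.q, self.q))
        return h.mean(axis=4)


def count_parameters(module: Module) -> int:
    """Exact count of trainable scalars."""
    return int(sum(p.size for p in module.parameters()))
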