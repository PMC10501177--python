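"""Richardson-Lucy slice-profile deconvolution along one axis.

The through-plane SR volume is still convolved by the slice profile along AP
(an elongated effective voxel); deconvolving with the same 1D kernel turns
it into the isotropic result.  Richardson-Lucy is the multiplicative EM
iteration for a Poisson observation model,

    u <- u * H^T(d / (H u)) / H^T(1),

which preserves non-negativity and, in the noiseless case, monotonically
improves the Poisson likelihood.  ``H`` is the exact 1D blur matrix of the
slice profile (boundary-renormalized or reflected), and its true transpose
is used, so constants are exact fixed points under both boundary modes.

A damped ("noise-robust") variant attenuates the multiplicative correction
where the residual ``d - Hu`` is within a configurable noise floor, which
prevents noise amplification at late iterations; ``damping_threshold = 0``
recovers plain RL.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import VolumeGrid
from .kernelops import apply_matrix_along_axis, blur_matrix
from .profiles import SliceProfile, resample_profile

__all__ = ["DeconvConfig", "rl_deconvolve"]


@dataclasses.dataclass
class DeconvConfig:
    """Iteration and stabilization settings for the RL deconvolution.

    ``n_iterations`` defaults to 20, chosen on blur-then-restore synthetic
    benchmarks as the point of diminishing RMSE returns for 3 mm-FWHM
    kernels on sub-millimeter grids.  ``damping_threshold`` is relative to
    the data maximum (0 disables damping).  ``nonneg_floor`` is the relative
    epsilon used to floor magnitude images away from zero divisions.
    """

    n_iterations: int = 20
    damping_threshold: float = 0.0
    boundary: str = "renormalize"
    nonneg_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("need at least one RL iteration")
        if self.damping_threshold < 0:
            raise ValueError("damping threshold must be >= 0")
        if self.boundary not in ("renormalize", "reflect"):
            raise ValueError(f"unknown boundary {self.boundary!r}")


def rl_deconvolve(
    volume: VolumeGrid,
    profile: SliceProfile,
    axis: int = 1,
    config: DeconvConfig | None = None,
) -> VolumeGrid:
    """Deconvolve a volume along one axis with a 1D slice-profile kernel.

    Parameters
    ----------
    volume:
        Non-negative (magnitude) volume; values are floored at
        ``nonneg_floor * max`` to avoid division blow-ups.
    profile:
        Normalized slice profile; resampled onto the volume's grid along
        ``axis``.
    axis:
        Canonical axis to deconvolve (default 1 = AP).
    """
    cfg = config or DeconvConfig()
    data = np.asarray(volume.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values")
    if np.any(data < 0):
        raise ValueError("RL deconvolution expects a non-negative (magnitude) volume")
    grid = volume.spacing_mm[axis]
    prof = resample_profile(profile, grid)
    n = data.shape[axis]
    if prof.weights.size > n:
        raise ValueError("profile support exceeds the axis extent")
    if prof.weights.size == 1:
        return volume.copy_with(data=data.copy())

    H = blur_matrix(n, prof.weights, boundary=cfg.boundary)
    Ht = H.T
    # normalization field H^T 1 (column sums), strictly positive
    ht_one = Ht @ np.ones(n)

    peak = data.max()
    floor = cfg.nonneg_floor * (peak if peak > 0 else 1.0)
    d = np.maximum(data, floor)
    u = d.copy()
    damp_scale = cfg.damping_threshold * peak if cfg.damping_threshold > 0 else 0.0

    def along(M, x):
        return apply_matrix_along_axis(M, x, axis)

    shape_b = [1, 1, 1]
    shape_b[axis] = n
    ht_one_b = ht_one.reshape(shape_b)

    for _ in range(cfg.n_iterations):
        hu = np.maximum(along(H, u), floor)
        ratio = d / hu
        if damp_scale > 0.0:
            # attenuate corrections where the residual is within the noise floor
            m = np.minimum(1.0, ((d - hu) / damp_scale) ** 2)
            ratio = 1.0 + m * (ratio - 1.0)
        u = u * along(Ht, ratio) / ht_one_b
        u = np.maximum(u, 0.0)
    return volume.copy_with(data=u)
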