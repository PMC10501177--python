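"""Volumetric image-quality metrics and paired method comparisons.

PSNR is ``10 log10(peak^2 / MSE)`` with the peak defaulting to the reference
maximum (configurable for cross-run comparability); NMSE is the squared
error normalized by the reference energy, stored as a raw ratio (display
scalings such as x10^-2 are applied at report time); SSIM is the standard
windowed index computed slice-wise in a named plane and averaged.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

from .geometry import STACK_AXIS, VolumeGrid

__all__ = ["MetricsReport", "psnr", "nmse", "ssim_slicewise", "paired_compare", "evaluate_volume"]


def _check_grids(test: VolumeGrid, ref: VolumeGrid) -> None:
    if test.shape != ref.shape:
        raise ValueError(f"grid mismatch: {test.shape} vs {ref.shape}")
    if not np.allclose(test.spacing_mm, ref.spacing_mm, rtol=1e-6):
        raise ValueError(f"spacing mismatch: {test.spacing_mm} vs {ref.spacing_mm}")


def psnr(test: VolumeGrid, ref: VolumeGrid, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical volumes."""
    _check_grids(test, ref)
    mse = float(np.mean((test.data - ref.data) ** 2))
    if mse == 0.0:
        return float("inf")
    if peak is None:
        peak = float(ref.data.max())
    return float(10.0 * np.log10(peak**2 / mse))


def nmse(test: VolumeGrid, ref: VolumeGrid) -> float:
    """||test - ref||^2 / ||ref||^2 (scale-invariant under joint rescaling)."""
    _check_grids(test, ref)
    denom = float(np.sum(ref.data**2))
    if denom == 0.0:
        raise ValueError("reference volume has zero energy")
    return float(np.sum((test.data - ref.data) ** 2) / denom)


def ssim_slicewise(test: VolumeGrid, ref: VolumeGrid, plane: str = "coronal") -> float:
    """Mean SSIM over the slices of the named plane (11-tap Gaussian window).

    Note SSIM is only approximately invariant to global affine intensity
    changes; exact invariance is not expected or asserted anywhere.
    """
    _check_grids(test, ref)
    axis = STACK_AXIS[plane]
    data_range = float(ref.data.max() - ref.data.min())
    if data_range == 0.0:
        return 1.0 if np.array_equal(test.data, ref.data) else 0.0
    vals = []
    for i in range(test.shape[axis]):
        t = np.take(test.data, i, axis=axis)
        r = np.take(ref.data, i, axis=axis)
        vals.append(
            structural_similarity(
                r, t, data_range=data_range, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False,
            )
        )
    return float(np.mean(vals))


@dataclasses.dataclass
class MetricsReport:
    """Per-volume metrics for one labelled method plus aggregates."""

    method: str
    per_volume: list[tuple[float, float, float]]  # (psnr_db, nmse, ssim)

    @property
    def aggregate(self) -> dict[str, tuple[float, float]]:
        arr = np.asarray(self.per_volume, dtype=float)
        names = ("psnr_db", "nmse", "ssim")
        return {n: (float(arr[:, i].mean()), float(arr[:, i].std(ddof=1)) if len(arr) > 1 else 0.0)
                for i, n in enumerate(names)}

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "per_volume": [list(v) for v in self.per_volume],
            "aggregate": {k: list(v) for k, v in self.aggregate.items()},
        }


def evaluate_volume(test: VolumeGrid, ref: VolumeGrid, plane: str = "coronal",
                    peak: float | None = None) -> tuple[float, float, float]:
    return (psnr(test, ref, peak=peak), nmse(test, ref), ssim_slicewise(test, ref, plane))


def paired_compare(values_a, values_b) -> dict:
    """Paired-difference summary between two methods' per-volume metrics.

    ``values_a/b`` are equal-length sequences of a scalar metric (one entry
    per volume).  Returns per-volume differences, their mean, and the paired
    t statistic with its two-sided p-value.  When the differences have zero
    variance the t statistic is reported as a signed infinity sentinel
    (0 for an identically-zero difference) with p = nan.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired comparison needs two equal-length 1D sequences")
    diffs = a - b
    mean_diff = float(diffs.mean())
    if len(diffs) < 2 or float(diffs.std(ddof=1)) == 0.0:
        t = 0.0 if mean_diff == 0.0 else float(np.sign(mean_diff) * np.inf)
        p = float("nan")
    else:
        res = stats.ttest_rel(a, b)
        t, p = float(res.statistic), float(res.pvalue)
    return {
        "per_volume_diff": diffs.tolist(),
        "mean_diff": mean_diff,
        "t_statistic": t,
        "p_value": p,
        "n": int(len(diffs)),
    }
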