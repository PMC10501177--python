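"""Apply 1D slice-profile kernels along one axis of gridded data.

All profile-weighted sums in the acquisition model share the same boundary
convention: the kernel window is clipped at the grid edge and the remaining
weights are renormalized, so a constant signal is reproduced exactly.  A
``reflect`` boundary is also provided for the deconvolution stage.

The operators are materialized as small (rows x n) matrices so that the
deconvolution can use the exact transpose of the forward blur.
"""

from __future__ import annotations

import numpy as np

__all__ = ["blur_matrix", "sampling_matrix", "apply_matrix_along_axis"]


def _place_row(row: np.ndarray, center: int, weights: np.ndarray, boundary: str) -> None:
    n = row.size
    hw = weights.size // 2
    for j, w in enumerate(weights):
        idx = center + j - hw
        if 0 <= idx < n:
            row[idx] += w
        elif boundary == "reflect":
            # half-sample reflection: ... 1 0 | 0 1 ...
            if idx < 0:
                idx = -idx - 1
            else:
                idx = 2 * n - idx - 1
            if 0 <= idx < n:
                row[idx] += w


def blur_matrix(
    n: int,
    weights: np.ndarray,
    center_shift: int = 0,
    boundary: str = "renormalize",
    clamp_centers: bool = False,
) -> np.ndarray:
    """Sliding-window convolution matrix (n x n) for a normalized kernel.

    Row ``i`` holds the kernel centered at sample ``i + center_shift``.
    With ``boundary="renormalize"`` the clipped rows are rescaled to unit
    sum; with ``"reflect"`` out-of-range taps fold back into the grid (rows
    then sum to 1 whenever the full kernel does).  ``clamp_centers`` pins
    shifted centers to the grid edge (used for neighbor views whose nominal
    position falls outside the volume).
    """
    if boundary not in ("renormalize", "reflect"):
        raise ValueError(f"unknown boundary {boundary!r}")
    weights = np.asarray(weights, dtype=np.float64)
    if weights.size > n and boundary == "renormalize":
        raise ValueError(f"kernel support ({weights.size} samples) exceeds the axis extent ({n})")
    H = np.zeros((n, n))
    for i in range(n):
        center = i + center_shift
        if clamp_centers:
            center = min(max(center, 0), n - 1)
        _place_row(H[i], center, weights, boundary)
        if boundary == "renormalize":
            s = H[i].sum()
            if s <= 0:
                raise ValueError(f"kernel centered at sample {i + center_shift} misses the grid")
            H[i] /= s
    return H


def sampling_matrix(n: int, centers_idx: np.ndarray, weights_per_center) -> np.ndarray:
    """Matrix (len(centers) x n) of clipped+renormalized kernels at arbitrary
    integer sample positions; ``weights_per_center`` may be a single kernel
    or one kernel per center (for fractionally shifted placements)."""
    centers_idx = np.asarray(centers_idx, dtype=int)
    m = centers_idx.size
    H = np.zeros((m, n))
    for i, c in enumerate(centers_idx):
        w = weights_per_center[i] if isinstance(weights_per_center, (list, tuple)) else weights_per_center
        _place_row(H[i], int(c), np.asarray(w, dtype=np.float64), "renormalize")
        s = H[i].sum()
        if s <= 0:
            raise ValueError(f"slice center at sample {c} falls entirely outside the grid")
        H[i] /= s
    return H


def apply_matrix_along_axis(H: np.ndarray, data: np.ndarray, axis: int) -> np.ndarray:
    """Contract ``H`` (m x n) with ``data`` along ``axis`` (extent n)."""
    moved = np.moveaxis(data, axis, -1)
    out = moved @ H.T
    return np.moveaxis(out, -1, axis)
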