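"""Normalized 1D slice-selection profiles.

The through-plane sensitivity of a 2D-excited slice (its PSF) is modelled as
a normalized symmetric 1D kernel sampled on a fine grid, with FWHM equal to
the nominal slice thickness ``L``.  Three families are provided:

``truncated_sinc``
    ``sinc(x / a)`` scaled so its half-maximum width equals ``L``
    (``a = L / 1.20678``) and truncated to a finite support (default: the
    slice thickness itself, i.e. main lobe only, all weights >= 0).
``gaussian``
    ``sigma = L / (2 sqrt(2 ln 2))``.
``delta``
    a single unit sample; the idealized rectangular-thin slice.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy.optimize import brentq

__all__ = ["SliceProfile", "make_profile", "measure_fwhm", "shift_profile", "resample_profile"]

# half-max abscissa of np.sinc: sinc(t0) = 1/2
_SINC_HALF_MAX_T = brentq(lambda t: np.sinc(t) - 0.5, 0.4, 0.9, xtol=1e-14)
#: FWHM of np.sinc(x) in its own units (~1.20678)
SINC_FWHM = 2.0 * _SINC_HALF_MAX_T

FAMILIES = ("truncated_sinc", "gaussian", "delta")


@dataclasses.dataclass
class SliceProfile:
    """A sampled, normalized, symmetric slice-selection kernel."""

    family: str
    fwhm_mm: float
    grid_spacing_mm: float
    support_mm: float
    weights: np.ndarray
    center_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 1 or self.weights.size % 2 != 1:
            raise ValueError("weights must be an odd-length 1D vector")

    @property
    def positions_mm(self) -> np.ndarray:
        """Sample positions relative to the (unshifted) kernel center."""
        n = self.weights.size // 2
        return np.arange(-n, n + 1) * self.grid_spacing_mm

    @property
    def half_width_samples(self) -> int:
        return self.weights.size // 2

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["weights"] = self.weights.tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "SliceProfile":
        d = json.loads(text)
        d["weights"] = np.asarray(d["weights"], dtype=np.float64)
        return cls(**d)


def make_profile(
    family: str,
    fwhm_mm: float,
    grid_spacing_mm: float,
    support_mm: float | None = None,
) -> SliceProfile:
    """Construct a normalized slice profile on a fine grid.

    ``support_mm`` defaults to ``fwhm_mm`` for the truncated sinc (main lobe
    only) and to ``4 x fwhm_mm`` for the Gaussian (captures >= 99.99% of the
    mass).  The sampled kernel is renormalized to unit sum after truncation.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown profile family {family!r}")
    if family == "delta":
        return SliceProfile(
            family="delta",
            fwhm_mm=float(fwhm_mm),
            grid_spacing_mm=float(grid_spacing_mm),
            support_mm=float(grid_spacing_mm),
            weights=np.array([1.0]),
        )
    if fwhm_mm <= 0 or grid_spacing_mm <= 0:
        raise ValueError("fwhm and grid spacing must be positive")
    if support_mm is None:
        support_mm = fwhm_mm if family == "truncated_sinc" else 4.0 * fwhm_mm
    if support_mm < grid_spacing_mm:
        raise ValueError("support must cover at least one grid step")
    n = int(np.floor(support_mm / 2.0 / grid_spacing_mm + 1e-9))
    x = np.arange(-n, n + 1) * grid_spacing_mm
    if family == "truncated_sinc":
        a = fwhm_mm / SINC_FWHM
        w = np.sinc(x / a)
    else:  # gaussian
        sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        w = np.exp(-0.5 * (x / sigma) ** 2)
    w = w / w.sum()
    return SliceProfile(
        family=family,
        fwhm_mm=float(fwhm_mm),
        grid_spacing_mm=float(grid_spacing_mm),
        support_mm=float(support_mm),
        weights=w,
    )


def measure_fwhm(profile: SliceProfile) -> float:
    """Full width at half maximum, by linear interpolation of the crossings.

    Conventions for degenerate kernels: a single-sample (delta) profile
    reports one grid step; a kernel that never falls below half-max within
    its truncation window reports its support width.  Monotone or flat
    kernels (no unique central maximum) raise.
    """
    w = profile.weights
    if w.size == 1:
        return profile.grid_spacing_mm
    x = profile.positions_mm
    c = w.size // 2
    if w[c] < w.max():
        raise ValueError("profile maximum is not at the center (monotone kernel?)")
    if np.count_nonzero(w == w.max()) > 1:
        raise ValueError("flat profile: FWHM undefined")
    half = w[c] / 2.0

    def crossing(idx_range) -> float | None:
        prev = c
        for i in idx_range:
            if w[i] < half:
                # linear interpolation between samples prev (>= half) and i
                t = (half - w[i]) / (w[prev] - w[i])
                return x[i] + t * (x[prev] - x[i])
            prev = i
        return None

    left = crossing(range(c - 1, -1, -1))
    right = crossing(range(c + 1, w.size))
    if left is None or right is None:
        return profile.support_mm
    return float(right - left)


def shift_profile(profile: SliceProfile, offset_mm: float) -> SliceProfile:
    """Resample the kernel with its center displaced by ``offset_mm``.

    Uses linear interpolation of the sampled kernel on the same grid (the
    kernels are smooth, so linear resampling is stable for truncated
    supports), then renormalizes.  Sub-grid-step shifts realize non-integer
    slice-center placement; an offset of exactly one grid step is a pure
    index shift.
    """
    if offset_mm == 0.0:
        return dataclasses.replace(profile, weights=profile.weights.copy())
    if abs(offset_mm) > profile.support_mm / 2.0:
        raise ValueError(
            f"offset {offset_mm} mm pushes the kernel support outside its "
            f"representable window (+-{profile.support_mm / 2.0} mm)"
        )
    x = profile.positions_mm
    w = np.interp(x - offset_mm, x, profile.weights, left=0.0, right=0.0)
    s = w.sum()
    if s <= 0:
        raise ValueError("shifted kernel has no remaining mass")
    return dataclasses.replace(
        profile,
        weights=w / s,
        center_offset_mm=profile.center_offset_mm + offset_mm,
    )


def resample_profile(profile: SliceProfile, grid_spacing_mm: float) -> SliceProfile:
    """Regenerate an (unshifted) profile at a different grid spacing."""
    if profile.center_offset_mm != 0.0:
        raise ValueError("cannot resample a shifted profile; shift after resampling")
    if profile.grid_spacing_mm == grid_spacing_mm:
        return dataclasses.replace(profile, weights=profile.weights.copy())
    if profile.family == "delta":
        return make_profile("delta", profile.fwhm_mm, grid_spacing_mm)
    return make_profile(profile.family, profile.fwhm_mm, grid_spacing_mm, profile.support_mm)
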