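"""The slice-acquisition forward model and low-resolution input synthesis.

A multi-slice 2D scan of an underlying isotropic volume ``V`` is modelled as
a profile-weighted projection: the value of slice ``s`` at each in-plane
position is the sum of ``V`` along the stacking axis weighted by the slice
profile centered at that slice's physical position (slice centers are spaced
``DS`` apart, the profile FWHM is the slice thickness ``L``).

Three LR-synthesis / pre-processing transforms are built on this model:

``sp_downsample``
    slice-profile downsampling of a high-resolution coronal stack along SI;
    produces the physically realistic LR half of an LR-HR training pair.
``kszf_downsample``
    the conventional k-space zero-fill baseline: 1D FFT along SI, centered
    crop of the spectrum, inverse FFT.
``sp_convolve``
    sliding-window slice-profile convolution along AP that gives reformatted
    orthogonal (axial) data the same through-plane blur as the coronal
    training slices, keeping the matrix size.

Non-integer slice centers are realized by fractionally shifting the kernel
on the fine grid rather than rounding to voxels; all windows are clipped and
renormalized at the grid boundary.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import IN_PLANE_AXES, STACK_AXIS, SliceStack, VolumeGrid
from .kernelops import apply_matrix_along_axis, blur_matrix, sampling_matrix
from .profiles import SliceProfile, resample_profile, shift_profile

__all__ = [
    "AcquisitionProtocol",
    "TrainingPair",
    "acquire_slices",
    "sp_downsample",
    "kszf_downsample",
    "sp_convolve",
    "make_training_pairs",
]


@dataclasses.dataclass
class AcquisitionProtocol:
    """Geometry of one multi-slice 2D acquisition."""

    orientation: str
    profile: SliceProfile
    slice_spacing_mm: float
    n_slices: int
    first_slice_center_mm: float | None = None  # None: stack centered in the FOV
    in_plane_spacing_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.orientation not in STACK_AXIS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.slice_spacing_mm <= 0 or self.n_slices < 1:
            raise ValueError("slice spacing must be positive and n_slices >= 1")

    @property
    def slice_thickness_mm(self) -> float:
        """Nominal thickness = FWHM of the slice profile."""
        return self.profile.fwhm_mm

    def slice_centers_mm(self, fov_mm: float) -> np.ndarray:
        """Physical slice-center positions within a FOV of the stacking axis."""
        if self.first_slice_center_mm is None:
            first = (fov_mm - (self.n_slices - 1) * self.slice_spacing_mm) / 2.0
        else:
            first = self.first_slice_center_mm
        return first + np.arange(self.n_slices) * self.slice_spacing_mm


@dataclasses.dataclass
class TrainingPair:
    """Three consecutive LR slices plus the HR center target slice.

    ``lr_triplet`` has shape (3, N_LR, NS_SI) and ``hr_target`` shape
    (1, N_LR, N_SI): the network's channel-stacked input and its target.
    """

    lr_triplet: np.ndarray
    hr_target: np.ndarray
    subject_id: int = 0
    center_slice: int = 0

    def __post_init__(self) -> None:
        if self.lr_triplet.shape[0] != 3 or self.hr_target.shape[0] != 1:
            raise ValueError("expected 3 LR channels and 1 HR channel")
        if self.lr_triplet.shape[1] != self.hr_target.shape[1]:
            raise ValueError("LR and HR slices disagree along the in-plane LR axis")


# ---------------------------------------------------------------------------
# profile placement on a data grid
# ---------------------------------------------------------------------------

def _kernels_at_centers(
    profile: SliceProfile, centers_mm: np.ndarray, grid_mm: float
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Integer anchor index and fractionally shifted kernel per slice center.

    The kernel lives on the data grid (voxel centers at ``(i+0.5)*grid``);
    sub-sample placement is handled by shifting the kernel, not the data.
    """
    prof = resample_profile(profile, grid_mm)
    idx_cont = centers_mm / grid_mm - 0.5
    anchors = np.round(idx_cont).astype(int)
    kernels = []
    for ic, k0 in zip(idx_cont, anchors):
        frac_mm = (ic - k0) * grid_mm
        kernels.append(shift_profile(prof, frac_mm).weights if frac_mm != 0.0 else prof.weights)
    return anchors, kernels


def acquire_slices(volume: VolumeGrid, protocol: AcquisitionProtocol) -> SliceStack:
    """Simulate a multi-slice 2D acquisition of an isotropic volume.

    Each slice is the profile-weighted sum of the volume along the stacking
    axis, centered at the slice's physical position; boundary-clipped
    windows are renormalized, so a constant volume yields constant slices.
    """
    axis = STACK_AXIS[protocol.orientation]
    grid = volume.spacing_mm[axis]
    fov = volume.fov_mm[axis]
    if (protocol.n_slices - 1) * protocol.slice_spacing_mm >= fov:
        raise ValueError(
            f"{protocol.n_slices} slices at {protocol.slice_spacing_mm} mm spacing "
            f"do not fit the {fov} mm FOV along axis {axis}"
        )
    centers = protocol.slice_centers_mm(fov)
    if np.all(centers < 0) or np.all(centers > fov):
        raise ValueError("slice centers fall entirely outside the volume")
    anchors, kernels = _kernels_at_centers(protocol.profile, centers, grid)
    H = sampling_matrix(volume.shape[axis], anchors, kernels)
    data = apply_matrix_along_axis(H, volume.data, axis)
    r, c = IN_PLANE_AXES[protocol.orientation]
    spacing = list(volume.spacing_mm)
    return SliceStack(
        data=data,
        orientation=protocol.orientation,
        in_plane_spacing_mm=(spacing[r], spacing[c]),
        slice_thickness_mm=protocol.slice_thickness_mm,
        slice_spacing_mm=protocol.slice_spacing_mm,
        si_offset_vox=volume.si_offset_vox,
        first_slice_center_mm=float(centers[0]),
    )


def sp_downsample(
    hr_stack: SliceStack,
    profile_si: SliceProfile,
    spacing_si_mm: float,
    n_out: int,
    first_center_mm: float | None = None,
) -> SliceStack:
    """Slice-profile downsampling of a coronal stack along SI.

    Each output SI row is the PSF-weighted combination of the HR SI rows at
    the physical slice-center locations, reproducing how an orthogonal
    (axial) scan would have sampled the same anatomy.  The result pairs with
    ``hr_stack`` as the LR-HR training input.
    """
    if hr_stack.orientation != "coronal":
        raise ValueError("sp_downsample expects a coronal (SI-fine) stack")
    grid = hr_stack.spacing_mm[2]
    fov = hr_stack.data.shape[2] * grid
    if (n_out - 1) * spacing_si_mm >= fov:
        raise ValueError(
            f"{n_out} output rows at {spacing_si_mm} mm spacing exceed the {fov} mm SI coverage"
        )
    if first_center_mm is None:
        first_center_mm = (fov - (n_out - 1) * spacing_si_mm) / 2.0
    centers = first_center_mm + np.arange(n_out) * spacing_si_mm
    anchors, kernels = _kernels_at_centers(profile_si, centers, grid)
    H = sampling_matrix(hr_stack.data.shape[2], anchors, kernels)
    data = apply_matrix_along_axis(H, hr_stack.data, 2)
    # SI sampling of the output is the slice spacing of the simulated scan
    return SliceStack(
        data=data,
        orientation="coronal",
        in_plane_spacing_mm=(spacing_si_mm, hr_stack.in_plane_spacing_mm[1]),
        slice_thickness_mm=hr_stack.slice_thickness_mm,
        slice_spacing_mm=hr_stack.slice_spacing_mm,
        si_offset_vox=hr_stack.si_offset_vox,
        first_slice_center_mm=hr_stack.first_slice_center_mm,
    )


def kszf_downsample(hr_stack: SliceStack, factor: float) -> SliceStack:
    """K-space zero-fill downsampling along SI (the conventional baseline).

    1D FFT along SI, retain the ``round(N / factor)`` centered frequencies
    (indices ``[-floor(k/2), ceil(k/2))`` around DC), inverse FFT, keep the
    real part.  Amplitudes are rescaled by ``k/N`` so the DC level (mean
    intensity) is preserved.
    """
    if factor < 1:
        raise ValueError("downsampling factor must be >= 1")
    n = hr_stack.data.shape[2]
    k = int(np.round(n / factor))
    if k < 1:
        raise ValueError("factor leaves no retained frequencies")
    spec = np.fft.fft(hr_stack.data, axis=2)
    spec = np.fft.fftshift(spec, axes=2)
    center = n // 2
    lo = center - k // 2
    cropped = spec[:, :, lo : lo + k]
    cropped = np.fft.ifftshift(cropped, axes=2)
    out = np.fft.ifft(cropped, axis=2) * (k / n)
    data = np.real(out)
    new_spacing_si = (n * hr_stack.spacing_mm[2]) / k  # FOV preserved
    return SliceStack(
        data=data,
        orientation="coronal",
        in_plane_spacing_mm=(new_spacing_si, hr_stack.in_plane_spacing_mm[1]),
        slice_thickness_mm=hr_stack.slice_thickness_mm,
        slice_spacing_mm=hr_stack.slice_spacing_mm,
        si_offset_vox=hr_stack.si_offset_vox,
        first_slice_center_mm=hr_stack.first_slice_center_mm,
    )


def sp_convolve(
    stack: SliceStack, profile_ap: SliceProfile, offset_mm: float = 0.0
) -> SliceStack:
    """Sliding-window slice-profile convolution along AP, keeping matrix size.

    Applied to orthogonal (axial) data reformatted to coronal orientation so
    the inference input carries the same AP slice-thickness blur as the
    coronal training slices.  ``offset_mm`` displaces the kernel center, used
    to form the neighbor views of the 3-slice inference input at the
    physical distance of the coronal slice spacing; sub-voxel offsets are
    realized by fractional kernel shifts.
    """
    grid = stack.spacing_mm[1]
    n_ap = stack.data.shape[1]
    prof = resample_profile(profile_ap, grid)
    if prof.weights.size > n_ap:
        raise ValueError("profile support exceeds the AP extent")
    idx = offset_mm / grid
    k0 = int(np.round(idx))
    frac_mm = (idx - k0) * grid
    kern = shift_profile(prof, frac_mm).weights if frac_mm != 0.0 else prof.weights
    # neighbor views whose nominal center leaves the volume clamp to the edge
    H = blur_matrix(n_ap, kern, center_shift=k0, boundary="renormalize", clamp_centers=True)
    data = apply_matrix_along_axis(H, stack.data, 1)
    return stack.copy_with(data=data)


def make_training_pairs(hr_cor: SliceStack, lr_cor: SliceStack) -> list[TrainingPair]:
    """Assemble 3-slice LR inputs with their HR center targets.

    Consecutive coronal slices i-1, i, i+1 of the LR stack form the input
    channels and the HR slice i is the target; an NS-slice scan yields
    NS - 2 pairs.
    """
    if hr_cor.orientation != "coronal" or lr_cor.orientation != "coronal":
        raise ValueError("training pairs are assembled from coronal stacks")
    ns = hr_cor.data.shape[1]
    if lr_cor.data.shape[1] != ns:
        raise ValueError("LR and HR stacks must have equal slice counts along AP")
    if ns < 3:
        raise ValueError("need at least 3 slices to form a triplet")
    pairs = []
    for i in range(1, ns - 1):
        lr = np.stack([lr_cor.data[:, i - 1, :], lr_cor.data[:, i, :], lr_cor.data[:, i + 1, :]])
        hr = hr_cor.data[:, i, :][None]
        pairs.append(TrainingPair(lr_triplet=lr, hr_target=hr, center_slice=i))
    return pairs
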