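"""Volume and slice-stack containers with physical-coordinate bookkeeping.

All 3D data is held internally on a fixed canonical axis order
``(LR, AP, SI)`` (left-right, anterior-posterior, superior-inferior) with
0-based indices.  Voxel ``i`` along an axis with spacing ``s`` spans the
physical interval ``[i*s, (i+1)*s)`` and has its center at ``(i + 0.5) * s``.

A multi-slice 2D acquisition is represented by :class:`SliceStack`, which
keeps the same canonical array layout plus acquisition metadata (orientation,
slice thickness, slice spacing).  Reformatting between orientations is a pure
axis permutation and never resamples.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "SliceStack",
    "read_volume",
    "write_volume",
    "read_stack",
    "write_stack",
    "reformat",
    "crop_si",
    "regrid_isotropic",
    "STACK_AXIS",
    "IN_PLANE_AXES",
]

#: canonical axis index each orientation stacks along
STACK_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}

#: canonical axes forming the displayed in-plane (row, column) of one slice
IN_PLANE_AXES = {"coronal": (2, 0), "axial": (1, 0), "sagittal": (2, 1)}

AXIS_NAMES = ("LR", "AP", "SI")


def _validate_3d(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D array, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    return data


@dataclasses.dataclass
class VolumeGrid:
    """A 3D scalar field on a regular grid, indexed ``(LR, AP, SI)``.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units).
    spacing_mm:
        Physical voxel size per canonical axis, strictly positive.
    si_offset_vox:
        Index of this array's first SI voxel within the un-cropped parent
        grid; lets paired crops be taken at identical scanner locations.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    si_offset_vox: int = 0
    meta: dict = dataclasses.field(default_factory=dict)  # JSON-safe provenance

    def __post_init__(self) -> None:
        self.data = _validate_3d(self.data)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacings must be three positive numbers, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        """Field of view per axis, ``N_* x s_*``."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing_mm))

    def copy_with(self, data: np.ndarray | None = None, **kw) -> "VolumeGrid":
        fields = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        fields.pop("data")
        fields.update(kw)
        return VolumeGrid(data=self.data.copy() if data is None else data, **fields)


@dataclasses.dataclass
class SliceStack:
    """A multi-slice 2D acquisition stored on the canonical (LR, AP, SI) grid.

    ``data`` is indexed canonically; the acquisition view (in-plane row,
    in-plane column, slice index) is exposed by :attr:`slices`.  The sampling
    step along the stacking axis is the slice spacing ``DS`` (center-to-center
    distance), which may exceed the slice thickness ``L`` (FWHM of the slice
    profile), leaving a nominal gap ``DS - L``.
    """

    data: np.ndarray
    orientation: str
    in_plane_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    slice_spacing_mm: float
    si_offset_vox: int = 0
    first_slice_center_mm: float | None = None

    def __post_init__(self) -> None:
        self.data = _validate_3d(self.data)
        if self.orientation not in STACK_AXIS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        self.in_plane_spacing_mm = tuple(float(s) for s in self.in_plane_spacing_mm)
        if any(s <= 0 for s in self.in_plane_spacing_mm):
            raise ValueError("in-plane spacings must be positive")
        if self.slice_thickness_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("slice thickness and spacing must be positive")
        if self.n_slices < 1:
            raise ValueError("a stack needs at least one slice")
        if self.gap_mm < 0:
            warnings.warn(
                f"slice spacing {self.slice_spacing_mm} mm is smaller than the "
                f"slice thickness {self.slice_thickness_mm} mm: adjacent slices overlap",
                UserWarning,
                stacklevel=2,
            )

    # -- geometry ----------------------------------------------------------
    @property
    def stack_axis(self) -> int:
        return STACK_AXIS[self.orientation]

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.stack_axis]

    @property
    def gap_mm(self) -> float:
        """Nominal gap between adjacent slice boundaries (may be negative)."""
        return self.slice_spacing_mm - self.slice_thickness_mm

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        """Canonical per-axis sampling step (DS along the stacking axis)."""
        out = [0.0, 0.0, 0.0]
        out[self.stack_axis] = self.slice_spacing_mm
        for ax, s in zip(self._in_plane_canonical_axes(), self.in_plane_spacing_mm):
            out[ax] = s
        return tuple(out)

    def _in_plane_canonical_axes(self) -> tuple[int, int]:
        return IN_PLANE_AXES[self.orientation]

    @property
    def slices(self) -> np.ndarray:
        """View of the data as (in-plane row, in-plane column, slice index)."""
        r, c = self._in_plane_canonical_axes()
        return np.transpose(self.data, (r, c, self.stack_axis))

    @classmethod
    def from_slices(cls, slices: np.ndarray, orientation: str, **kw) -> "SliceStack":
        """Build a stack from acquisition-ordered slices."""
        if orientation not in STACK_AXIS:
            raise ValueError(f"unknown orientation {orientation!r}")
        r, c = IN_PLANE_AXES[orientation]
        perm = np.argsort((r, c, STACK_AXIS[orientation]))
        return cls(data=np.transpose(np.asarray(slices), perm), orientation=orientation, **kw)

    def as_volume(self) -> VolumeGrid:
        """Reinterpret the stack samples as a (generally anisotropic) volume."""
        return VolumeGrid(self.data.copy(), self.spacing_mm, si_offset_vox=self.si_offset_vox)

    def copy_with(self, data: np.ndarray | None = None, **kw) -> "SliceStack":
        fields = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        fields.pop("data")
        fields.update(kw)
        return SliceStack(data=self.data.copy() if data is None else data, **fields)

    # -- metadata sidecar --------------------------------------------------
    def metadata(self) -> dict:
        return {
            "orientation": self.orientation,
            "in_plane_spacing_mm": list(self.in_plane_spacing_mm),
            "slice_thickness_mm": self.slice_thickness_mm,
            "slice_spacing_mm": self.slice_spacing_mm,
            "si_offset_vox": self.si_offset_vox,
            "first_slice_center_mm": self.first_slice_center_mm,
        }


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _canonical_affine(spacing_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def write_volume(volume: VolumeGrid, path) -> None:
    """Write a volume as NIfTI-1 with the spacing encoded in the affine."""
    img = nib.Nifti1Image(np.asarray(volume.data), _canonical_affine(volume.spacing_mm))
    img.header.set_data_dtype(volume.data.dtype)
    nib.save(img, str(path))


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI-1 volume and canonicalize its axes to (LR, AP, SI).

    The affine must be orthogonal (axis-aligned up to flips/permutations);
    oblique acquisitions are rejected because a pure permutation cannot
    canonicalize them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI, got {img.ndim}D")
    aff = img.affine
    R = aff[:3, :3]
    # orthogonality check: columns mutually perpendicular
    G = R.T @ R
    off = G - np.diag(np.diag(G))
    if np.max(np.abs(off)) > 1e-4 * max(np.max(np.abs(np.diag(G))), 1e-12):
        raise ValueError("non-orthogonal (oblique) affine: cannot canonicalize by permutation")
    zooms = np.sqrt(np.diag(G))
    if np.any(zooms <= 0) or not np.all(np.isfinite(zooms)):
        raise ValueError("affine encodes missing or non-positive voxel spacing")
    canonical = nib.as_closest_canonical(img)  # RAS+: (LR, PA->AP axis, IS->SI axis)
    data = np.asarray(canonical.dataobj)
    spacing = tuple(float(z) for z in canonical.header.get_zooms()[:3])
    return VolumeGrid(data=data, spacing_mm=spacing)


def write_stack(stack: SliceStack, path) -> None:
    """Write stack samples as NIfTI plus a JSON metadata sidecar."""
    path = Path(path)
    write_volume(stack.as_volume(), path)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
    sidecar = Path(str(sidecar) + ".json")
    sidecar.write_text(json.dumps(stack.metadata(), indent=2))


def read_stack(path) -> SliceStack:
    path = Path(path)
    vol = read_volume(path)
    sidecar = path.with_suffix("").with_suffix("")
    sidecar = Path(str(sidecar) + ".json")
    meta = json.loads(sidecar.read_text())
    return SliceStack(
        data=vol.data,
        orientation=meta["orientation"],
        in_plane_spacing_mm=tuple(meta["in_plane_spacing_mm"]),
        slice_thickness_mm=meta["slice_thickness_mm"],
        slice_spacing_mm=meta["slice_spacing_mm"],
        si_offset_vox=meta.get("si_offset_vox", 0),
        first_slice_center_mm=meta.get("first_slice_center_mm"),
    )


# ---------------------------------------------------------------------------
# Reformatting, cropping, regridding
# ---------------------------------------------------------------------------

def _canonical_data_and_spacing(obj) -> tuple[np.ndarray, tuple[float, float, float], int]:
    if isinstance(obj, SliceStack):
        return obj.data, obj.spacing_mm, obj.si_offset_vox
    if isinstance(obj, VolumeGrid):
        return obj.data, obj.spacing_mm, obj.si_offset_vox
    raise TypeError(f"expected VolumeGrid or SliceStack, got {type(obj).__name__}")


def reformat(obj, target_orientation: str) -> SliceStack:
    """Re-slice a volume or stack into another orientation.

    This is multi-planar reformation by pure axis permutation: per-voxel
    values are unchanged and no resampling occurs.  The output slice count
    equals the input extent along the new stacking axis, and the reformatted
    "slice thickness" is the source sampling step along that axis (e.g. an
    axial scan reformatted to coronal has thin 0.625 mm effective slices
    along AP).
    """
    if target_orientation not in STACK_AXIS:
        raise ValueError(f"unknown orientation {target_orientation!r}")
    data, spacing, si_off = _canonical_data_and_spacing(obj)
    axis = STACK_AXIS[target_orientation]
    r, c = IN_PLANE_AXES[target_orientation]
    return SliceStack(
        data=data.copy(),
        orientation=target_orientation,
        in_plane_spacing_mm=(spacing[r], spacing[c]),
        slice_thickness_mm=spacing[axis],
        slice_spacing_mm=spacing[axis],
        si_offset_vox=si_off,
    )


def crop_si(obj, n_keep: int, anchor="center"):
    """Crop along the SI axis to ``n_keep`` samples.

    ``anchor`` is either ``"center"`` or an integer start offset.  The crop
    offset is accumulated into ``si_offset_vox`` so paired stacks can be
    cropped at identical scanner locations.
    """
    data, spacing, si_off = _canonical_data_and_spacing(obj)
    n = data.shape[2]
    if n_keep > n:
        raise ValueError(f"cannot keep {n_keep} SI samples from an extent of {n}")
    if n_keep < 1:
        raise ValueError("n_keep must be at least 1")
    if anchor == "center":
        start = (n - n_keep) // 2
    else:
        start = int(anchor)
        if start < 0 or start + n_keep > n:
            raise ValueError(f"crop window [{start}, {start + n_keep}) outside extent {n}")
    cropped = data[:, :, start : start + n_keep].copy()
    return obj.copy_with(data=cropped, si_offset_vox=si_off + start)


def si_coverage_mm(obj) -> float:
    """Physical SI coverage of a volume or stack (extent x sampling step)."""
    data, spacing, _ = _canonical_data_and_spacing(obj)
    return data.shape[2] * spacing[2]


def regrid_isotropic(volume: VolumeGrid, target_spacing_mm: float) -> VolumeGrid:
    """Trilinearly resample a volume onto an isotropic grid.

    The output extent per axis is ``round(F_axis / target)``.  Sampling uses
    the voxel-center convention; coordinates outside the input are clamped to
    the edge voxel, so output values stay within the input's [min, max].
    """
    from scipy.ndimage import map_coordinates

    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    if any(n < 2 for n in volume.shape):
        raise ValueError("cannot regrid a degenerate (single-voxel) axis")
    new_shape = tuple(int(np.round(f / target_spacing_mm)) for f in volume.fov_mm)
    if any(n < 1 for n in new_shape):
        raise ValueError("target spacing larger than the field of view")
    coords = np.meshgrid(
        *[
            ((np.arange(n) + 0.5) * target_spacing_mm) / s - 0.5
            for n, s in zip(new_shape, volume.spacing_mm)
        ],
        indexing="ij",
    )
    out = map_coordinates(
        np.asarray(volume.data, dtype=np.float64), np.stack(coords), order=1, mode="nearest"
    )
    return VolumeGrid(out, (target_spacing_mm,) * 3, si_offset_vox=0)
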