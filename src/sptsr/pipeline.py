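"""End-to-end through-plane SR inference.

Given an orthogonal (axial) multi-slice 2D stack and a generator trained on
slice-profile-downsampled coronal pairs, the flow is:

1. reformat the axial stack to coronal orientation (pure permutation);
2. slice-profile-convolve along AP so the input carries the same
   through-plane blur as the coronal training slices; the two neighbor
   views of the 3-slice input are convolved at the physical distance of the
   coronal slice spacing from the center position;
3. slide over every AP position, run the generator on each 3-slice input,
   and stack the outputs into the through-plane SR volume ``SR_ax`` (still
   AP-blurred, but on an isotropic voxel grid);
4. Richardson-Lucy deconvolve ``SR_ax`` along AP with the same profile to
   obtain the isotropic result ``SR_ax_deconv``.

Inference runs in the generator's normalized intensity space (including the
deconvolution) and is de-normalized with the checkpoint's stored scale at
the end.  The 2x2 ablation grid (training synthesis x input convolution)
and the linear-interpolation floor baseline are also provided here.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .deconvolution import DeconvConfig, rl_deconvolve
from .geometry import SliceStack, VolumeGrid, reformat
from .observation import sp_convolve
from .profiles import SliceProfile
from .training import Checkpoint

__all__ = [
    "PipelineConfig",
    "SRResult",
    "run_sptsr",
    "run_ablation_grid",
    "run_interpolation_baseline",
]


@dataclasses.dataclass
class PipelineConfig:
    """Inference-time geometry and processing options.

    ``neighbor_offset_mm`` is the physical distance of the two neighbor
    views from the center slice; it defaults to the coronal training slice
    spacing (``F_AP / NS_AP``) and is realized by fractional kernel shifts
    (``fractional_neighbors=False`` rounds to the nearest voxel instead).
    """

    neighbor_offset_mm: float | None = None
    use_sp_conv: bool = True
    fractional_neighbors: bool = True
    output_si_spacing_mm: float | None = None
    deconv: DeconvConfig = dataclasses.field(default_factory=DeconvConfig)
    batch_size: int = 16
    keep_stage_artifacts: bool = False


@dataclasses.dataclass
class SRResult:
    """Through-plane SR volume and its slice-profile-deconvolved counterpart."""

    through_plane_sr: VolumeGrid
    isotropic_sr: VolumeGrid
    provenance: dict
    stage_artifacts: dict | None = None

    def __post_init__(self) -> None:
        if self.through_plane_sr.shape != self.isotropic_sr.shape:
            raise ValueError("SR stages must share the matrix size")
        if self.through_plane_sr.spacing_mm != self.isotropic_sr.spacing_mm:
            raise ValueError("SR stages must share the grid spacing")


def _resolve_model(model):
    """Accept a Checkpoint, a generator, or any object with ``infer``."""
    if isinstance(model, Checkpoint):
        return model.build(), float(model.norm_scale), f"checkpoint(epoch={model.best_epoch})"
    scale = float(getattr(model, "norm_scale", 1.0))
    return model, scale, type(model).__name__


def _shifted_ap_view(data: np.ndarray, shift_vox: int) -> np.ndarray:
    """Edge-clamped integer shift along AP (axis 1)."""
    idx = np.clip(np.arange(data.shape[1]) + shift_vox, 0, data.shape[1] - 1)
    return data[:, idx, :]


def run_sptsr(
    axial_stack: SliceStack,
    model,
    psf_ap: SliceProfile,
    psf_si: SliceProfile,
    config: PipelineConfig | None = None,
) -> SRResult:
    """Full SPTSR inference on one axial stack; deterministic per checkpoint."""
    cfg = config or PipelineConfig()
    gen, norm_scale, model_id = _resolve_model(model)

    cor = reformat(axial_stack, "coronal")
    s_lr, s_ap, s_si = cor.spacing_mm  # s_si is the axial slice spacing DS_SI
    n_lr, n_ap, ns_si = cor.data.shape
    # default neighbor distance: the coronal training slice spacing; axial and
    # coronal protocols share sequence geometry, so the axial DS is its proxy
    offset = (
        cfg.neighbor_offset_mm
        if cfg.neighbor_offset_mm is not None
        else axial_stack.slice_spacing_mm
    )
    if cfg.use_sp_conv:
        views = []
        for off in (-offset, 0.0, offset):
            off_eff = off if cfg.fractional_neighbors else round(off / s_ap) * s_ap
            views.append(sp_convolve(cor, psf_ap, offset_mm=off_eff).data)
    else:
        shift = int(round(offset / s_ap))
        views = [
            _shifted_ap_view(cor.data, -shift),
            cor.data,
            _shifted_ap_view(cor.data, +shift),
        ]

    # slide the 3-view input over every AP position
    x = np.stack(views, axis=0)  # (3, N_LR, N_AP, NS_SI)
    batches = np.transpose(x, (2, 0, 1, 3)) / norm_scale  # (N_AP, 3, N_LR, NS_SI)
    outs = []
    for i in range(0, n_ap, cfg.batch_size):
        outs.append(gen.infer(batches[i : i + cfg.batch_size]))
    sr = np.concatenate(outs, axis=0)[:, 0]  # (N_AP, N_LR, N_SI)
    sr = np.transpose(sr, (1, 0, 2))  # canonical (LR, AP, SI)
    n_si = sr.shape[2]

    out_s_si = (
        cfg.output_si_spacing_mm
        if cfg.output_si_spacing_mm is not None
        else ns_si * s_si / n_si
    )
    spacing = (s_lr, s_ap, out_s_si)
    sr = np.maximum(sr, 0.0)  # magnitude images; RL needs non-negativity
    through = VolumeGrid(sr * norm_scale, spacing, si_offset_vox=cor.si_offset_vox)
    deconv = rl_deconvolve(
        VolumeGrid(sr, spacing, si_offset_vox=cor.si_offset_vox),
        psf_ap,
        axis=1,
        config=cfg.deconv,
    )
    iso = deconv.copy_with(data=deconv.data * norm_scale)

    artifacts = None
    if cfg.keep_stage_artifacts:
        artifacts = {"reformatted": cor, "convolved_views": views}
    return SRResult(
        through_plane_sr=through,
        isotropic_sr=iso,
        provenance={
            "model": model_id,
            "sp_conv": cfg.use_sp_conv,
            "neighbor_offset_mm": float(offset),
            "psf_ap": psf_ap.family,
            "psf_si": psf_si.family,
            "deconv_iterations": cfg.deconv.n_iterations,
        },
        stage_artifacts=artifacts,
    )


def run_ablation_grid(
    axial_stack: SliceStack,
    models: dict,
    psf_ap: SliceProfile,
    psf_si: SliceProfile,
    config: PipelineConfig | None = None,
) -> dict[str, SRResult]:
    """The 2x2 grid: {KS-ZF, SP-DS}-trained x {without, with} SP-conv.

    ``models`` maps ``"kszf_trained"`` and ``"spds_trained"`` to trained
    generators/checkpoints.  The ``"proposed"`` variant is the SP-DS-trained
    model with SP-convolved input.
    """
    cfg = config or PipelineConfig()
    grid = {}
    for label, model_key, use_conv in [
        ("kszf_no_spconv", "kszf_trained", False),
        ("spds_no_spconv", "spds_trained", False),
        ("kszf_spconv", "kszf_trained", True),
        ("proposed", "spds_trained", True),
    ]:
        variant_cfg = dataclasses.replace(cfg, use_sp_conv=use_conv)
        res = run_sptsr(axial_stack, models[model_key], psf_ap, psf_si, variant_cfg)
        res.provenance["trained_on"] = model_key
        grid[label] = res
    return grid


def run_interpolation_baseline(
    axial_stack: SliceStack, factor: float, align: str = "fov"
) -> VolumeGrid:
    """Through-plane linear interpolation to the SR grid (the floor baseline).

    ``align="fov"`` (default) interpolates the slice-center samples onto the
    voxel centers of an FOV-preserving grid of ``round(factor x NS)`` rows;
    ``align="span"`` distributes the output rows end-to-end across the span
    of the slice centers (the midpoint of a two-slice stack then lands
    exactly between them).  Ends are edge-clamped.
    """
    cor = reformat(axial_stack, "coronal")
    s_lr, s_ap, ds_si = cor.spacing_mm
    ns = cor.data.shape[2]
    n_out = int(round(factor * ns))
    centers = (np.arange(ns) + 0.5) * ds_si
    if align == "fov":
        fov = ns * ds_si
        out_s = fov / n_out
        targets = (np.arange(n_out) + 0.5) * out_s
    elif align == "span":
        targets = np.linspace(centers[0], centers[-1], n_out)
        out_s = ds_si * ns / n_out
    else:
        raise ValueError(f"unknown alignment {align!r}")
    lo = np.clip(np.searchsorted(centers, targets) - 1, 0, ns - 2)
    t = np.clip((targets - centers[lo]) / ds_si, 0.0, 1.0)
    data = cor.data[:, :, lo] * (1 - t) + cor.data[:, :, lo + 1] * t
    return VolumeGrid(data, (s_lr, s_ap, out_s), si_offset_vox=cor.si_offset_vox)
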