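# Methods

`sptsr` implements slice-profile transformation super-resolution (SPTSR):
through-plane super-resolution of multi-slice 2D MRI in which the
slice-selection profile is modelled explicitly at three points of the
pipeline — synthesis of the low-resolution (LR) training input
(SP-downsampling), pre-processing of the orthogonal inference input
(SP-convolution), and post-processing of the network output to an isotropic
volume (SP-deconvolution).

## Coordinate and sampling conventions

All 3D data uses a fixed canonical axis order (LR, AP, SI) with 0-based
indices. Voxel `i` along an axis of spacing `s` spans `[i*s, (i+1)*s)` with
its center at `(i + 0.5) * s`. Multi-planar reformation between axial,
coronal and sagittal orientations is a pure axis permutation; no operation
in the package resamples during reformatting.

A multi-slice 2D acquisition is parameterized by slice thickness `L` (the
FWHM of the slice profile), slice spacing `DS` (center-to-center), and the
slice count `NS`. Unless a first-slice position is given, stacks are
centered in the field of view: the first slice center sits at
`(F - (NS-1)*DS) / 2`. We require the slice-center span `(NS-1)*DS` to fit
strictly inside the FOV (the clinical 20-slice/3.6 mm protocol spans
68.4 mm inside its 68.75 mm cropped coverage).

## Slice profiles

The through-plane PSF is a normalized symmetric 1D kernel with FWHM equal
to the nominal slice thickness. Three families:

- **truncated sinc** (default): `sinc(x/a)` with `a = L / 1.20678` so the
  half-maximum width equals `L`, truncated by default to a support of `L`
  (main lobe only, all weights non-negative) and renormalized. The paper
  trail for TSE slice excitation suggests profile mis-specification is
  benign, so the support is configurable rather than fixed.
- **gaussian**: `sigma = L / (2 sqrt(2 ln 2))`, default support `4L`.
- **delta**: a single unit sample (the idealized slice; useful as an
  identity element in tests).

Profiles live on a fine grid equal to the data grid they are applied to.
Non-integer slice-center placement is realized by resampling the kernel
with a sub-grid shift (linear interpolation, renormalized), never by
rounding centers to voxels. FWHM is measured by linear interpolation of
the half-maximum crossings; a delta reports one grid step and a kernel that
never falls below half-max within its truncation window reports its
support, by convention.

## Forward model and LR synthesis

Slice acquisition is a profile-weighted projection: the slice at center `c`
equals the sum over the stacking axis of the volume weighted by the kernel
centered at `c`. All profile-weighted sums share one boundary convention —
the window is clipped at the grid edge and remaining weights renormalized —
so constant signals are reproduced exactly everywhere (acquisition,
SP-downsampling, SP-convolution and the RL forward blur).

- **SP-downsampling** applies the SI-profile to the SI axis of a
  high-resolution coronal stack at the orthogonal protocol's slice centers,
  producing the LR half of an LR–HR training pair with the correct slice
  spacing (3.6 mm for the clinical protocol, i.e. a 0.6 mm gap over the
  3 mm thickness).
- **KS-ZF** (the conventional baseline) performs a 1D FFT along SI,
  retains the `round(N/factor)` centered frequencies with the even-length
  convention `[-floor(k/2), ceil(k/2))`, inverse-transforms, rescales by
  `k/N` (DC preserved) and takes the real part. For even `k` the unpaired
  Nyquist bin can leave a small imaginary residue; taking the real part is
  the standard convention and is what we do.
- **SP-convolution** is a sliding-window convolution along AP that keeps
  the matrix size; boundary windows are renormalized. The neighbor views of
  the 3-slice inference input are produced by shifting the kernel center by
  the physical coronal slice spacing (sub-voxel residues via fractional
  kernel shift; centers that leave the volume clamp to the edge).

## Networks

The generator follows the SRGAN residual-trunk lineage with three
modifications for anisotropic multi-slice data: 3 consecutive LR slices
enter as input channels; upsampling is 1D sub-pixel (pixel-shuffle) along
SI only, with non-integer factors realized rationally (5.5x = sub-pixel
x11 then average-pool /2; 4x = two x2 stages); and the default
configuration (48 channels, 8 residual blocks, 9x9 head/tail kernels)
lands at 597,553 trainable parameters, i.e. the ~0.5M scale. Activations
are LeakyReLU(0.2); initialization is seeded Kaiming fan-in.

Two further choices are this package's own: a **global interpolation
skip** — the trunk output is added to a linear upsampling of the center
slice, and the tail convolution is zero-initialized so optimization starts
exactly at the interpolation solution — which is what makes very short CPU
training budgets productive; and a fully convolutional layout, so a model
trained on small phantoms runs on larger ones.

The Wasserstein critic is a plain convolutional stack (no normalization
layers, no terminal squashing — structural requirements of WGAN-GP),
followed by global average pooling and a linear score head.

All network code runs on a small reverse-mode autodiff engine written on
numpy for this package (`sptsr.nn`). Every operation's vector-Jacobian
product is itself expressed in engine operations, so gradients are
twice-differentiable — required to train the critic through the gradient
penalty. Float64 is used throughout; convolutions lower to gather (im2col)
plus a single GEMM with cached index tables.

## Training

WGAN-GP: the critic minimizes
`mean(D(fake)) - mean(D(real)) + lambda * E[(||grad D(xhat)|| - 1)^2]`
with `lambda = 10` and `xhat` a per-sample uniform interpolate; the
generator minimizes
`w_adv * (-mean(D(G(x)))) + w_mse * MSE + w_perc * MSE(f(.))`
with weights `(1e-3, 1, 1e-6)`. The source notation "10e-3" etc. is read
as `1e-3`; the literal reading (1e-2, 1e-5) remains selectable in the
config. The perceptual feature extractor `f` is pluggable; the default
configuration sets `w_perc = 0` so no pretrained feature network is
required. Slices are normalized to [0, 1] by the training set's 99.5th
percentile (heavy-tailed magnitude intensities); the scale is stored in
the checkpoint and restored at inference. Adam is used throughout; the
checkpoint returned is the epoch with the lowest validation MSE. One
critic step per generator step is used at desk scale (five is standard at
full scale and is the config default).

## Inference and deconvolution

For each AP position of the coronal-reformatted orthogonal stack, the
three SP-convolved views (center, +-DS) form the network input; outputs
stack into the through-plane SR volume `SR_ax`, which is still blurred
along AP by the slice profile. Richardson–Lucy deconvolution along AP with
the same 1D kernel produces the isotropic result. RL is implemented as the
exact EM iteration `u <- u * H^T(d/(Hu)) / H^T(1)` with `H` the
materialized 1D blur matrix (boundary-renormalized by default, reflection
optional) and its true transpose, so constants are exact fixed points and
the Poisson likelihood is monotone in the noiseless case. The
"noise-robust" variant damps the multiplicative correction where the
residual `d - Hu` lies within a threshold relative to the data maximum
(`ratio -> 1 + m*(ratio-1)`, `m = min(1, ((d-Hu)/T)^2)`); threshold 0 is
plain RL. Default 20 iterations, chosen on blur-then-restore benchmarks
with 3 mm kernels. Inference (including deconvolution) runs in the
normalized intensity space and is de-normalized at the end.

## Synthetic phantoms

Phantoms emulate anatomies with fine through-plane structure: a smooth
textured background (bimodal tissue/background contrast) with randomly
oriented ellipsoids, thin plates (1–2 mm, below the 3 mm slice thickness)
and rods. Structure orientations are uniform on the sphere — oblique,
curved boundaries are what allow any super-resolver to beat linear
interpolation, exactly as anatomical boundaries do — and structure sizes
are absolute in millimeters so learned priors transfer across phantom
sizes. Edges carry a one-voxel linear ramp so sub-voxel widths are
well-defined on the grid. Noise is Rician (magnitude of a complex
Gaussian, sigma = 0.02 of the intensity range by default) or Gaussian for
analytic tests. What the phantoms do *not* model: sequence contrast
(TR/TE), coil profiles, inter-slice motion, and the long-range anatomical
regularity of real organs — so passing the simulation study demonstrates
the pipeline's correctness and the benefit of the slice-profile
transformations on generic structure, not clinical image quality.

## Simulation study (desk scale)

The study mirrors the 3D simulation protocol: 1 mm isotropic ground truth,
3 mm-FWHM truncated-sinc profile at 4 mm slice spacing (4x downsampling);
training pairs from coronal stacks of 40 synthetic subjects (48 cubed),
validation on 3, evaluation on 10 held-out 64-cubed phantoms through the
full pipeline. The generator at this scale uses 12 channels / 3 residual
blocks / 5x5 head and tail kernels, trained 14 epochs at lr 1e-3 with 0.9
per-epoch decay, batch 8. These problem sizes are the package's default
`StudyConfig` and complete in a few minutes on one CPU. Reported
quantities: mean volumetric PSNR/NMSE of the interpolation baseline, the
through-plane SR stage, the isotropic (deconvolved) stage, and the 2x2
synthesis-x-convolution ablation grid. The expected qualitative outcome is
the stage ordering isotropic >= through-plane >= interpolation and a large
margin of the proposed variant (SP-DS-trained + SP-conv) over the
KS-ZF-trained/no-SP-conv baseline; margins between adjacent stages are a
few tenths of a dB at this scale, against several dB for the ablation
grid.

The dataset-size ablation trains the same model on 1 vs 12 synthetic
subjects (32-cubed, 24 epochs) and inspects the validation-MSE curves: the
tiny set turns upward after its minimum (memorization of training noise),
the larger set keeps improving; the flag is "mean of the last quarter of
the curve exceeds 1.1x the curve minimum", majority over 3 seeds.

## Numerical choices and degenerate inputs

- Blur operators are materialized as small matrices; their exact
  transposes are used in RL (no adjoint mismatch).
- Magnitude images may contain zeros: RL floors inputs at `1e-12 * max`.
- KS-ZF with non-integer factors keeps `round(N/factor)` bins
  (110 / 5.5 = 20 exactly for the clinical crop).
- `regrid_isotropic` uses trilinear interpolation with edge clamping and
  `round(F/target)` output extents (169.98 mm -> 170 voxels at 1 mm by
  nearest-integer rounding).
- Identical seeds give bit-identical phantoms, initializations, training
  histories and inference outputs.

## Known limitations

- No inter-slice motion model; stacks are assumed perfectly registered.
- The acquisition model is noise-free; noise enters only through the
  phantom. Scanner noise correlations along the reconstruction chain are
  not modelled.
- The perceptual loss term requires an external feature network to be
  supplied; with none it reduces to an image-space MSE (or is disabled).
- Bloch-equation slice-profile computation is out of scope; the truncated
  sinc (or Gaussian) approximation stands in for the true excitation
  profile.
- At desk scale the stage-ordering margins are small; they sharpen with
  longer training and more synthetic subjects.
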