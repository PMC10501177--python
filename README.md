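# sptsr — slice-profile transformation super-resolution for multi-slice 2D MRI

Multi-slice 2D TSE/FSE MRI gives excellent in-plane resolution
(0.3–1 mm) but thick slices (3–6 mm), so reformatting a single stack into
another orientation shows staircase artifacts, and clinics compensate by
acquiring several orthogonal stacks. `sptsr` turns **one** multi-slice 2D
stack into an isotropic 3D volume by modelling the slice-selection profile
(the through-plane PSF) at every step:

1. **SP-downsampling** — the LR half of each training pair is synthesized
   from a high-resolution coronal stack `I_cor` by applying the normalized
   1D slice profile `PSF_SI` (FWHM = slice thickness `L`) at the orthogonal
   protocol's slice centers (spacing `DS_SI`), instead of the conventional
   k-space zero-fill (KS-ZF) crop. This reproduces the true sampling
   physics, including the slice gap `DS − L`.
2. **Adversarial SR training** — a residual generator takes three
   consecutive LR slices as channels and upsamples 1D along the
   through-plane axis (rationally, e.g. 5.5x = sub-pixel x11 then
   average-pool /2), trained under WGAN-GP (critic without batch norm or a
   terminal sigmoid) with loss
   `w_adv·(−D(G(x))) + w_mse·MSE + w_perc·MSE(f(·))`, weights
   `(1e-3, 1, 1e-6)`, and validation-MSE epoch selection.
3. **SP-convolution** — at inference the orthogonal (axial) stack is
   reformatted to coronal and convolved along AP with `PSF_AP` (sliding
   window, matrix size kept), so the input carries the same two-axis blur
   as the training slices; neighbor views are taken at the physical slice
   spacing.
4. **SP-deconvolution** — the generator output `SR_ax` is still
   profile-blurred along AP; noise-robust Richardson–Lucy deconvolution
   with the same 1D kernel yields the isotropic volume `SR_ax_deconv`.

Everything runs on synthetic phantoms with fine through-plane structure,
so the full pipeline is testable end-to-end with no data downloads. The
neural networks run on a small numpy autodiff engine included in the
package (`sptsr.nn`, with second-order gradients for the WGAN-GP penalty);
there is no GPU or deep-learning-framework dependency.

## Worked example

```python
import numpy as np
from sptsr import (make_profile, measure_fwhm, PhantomSpec, generate_phantom,
                   AcquisitionProtocol, acquire_slices, sp_downsample,
                   make_training_pairs)

psf = make_profile("truncated_sinc", fwhm_mm=3.0, grid_spacing_mm=0.625)
print("profile taps:", np.round(psf.weights, 4))
print("measured FWHM (mm):", round(measure_fwhm(psf), 3))

phantom = generate_phantom(PhantomSpec(size=(48, 48, 48), seed=7))
protocol = AcquisitionProtocol("coronal", make_profile("truncated_sinc", 3.0, 1.0),
                               slice_spacing_mm=4.0, n_slices=12)
stack = acquire_slices(phantom, protocol)
print("coronal stack:", stack.slices.shape, "gap:", stack.gap_mm, "mm")

lr = sp_downsample(stack, make_profile("truncated_sinc", 3.0, 1.0), 4.0, 12)
pairs = make_training_pairs(stack, lr)
print("training pairs:", len(pairs), "input", pairs[0].lr_triplet.shape,
      "target", pairs[0].hr_target.shape)
```

prints

```
profile taps: [0.1557 0.2212 0.246  0.2212 0.1557]
measured FWHM (mm): 3.0
coronal stack: (48, 48, 12) gap: 1.0 mm
training pairs: 10 input (3, 48, 12) target (1, 48, 48)
```

— the truncated-sinc slice profile sampled on the 0.625 mm grid sums to 1
with its half-maximum width at the 3 mm slice thickness; a 48 mm phantom
acquired at 4 mm spacing gives 12 slices (1 mm nominal gap) and 10
three-slice training samples, each pairing a `(3, 48, 12)` LR input with
its `(1, 48, 48)` HR center-slice target.

The full simulation experiment — train an SP-DS and a KS-ZF generator on
synthetic subjects, run the 2x2 ablation grid and the interpolation
baseline on held-out phantoms, and score volumetric PSNR/NMSE against the
ground truth — is one call (a few minutes on one CPU):

```python
from sptsr.study import run_simulation_study
study = run_simulation_study(seed=1)
for m in ("interpolation", "through_plane_sr", "isotropic_sr",
          "kszf_no_spconv", "proposed"):
    print(f"{m:20s} {study.mean_psnr(m):.2f} dB")
```

```
interpolation        25.76 dB
through_plane_sr     26.06 dB
isotropic_sr         26.24 dB
kszf_no_spconv       20.94 dB
proposed             26.24 dB
```

The stage ordering (isotropic ≥ through-plane ≥ interpolation) shows that
the SR network beats the linear baseline and that the final deconvolution
adds through-plane-consistent sharpness, while the ~5 dB gap to the
KS-ZF-trained/no-SP-conv variant is the value of modelling the slice
profile on both the training and inference sides.

## Command line

```sh
sptsr simulate --spec spec.yaml --out sim/          # phantom + stacks (NIfTI)
sptsr prepare  --n-phantoms 8 --out pairs.npz       # LR-HR 3-slice pairs
sptsr train    --pairs pairs.npz --out ck.npz       # WGAN-GP training
sptsr infer    --input sim/axial.nii.gz --checkpoint ck.npz --out sr/
sptsr evaluate --test sr/sr_isotropic.nii.gz --ref sim/ground_truth.nii.gz --out report.json
sptsr describe --factor 5.5                         # layer table + parameter count
```

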