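"""Forward acquisition model, LR synthesis transforms, training pairs."""

import numpy as np
import pytest

from sptsr.geometry import SliceStack, VolumeGrid, reformat
from sptsr.observation import (
    AcquisitionProtocol,
    acquire_slices,
    kszf_downsample,
    make_training_pairs,
    sp_convolve,
    sp_downsample,
)
from sptsr.profiles import make_profile, resample_profile, shift_profile


def brute_force_acquire(volume, profile, centers_mm, axis, grid_mm):
    """Independent loop-based profile-weighted summation oracle."""
    prof = resample_profile(profile, grid_mm)
    n = volume.shape[axis]
    out_shape = list(volume.shape)
    out_shape[axis] = len(centers_mm)
    out = np.zeros(out_shape)
    for s, c in enumerate(centers_mm):
        ic = c / grid_mm - 0.5
        k0 = int(np.round(ic))
        kern = shift_profile(prof, (ic - k0) * grid_mm).weights if ic != k0 else prof.weights
        hw = kern.size // 2
        acc = np.zeros([d for i, d in enumerate(volume.shape) if i != axis])
        wsum = 0.0
        for j, w in enumerate(kern):
            idx = k0 + j - hw
            if 0 <= idx < n:
                acc += w * np.take(volume, idx, axis=axis)
                wsum += w
        sl = [slice(None)] * 3
        sl[axis] = s
        out[tuple(sl)] = acc / wsum
    return out


def coronal_stack(data, in_plane=(1.0, 1.0), thickness=3.0, spacing=4.0):
    return SliceStack(data, "coronal", in_plane, thickness, spacing)


class TestAcquireSlices:
    def test_constant_volume_gives_constant_slices(self):
        v = VolumeGrid(np.full((8, 32, 8), 2.5), (1, 1, 1))
        prot = AcquisitionProtocol("coronal", make_profile("truncated_sinc", 3.0, 1.0), 4.0, 7)
        stack = acquire_slices(v, prot)
        np.testing.assert_allclose(stack.data, 2.5, atol=1e-9)

    def test_delta_profile_extracts_nearest_samples(self, rng):
        v = VolumeGrid(rng.normal(size=(4, 16, 4)) + 5.0, (1, 1, 1))
        prot = AcquisitionProtocol(
            "coronal", make_profile("delta", 1.0, 1.0), 2.0, 8, first_slice_center_mm=0.5
        )
        stack = acquire_slices(v, prot)
        np.testing.assert_allclose(stack.data, v.data[:, ::2, :], atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        v = VolumeGrid(rng.normal(size=(16, 16, 64)) + 3.0, (1, 1, 1))
        prof = make_profile("gaussian", 3.0, 1.0)
        prot = AcquisitionProtocol("axial", prof, 4.0, 12)
        stack = acquire_slices(v, prot)
        centers = prot.slice_centers_mm(64.0)
        expected = brute_force_acquire(v.data, prof, centers, 2, 1.0)
        np.testing.assert_allclose(stack.data, expected, atol=1e-9)

    def test_protocol_that_does_not_fit_rejected(self):
        v = VolumeGrid(np.zeros((4, 8, 4)), (1, 1, 1))
        prot = AcquisitionProtocol("coronal", make_profile("delta", 1.0, 1.0), 4.0, 5)
        with pytest.raises(ValueError):
            acquire_slices(v, prot)


class TestSpDownsample:
    def test_clinical_geometry_row_count(self):
        # 110 HR rows at 0.625 mm; 20 output rows at 3.6 mm spacing
        hr = coronal_stack(np.zeros((8, 4, 110), dtype=np.float32), (0.625, 0.625), 3.0, 3.6)
        psf = make_profile("truncated_sinc", 3.0, 0.625)
        lr = sp_downsample(hr, psf, 3.6, 20)
        assert lr.data.shape == (8, 4, 20)

    def test_delta_profile_at_grid_spacing_is_identity(self, rng):
        hr = coronal_stack(rng.normal(size=(4, 4, 12)) + 2.0, (1.0, 1.0))
        lr = sp_downsample(hr, make_profile("delta", 1.0, 1.0), 1.0, 12, first_center_mm=0.5)
        np.testing.assert_allclose(lr.data, hr.data, atol=1e-12)

    def test_consistent_with_acquire_slices(self, rng):
        """SP-downsampling a stack equals acquiring the stack reinterpreted
        as a volume with an axial protocol at the same slice centers."""
        hr = coronal_stack(rng.normal(size=(6, 5, 48)) + 2.0, (1.0, 1.0))
        psf = make_profile("gaussian", 3.0, 1.0)
        lr = sp_downsample(hr, psf, 4.0, 11)
        prot = AcquisitionProtocol("axial", psf, 4.0, 11)
        ref = acquire_slices(hr.as_volume(), prot)
        np.testing.assert_allclose(lr.data, ref.data, atol=1e-9)

    def test_mean_preserved_for_interior_windows(self, rng):
        hr = coronal_stack(np.full((4, 4, 64), 1.7), (1.0, 1.0))
        psf = make_profile("truncated_sinc", 3.0, 1.0)
        lr = sp_downsample(hr, psf, 4.0, 14)
        np.testing.assert_allclose(lr.data, 1.7, atol=1e-9)

    def test_excessive_output_rejected(self):
        hr = coronal_stack(np.zeros((4, 4, 16)))
        with pytest.raises(ValueError):
            sp_downsample(hr, make_profile("delta", 1.0, 1.0), 4.0, 6)


class TestKszfDownsample:
    def test_constant_image_preserved(self):
        hr = coronal_stack(np.full((4, 4, 40), 3.25))
        lr = kszf_downsample(hr, 4.0)
        assert lr.data.shape[2] == 10
        np.testing.assert_allclose(lr.data, 3.25, atol=1e-9)

    def test_out_of_band_sinusoid_killed(self):
        n = 64
        z = np.arange(n)
        sig = np.cos(2 * np.pi * 20 * z / n)  # frequency 20 > retained band 8
        hr = coronal_stack(np.broadcast_to(sig, (4, 4, n)).copy())
        lr = kszf_downsample(hr, 4.0)
        assert np.linalg.norm(lr.data) < 1e-9 * np.linalg.norm(hr.data)

    def test_in_band_frequencies_match_dft_oracle(self, rng):
        n = 40
        hr = coronal_stack(rng.normal(size=(3, 3, n)))
        k = 10
        lr = kszf_downsample(hr, 4.0)
        # brute-force DFT oracle: evaluate the centered-cropped Fourier series
        line = hr.data[1, 2]
        spec = np.fft.fftshift(np.fft.fft(line))
        lo = n // 2 - k // 2
        kept = spec[lo : lo + k]
        rec = np.real(np.fft.ifft(np.fft.ifftshift(kept))) * k / n
        np.testing.assert_allclose(lr.data[1, 2], rec, atol=1e-9)

    def test_clinical_factor(self):
        hr = coronal_stack(np.zeros((4, 4, 110), dtype=np.float32), (0.625, 0.625), 3.0, 3.6)
        lr = kszf_downsample(hr, 5.5)
        assert lr.data.shape[2] == 20

    def test_differs_from_sp_downsample_on_structured_input(self):
        # super-Nyquist SI structure distinguishes the two LR syntheses
        n = 64
        z = np.arange(n)
        sig = 2.0 + np.cos(2 * np.pi * 12 * z / n)
        hr = coronal_stack(np.broadcast_to(sig, (4, 4, n)).copy())
        psf = make_profile("truncated_sinc", 3.0, 1.0)
        a = sp_downsample(hr, psf, 4.0, 16, first_center_mm=0.5)
        b = kszf_downsample(hr, 4.0)
        assert np.linalg.norm(a.data - b.data) > 1e-3


class TestSpConvolve:
    def test_delta_profile_identity(self, rng):
        stack = coronal_stack(rng.normal(size=(4, 32, 4)), (1.0, 1.0), 1.0, 1.0)
        out = sp_convolve(stack, make_profile("delta", 1.0, 1.0))
        np.testing.assert_array_equal(out.data, stack.data)

    def test_matrix_size_preserved(self, rng):
        stack = coronal_stack(rng.normal(size=(8, 320, 8)), (0.625, 0.625), 0.625, 0.625)
        out = sp_convolve(stack, make_profile("truncated_sinc", 3.0, 0.625))
        assert out.data.shape == stack.data.shape

    def test_matches_loop_oracle(self, rng):
        stack = coronal_stack(rng.normal(size=(5, 24, 5)) + 2.0, (1.0, 1.0), 1.0, 1.0)
        psf = make_profile("gaussian", 3.0, 1.0)
        out = sp_convolve(stack, psf)
        kern = resample_profile(psf, 1.0).weights
        hw = kern.size // 2
        n = 24
        for y in (0, 3, 12, 23):
            acc = np.zeros((5, 5))
            wsum = 0.0
            for j, w in enumerate(kern):
                idx = y + j - hw
                if 0 <= idx < n:
                    acc += w * stack.data[:, idx, :]
                    wsum += w
            np.testing.assert_allclose(out.data[:, y, :], acc / wsum, atol=1e-9)

    def test_constant_preserved_with_offset(self):
        stack = coronal_stack(np.full((4, 32, 4), 1.3), (1.0, 1.0), 1.0, 1.0)
        psf = make_profile("gaussian", 3.0, 1.0)
        out = sp_convolve(stack, psf, offset_mm=3.6)
        np.testing.assert_allclose(out.data, 1.3, atol=1e-9)

    def test_support_exceeding_extent_rejected(self):
        stack = coronal_stack(np.zeros((4, 3, 4)), (1.0, 1.0), 1.0, 1.0)
        with pytest.raises(ValueError):
            sp_convolve(stack, make_profile("gaussian", 3.0, 1.0, support_mm=12.0))


class TestEffectiveBlurCommutation:
    def test_training_and_inference_paths_share_si_spectra(self, rng):
        """The SP-downsampled coronal path and the SP-convolved
        reformatted-axial path apply the same pair of 1D blurs, so their SI
        power spectra agree on a band-limited phantom."""
        from scipy.ndimage import gaussian_filter

        v = VolumeGrid(gaussian_filter(rng.normal(size=(16, 48, 48)), 2.0) + 2.0, (1, 1, 1))
        psf = make_profile("gaussian", 3.0, 1.0)
        ns = 11
        cor_prot = AcquisitionProtocol("coronal", psf, 4.0, ns)
        ax_prot = AcquisitionProtocol("axial", psf, 4.0, ns)
        # training path: acquire coronal (AP blur), then SP-downsample SI
        cor = acquire_slices(v, cor_prot)
        lr_cor = sp_downsample(cor, psf, 4.0, ns)
        # inference path: acquire axial (SI blur), reformat, SP-convolve AP
        ax_cor = reformat(acquire_slices(v, ax_prot), "coronal")
        ax_conv = sp_convolve(ax_cor, psf)
        # compare 1D power along SI at matched AP positions (slice centers)
        centers_vox = np.round(cor_prot.slice_centers_mm(48.0) - 0.5).astype(int)
        a = lr_cor.data[:, 1:-1, :]  # interior slices only
        b = ax_conv.data[:, centers_vox[1:-1], :]
        pa = np.abs(np.fft.rfft(a - a.mean(), axis=2)) ** 2
        pb = np.abs(np.fft.rfft(b - b.mean(), axis=2)) ** 2
        # compare total in-band power (both paths sample SI differently, so
        # compare the common low-frequency band)
        k = min(pa.shape[2], pb.shape[2])
        ra, rb = pa[..., :k].mean(), pb[..., :k].mean()
        assert abs(ra - rb) / rb < 0.05


class TestMakeTrainingPairs:
    @staticmethod
    def _pairs(ns):
        hr = coronal_stack(np.zeros((4, ns, 16)))
        lr = coronal_stack(np.zeros((4, ns, 4)))
        return make_training_pairs(hr, lr)

    def test_clinical_slice_count(self):
        assert len(self._pairs(20)) == 18

    def test_minimal_case(self):
        assert len(self._pairs(3)) == 1

    @pytest.mark.parametrize("ns", range(4, 31))
    def test_enumeration(self, ns):
        pairs = self._pairs(ns)
        assert len(pairs) == ns - 2
        assert [p.center_slice for p in pairs] == list(range(1, ns - 1))

    def test_triplet_adjacency_and_target(self, rng):
        hr = coronal_stack(rng.normal(size=(4, 6, 16)))
        lr = coronal_stack(rng.normal(size=(4, 6, 4)))
        pairs = make_training_pairs(hr, lr)
        p = pairs[2]  # center slice 3
        np.testing.assert_array_equal(p.lr_triplet[0], lr.data[:, 2, :])
        np.testing.assert_array_equal(p.lr_triplet[1], lr.data[:, 3, :])
        np.testing.assert_array_equal(p.lr_triplet[2], lr.data[:, 4, :])
        np.testing.assert_array_equal(p.hr_target[0], hr.data[:, 3, :])

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError):
            self._pairs(2)
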