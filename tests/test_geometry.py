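"""Containers, NIfTI round-trips, reformatting, cropping, regridding."""

import itertools

import nibabel as nib
import numpy as np
import pytest

from sptsr.geometry import (
    IN_PLANE_AXES,
    STACK_AXIS,
    SliceStack,
    VolumeGrid,
    crop_si,
    read_volume,
    reformat,
    regrid_isotropic,
    si_coverage_mm,
    write_volume,
)


class TestVolumeGrid:
    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(ValueError):
            VolumeGrid(np.zeros((4, 4, 4)), (1.0, 0.0, 1.0))

    def test_rejects_nonfinite_data(self):
        bad = np.zeros((3, 3, 3))
        bad[1, 1, 1] = np.nan
        with pytest.raises(ValueError):
            VolumeGrid(bad, (1, 1, 1))

    def test_fov(self):
        v = VolumeGrid(np.zeros((32, 16, 8)), (0.5, 1.0, 2.0))
        assert v.fov_mm == (16.0, 16.0, 16.0)


class TestSliceStackInvariants:
    def test_negative_gap_warns_but_constructs(self):
        with pytest.warns(UserWarning, match="overlap"):
            s = SliceStack(
                np.zeros((8, 5, 8)),
                orientation="coronal",
                in_plane_spacing_mm=(1, 1),
                slice_thickness_mm=3.0,
                slice_spacing_mm=2.0,
            )
        assert s.gap_mm == pytest.approx(-1.0)

    def test_nominal_gap_of_clinical_protocol(self):
        s = SliceStack(
            np.zeros((8, 20, 8)),
            orientation="coronal",
            in_plane_spacing_mm=(0.625, 0.625),
            slice_thickness_mm=3.0,
            slice_spacing_mm=3.6,
        )
        assert s.gap_mm == pytest.approx(0.6)
        assert s.n_slices == 20

    def test_slices_view_matches_orientation_convention(self, rng):
        data = rng.normal(size=(4, 5, 6))
        for orientation in STACK_AXIS:
            s = SliceStack(data, orientation, (1, 1), 1.0, 1.0)
            r, c = IN_PLANE_AXES[orientation]
            assert s.slices.shape == (
                data.shape[r],
                data.shape[c],
                data.shape[STACK_AXIS[orientation]],
            )
            np.testing.assert_array_equal(
                s.slices, np.transpose(data, (r, c, STACK_AXIS[orientation]))
            )

    def test_from_slices_round_trips(self, rng):
        data = rng.normal(size=(4, 5, 6))
        s = SliceStack(data, "axial", (1, 1), 1.0, 1.0)
        s2 = SliceStack.from_slices(s.slices, "axial", in_plane_spacing_mm=(1, 1),
                                    slice_thickness_mm=1.0, slice_spacing_mm=1.0)
        np.testing.assert_array_equal(s2.data, data)


class TestNiftiIO:
    def test_round_trip_is_bit_exact(self, rng, tmp_path):
        v = VolumeGrid(rng.normal(size=(6, 7, 8)), (0.5, 1.0, 1.5))
        path = tmp_path / "vol.nii.gz"
        write_volume(v, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.data, v.data)
        assert back.spacing_mm == pytest.approx(v.spacing_mm)

    def test_isotropic_metadata(self, rng, tmp_path):
        v = VolumeGrid(rng.normal(size=(32, 32, 32)), (1, 1, 1))
        path = tmp_path / "iso.nii"
        write_volume(v, path)
        back = read_volume(path)
        assert back.spacing_mm == (1.0, 1.0, 1.0)
        assert back.shape == (32, 32, 32)

    def test_permuted_axes_are_canonicalized(self, rng, tmp_path):
        # store the array in (SI, LR, AP) order with an affine that says so;
        # the reader must undo the permutation (oracle: explicit transpose)
        arr = rng.normal(size=(5, 6, 7))  # (SI, LR, AP)
        aff = np.zeros((4, 4))
        aff[2, 0] = 2.0  # file axis 0 -> physical S (SI), spacing 2
        aff[0, 1] = 1.0  # file axis 1 -> physical R (LR), spacing 1
        aff[1, 2] = 1.5  # file axis 2 -> physical A (AP), spacing 1.5
        aff[3, 3] = 1.0
        nib.save(nib.Nifti1Image(arr, aff), str(tmp_path / "perm.nii"))
        v = read_volume(tmp_path / "perm.nii")
        expected = np.transpose(arr, (1, 2, 0))  # -> (LR, AP, SI)
        np.testing.assert_allclose(v.data, expected)
        assert v.spacing_mm == pytest.approx((1.0, 1.5, 2.0))

    def test_oblique_affine_rejected(self, rng, tmp_path):
        aff = np.eye(4)
        aff[0, 1] = 0.3  # shear: columns not orthogonal
        nib.save(nib.Nifti1Image(rng.normal(size=(4, 4, 4)), aff), str(tmp_path / "obl.nii"))
        with pytest.raises(ValueError, match="orthogonal|oblique"):
            read_volume(tmp_path / "obl.nii")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii")


class TestReformat:
    def test_clinical_axial_to_coronal_geometry(self):
        # a 320x320 in-plane, 20-slice axial stack reformats to 320 coronal
        # slices of 20 x 320 each
        ax = SliceStack.from_slices(
            np.zeros((320, 320, 20), dtype=np.float32),
            "axial",
            in_plane_spacing_mm=(0.625, 0.625),
            slice_thickness_mm=3.0,
            slice_spacing_mm=3.6,
        )
        cor = reformat(ax, "coronal")
        assert cor.n_slices == 320
        assert cor.slices.shape[:2] == (20, 320)

    def test_identity_and_involution(self, rng):
        data = rng.normal(size=(4, 5, 6))
        ax = SliceStack(data, "axial", (1, 1), 1.0, 1.0)
        same = reformat(ax, "axial")
        np.testing.assert_array_equal(same.data, data)
        back = reformat(reformat(ax, "coronal"), "axial")
        np.testing.assert_array_equal(back.data, data)

    def test_orientation_group_closure(self):
        # values never move in canonical storage: any chain of reformats
        # leaves the canonical array bit-identical
        labelled = np.arange(3 * 4 * 5, dtype=float).reshape(3, 4, 5)
        v = VolumeGrid(labelled, (1, 1, 1))
        for chain in itertools.product(STACK_AXIS, repeat=3):
            obj = v
            for orientation in chain:
                obj = reformat(obj, orientation)
            np.testing.assert_array_equal(obj.data, labelled)

    def test_unknown_orientation(self):
        with pytest.raises(ValueError):
            reformat(VolumeGrid(np.zeros((3, 3, 3)), (1, 1, 1)), "oblique")


class TestCropSI:
    def test_clinical_crop_coverage(self):
        v = VolumeGrid(np.zeros((8, 8, 320), dtype=np.float32), (0.625, 0.625, 0.625))
        c = crop_si(v, 110)
        assert c.shape[2] == 110
        assert si_coverage_mm(c) == pytest.approx(68.75)

    def test_identity_when_keeping_everything(self, rng):
        v = VolumeGrid(rng.normal(size=(4, 4, 12)), (1, 1, 1))
        np.testing.assert_array_equal(crop_si(v, 12).data, v.data)

    def test_center_crop_matches_slicing_oracle(self):
        ramp = np.broadcast_to(np.arange(20.0), (3, 3, 20)).copy()
        v = VolumeGrid(ramp, (1, 1, 1))
        c = crop_si(v, 10, anchor="center")
        np.testing.assert_array_equal(c.data, ramp[:, :, 5:15])
        assert c.si_offset_vox == 5

    def test_crop_beyond_extent(self):
        with pytest.raises(ValueError):
            crop_si(VolumeGrid(np.zeros((3, 3, 5)), (1, 1, 1)), 6)

    def test_crop_commutes_with_reformat(self, rng):
        data = rng.normal(size=(5, 6, 9))
        v = VolumeGrid(data, (1, 1, 1))
        a = crop_si(reformat(v, "coronal"), 4)
        b = reformat(crop_si(v, 4), "coronal")
        np.testing.assert_array_equal(a.data, b.data)


class TestRegridIsotropic:
    def test_clinical_3d_matrix(self):
        v = VolumeGrid(np.zeros((256, 256, 60), dtype=np.float32), (0.664, 0.664, 1.5))
        out = regrid_isotropic(v, 1.0)
        assert out.shape == (170, 170, 90)
        assert out.spacing_mm == (1.0, 1.0, 1.0)

    def test_identity_at_own_spacing(self, rng):
        v = VolumeGrid(rng.normal(size=(8, 9, 10)), (1, 1, 1))
        out = regrid_isotropic(v, 1.0)
        np.testing.assert_allclose(out.data, v.data, atol=1e-12)

    def test_linear_ramp_matches_analytic_line(self):
        n = 24
        ramp = np.broadcast_to(np.arange(n, dtype=float), (4, 4, n)).copy()
        v = VolumeGrid(ramp, (1.0, 1.0, 1.0))
        out = regrid_isotropic(v, 0.5)
        # analytic value at output voxel centers (interior; edges clamp)
        centers = (np.arange(out.shape[2]) + 0.5) * 0.5
        expected = np.clip(centers - 0.5, 0, n - 1)
        np.testing.assert_allclose(out.data[2, 2], expected, atol=1e-9)

    def test_constant_mean_preserved_exactly(self):
        v = VolumeGrid(np.full((10, 10, 10), 3.7), (1.3, 1.3, 1.3))
        out = regrid_isotropic(v, 1.0)
        assert out.data.mean() == pytest.approx(3.7, abs=1e-12)

    def test_values_bounded_by_input(self, rng):
        v = VolumeGrid(rng.normal(size=(8, 8, 8)), (1.1, 1.1, 1.1))
        out = regrid_isotropic(v, 0.7)
        assert out.data.min() >= v.data.min() - 1e-12
        assert out.data.max() <= v.data.max() + 1e-12

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            regrid_isotropic(VolumeGrid(np.zeros((1, 8, 8)), (1, 1, 1)), 1.0)
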