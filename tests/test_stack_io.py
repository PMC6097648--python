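import numpy as np
import pytest
import tifffile

from gfquant.stack_io import (
    BinaryMask,
    ChannelSet,
    CongruenceError,
    SpecimenRecord,
    VoxelGeometry,
    VoxelStack,
    crop_roi,
    load_specimen,
    read_channel_set,
    read_manifest,
    read_mask,
    subtract_mask_region,
    write_channel_set,
    write_manifest,
    write_mask,
)


class TestVoxelGeometry:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dx": 0.0},
            {"dz": -1.0},
            {"ap_axis": 3},
            {"ap_axis": 2, "ml_axis": 2},
            {"medial_direction": 0},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VoxelGeometry(**kwargs)

    def test_axis_pitches_follow_semantics(self):
        g = VoxelGeometry(dx=0.22, dy=0.25, dz=1.0, ap_axis=0, ml_axis=2)
        assert g.axis_pitch(0) == 1.0
        assert g.axis_pitch(1) == 0.25
        assert g.axis_pitch(2) == 0.22
        assert g.voxel_volume == pytest.approx(0.22 * 0.25 * 1.0)
        assert g.slice_area_pitch == pytest.approx(0.22 * 0.25)


class TestChannelSetIO:
    def test_roundtrip_preserves_intensities_and_geometry(self, tmp_path, rng, stack_geometry):
        arrays = {
            "GF": rng.integers(0, 256, size=(4, 16, 16)),
            "Brp": rng.integers(0, 256, size=(4, 16, 16)),
        }
        cs = ChannelSet(
            {n: VoxelStack(a, stack_geometry, n) for n, a in arrays.items()}
        )
        paths = write_channel_set(cs, tmp_path)
        back = read_channel_set(paths, None, stack_geometry)
        for name in arrays:
            np.testing.assert_array_equal(
                back[name].intensities, cs[name].intensities
            )
        assert back.geometry.isclose(stack_geometry)

    def test_channel_shape_mismatch_names_both_shapes(self, stack_geometry):
        a = VoxelStack(np.zeros((4, 16, 16), dtype=np.uint8), stack_geometry)
        b = VoxelStack(np.zeros((5, 16, 16), dtype=np.uint8), stack_geometry)
        with pytest.raises(CongruenceError, match=r"\(4, 16, 16\).*\(5, 16, 16\)"):
            ChannelSet({"a": a, "b": b})

    def test_unknown_channel_lists_available(self, tmp_path, stack_geometry):
        arr = np.zeros((2, 8, 8), dtype=np.uint8)
        paths = {
            "Brp": tmp_path / "brp.tif",
            "GFP": tmp_path / "gfp.tif",
        }
        for p in paths.values():
            tifffile.imwrite(p, arr, photometric="minisblack")
        with pytest.raises(KeyError, match="Brp.*GFP"):
            read_channel_set(paths, ["ShB"], stack_geometry)

    def test_16bit_input_rescaled_with_warning(self, tmp_path, stack_geometry, caplog):
        arr = np.full((2, 4, 4), 65535, dtype=np.uint16)
        arr[0, 0, 0] = 0
        p = tmp_path / "deep.tif"
        tifffile.imwrite(p, arr, photometric="minisblack")
        with caplog.at_level("WARNING"):
            cs = read_channel_set({"GF": p}, None, stack_geometry)
        assert "rescaled" in caplog.text
        assert cs["GF"].intensities.max() == 255
        assert cs["GF"].intensities[0, 0, 0] == 0

    def test_multipage_file_with_channel_indices(self, tmp_path, rng, stack_geometry):
        arr = rng.integers(0, 256, size=(2, 3, 8, 8)).astype(np.uint8)
        p = tmp_path / "multi.tif"
        tifffile.imwrite(p, arr, photometric="minisblack")
        cs = read_channel_set(p, {"GF": 0, "Brp": 1}, stack_geometry)
        np.testing.assert_array_equal(cs["Brp"].intensities, arr[1])
        with pytest.raises(KeyError, match="available channel indices"):
            read_channel_set(p, {"ShB": 5}, stack_geometry)

    def test_nonbinary_mask_reads_true_with_warning(self, tmp_path, stack_geometry, caplog):
        arr = np.zeros((2, 4, 4), dtype=np.uint8)
        arr[1, 2, 2] = 7
        p = tmp_path / "mask.tif"
        tifffile.imwrite(p, arr, photometric="minisblack")
        with caplog.at_level("WARNING"):
            mask = read_mask(p, stack_geometry)
        assert "nonzero" in caplog.text
        assert mask.voxels[1, 2, 2] and mask.count() == 1


class TestRoiArithmetic:
    def _set(self, rng, geometry, shape=(3, 8, 8)):
        return ChannelSet(
            {
                n: VoxelStack(rng.integers(0, 256, size=shape), geometry, n)
                for n in ("GF", "Brp")
            }
        )

    def test_all_true_roi_is_identity(self, rng, cubic_geometry):
        cs = self._set(rng, cubic_geometry)
        roi = BinaryMask(np.ones(cs.shape, dtype=bool), cubic_geometry)
        out = crop_roi(cs, roi)
        for n in cs.names():
            np.testing.assert_array_equal(out[n].intensities, cs[n].intensities)

    def test_all_false_roi_annihilates(self, rng, cubic_geometry):
        cs = self._set(rng, cubic_geometry)
        roi = BinaryMask(np.zeros(cs.shape, dtype=bool), cubic_geometry)
        out = crop_roi(cs, roi)
        for n in cs.names():
            assert not out[n].intensities.any()

    def test_crop_keeps_only_roi_positions(self, rng, cubic_geometry):
        cs = self._set(rng, cubic_geometry)
        roi = BinaryMask(rng.random(cs.shape) < 0.3, cubic_geometry)
        out = crop_roi(cs, roi)
        for n in cs.names():
            nonzero = out[n].intensities > 0
            # brute-force positional check: every surviving voxel is in the ROI
            for z, y, x in zip(*np.nonzero(nonzero)):
                assert roi.voxels[z, y, x]

    def test_crop_and_subtract_are_complementary(self, rng, cubic_geometry):
        stack = VoxelStack(rng.integers(0, 256, size=(3, 8, 8)), cubic_geometry, "GF")
        region = BinaryMask(rng.random((3, 8, 8)) < 0.5, cubic_geometry)
        kept = crop_roi(ChannelSet({"GF": stack}), region)["GF"]
        removed = subtract_mask_region(stack, region)
        np.testing.assert_array_equal(
            kept.intensities.astype(int) + removed.intensities.astype(int),
            stack.intensities.astype(int),
        )

    def test_subtract_trivial_regions(self, rng, cubic_geometry):
        stack = VoxelStack(rng.integers(1, 256, size=(2, 6, 6)), cubic_geometry)
        none = BinaryMask(np.zeros((2, 6, 6), dtype=bool), cubic_geometry)
        everything = BinaryMask(np.ones((2, 6, 6), dtype=bool), cubic_geometry)
        np.testing.assert_array_equal(
            subtract_mask_region(stack, none).intensities, stack.intensities
        )
        assert not subtract_mask_region(stack, everything).intensities.any()

    def test_incongruent_mask_rejected(self, rng, cubic_geometry):
        stack = VoxelStack(rng.integers(0, 256, size=(3, 8, 8)), cubic_geometry)
        small = BinaryMask(np.ones((2, 8, 8), dtype=bool), cubic_geometry)
        with pytest.raises(CongruenceError):
            subtract_mask_region(stack, small)
        other_geom = VoxelGeometry(dx=0.5, dy=0.5, dz=0.5)
        wrong = BinaryMask(np.ones((3, 8, 8), dtype=bool), other_geom)
        with pytest.raises(CongruenceError):
            crop_roi(ChannelSet({"GF": stack}), wrong)


class TestManifest:
    def test_manifest_roundtrip_and_load(self, tmp_path, rng, stack_geometry):
        arr = rng.integers(0, 256, size=(3, 8, 8)).astype(np.uint8)
        spec_dir = tmp_path / "s1"
        stack_path = spec_dir / "GF.tif"
        spec_dir.mkdir()
        tifffile.imwrite(stack_path, arr, photometric="minisblack")
        mask_path = write_mask(
            BinaryMask(arr > 128, stack_geometry), spec_dir / "ROI.tif"
        )
        rec = SpecimenRecord(
            "s1", "con", stack_geometry, {"GF": stack_path}, {"ROI": mask_path}
        )
        manifest = write_manifest([rec], tmp_path / "manifest.csv")
        back = read_manifest(manifest)
        assert len(back) == 1 and back[0].group == "con"
        channels, masks = load_specimen(back[0])
        np.testing.assert_array_equal(channels["GF"].intensities, arr)
        np.testing.assert_array_equal(masks["ROI"].voxels, arr > 128)

    def test_duplicate_specimen_ids_rejected(self, tmp_path, stack_geometry):
        recs = [
            SpecimenRecord("s1", "con", stack_geometry, {}, {}),
            SpecimenRecord("s1", "en", stack_geometry, {}, {}),
        ]
        manifest = write_manifest(recs, tmp_path / "manifest.csv")
        with pytest.raises(ValueError, match="duplicate"):
            read_manifest(manifest)
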