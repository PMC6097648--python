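import numpy as np
import pytest

from gfquant.stack_io import BinaryMask, CongruenceError, VoxelGeometry
from gfquant.quantify import (
    colocalization,
    medial_offset_pixels,
    nb_coupling_area,
    overlap_volume,
    partition_medial,
    per_slice_area,
    surface_area_proxy,
)


class TestPerSliceArea:
    def test_empty_mask_all_zero(self, stack_geometry):
        profile = per_slice_area(BinaryMask(np.zeros((4, 6, 6), dtype=bool), stack_geometry))
        assert not profile.areas.any() and profile.total_volume == 0

    def test_known_count_times_pixel_area(self, stack_geometry):
        m = np.zeros((3, 8, 8), dtype=bool)
        m[1].flat[:10] = True
        profile = per_slice_area(BinaryMask(m, stack_geometry))
        assert profile.areas[1] == pytest.approx(10 * 0.22 * 0.22)  # 0.484
        assert profile.areas[0] == 0

    def test_matches_brute_count_and_volume_identity(self, random_mask):
        mask = random_mask(shape=(5, 9, 9), p=0.4)
        profile = per_slice_area(mask)
        g = mask.geometry
        for z in range(5):
            brute = sum(
                1 for y in range(9) for x in range(9) if mask.voxels[z, y, x]
            )
            assert profile.areas[z] == pytest.approx(brute * g.dx * g.dy)
        assert profile.total_volume == pytest.approx(profile.areas.sum() * g.dz)
        assert profile.total_volume == pytest.approx(mask.volume())


class TestOverlapVolume:
    def test_self_overlap_is_volume(self, random_mask):
        m = random_mask()
        assert overlap_volume(m, m) == pytest.approx(m.volume())

    def test_disjoint_masks_overlap_zero(self, cubic_geometry):
        a = np.zeros((2, 4, 4), dtype=bool)
        b = np.zeros((2, 4, 4), dtype=bool)
        a[0], b[1] = True, True
        assert overlap_volume(BinaryMask(a, cubic_geometry), BinaryMask(b, cubic_geometry)) == 0

    def test_matches_brute_conjunction_count(self, random_mask):
        a, b = random_mask(p=0.5), random_mask(p=0.5)
        brute = sum(
            1
            for z in range(3)
            for y in range(8)
            for x in range(8)
            if a.voxels[z, y, x] and b.voxels[z, y, x]
        )
        assert overlap_volume(a, b) == pytest.approx(brute * a.geometry.voxel_volume)

    def test_symmetric_and_bounded_by_operands(self, random_mask):
        a, b = random_mask(p=0.3), random_mask(p=0.7)
        v = overlap_volume(a, b)
        assert v == overlap_volume(b, a)
        assert v <= min(a.volume(), b.volume()) + 1e-12

    def test_incongruent_masks_rejected(self, cubic_geometry):
        a = BinaryMask(np.ones((2, 4, 4), dtype=bool), cubic_geometry)
        b = BinaryMask(np.ones((2, 4, 5), dtype=bool), cubic_geometry)
        with pytest.raises(CongruenceError):
            overlap_volume(a, b)


class TestSurfaceAreaProxy:
    def test_single_voxel_at_cubic_pitch(self, cubic_geometry):
        m = np.zeros((3, 5, 5), dtype=bool)
        m[1, 2, 2] = True
        # 0.22^3 / 0.22 = 0.0484
        assert surface_area_proxy(BinaryMask(m, cubic_geometry)) == pytest.approx(0.0484)

    def test_empty_mask_zero(self, cubic_geometry):
        assert surface_area_proxy(BinaryMask(np.zeros((2, 4, 4), dtype=bool), cubic_geometry)) == 0

    @pytest.mark.parametrize("a", range(3, 21, 4))
    @pytest.mark.parametrize("b", range(3, 21, 4))
    def test_rectangle_closed_form(self, cubic_geometry, a, b):
        # outline voxels of an a x b rectangle: ab - (a-2)(b-2)
        m = np.zeros((1, 24, 24), dtype=bool)
        m[0, 1 : 1 + a, 2 : 2 + b] = True
        outline_count = a * b - (a - 2) * (b - 2)
        expected = outline_count * 0.22**3 / 0.22
        assert surface_area_proxy(BinaryMask(m, cubic_geometry)) == pytest.approx(expected)

    def test_worked_example_5x4(self, cubic_geometry):
        m = np.zeros((1, 10, 10), dtype=bool)
        m[0, 2:7, 3:7] = True
        assert surface_area_proxy(BinaryMask(m, cubic_geometry)) == pytest.approx(0.6776)


class TestPartitionMedial:
    def test_boundary_pixel_conversion(self):
        assert medial_offset_pixels(5.0, 0.22) == 23

    def test_compact_dendrite_has_no_medial_part(self, stack_geometry):
        m = np.zeros((4, 20, 20), dtype=bool)
        m[:, 8:12, 8:12] = True  # all within 5 um of its own center
        medial, core = partition_medial(BinaryMask(m, stack_geometry), 5.0)
        assert medial.count() == 0
        assert core.count() == m.sum()

    def test_branch_beyond_boundary_is_medial(self, stack_geometry):
        # trunk around x=30 plus a branch reaching 10 um (45 px) medially
        m = np.zeros((6, 20, 100), dtype=bool)
        m[:, 8:12, 28:33] = True
        m[3, 10, 33:76] = True
        mask = BinaryMask(m, stack_geometry)
        medial, core = partition_medial(mask, 5.0)
        # independent brute-force: centroid and cut recomputed by loops
        xs = [x for z in range(6) for y in range(20) for x in range(100) if m[z, y, x]]
        center = sum(xs) / len(xs)
        cut = center + 23
        expected = {
            (z, y, x)
            for z in range(6)
            for y in range(20)
            for x in range(100)
            if m[z, y, x] and x > cut
        }
        got = set(zip(*np.nonzero(medial.voxels)))
        assert {(int(a), int(b), int(c)) for a, b, c in got} == expected
        assert medial.count() > 0

    def test_partition_is_disjoint_and_exhaustive(self, random_mask):
        mask = random_mask(shape=(4, 10, 10), p=0.3)
        if not mask.voxels.any():
            pytest.skip("empty draw")
        medial, core = partition_medial(mask, 1.0)
        assert not (medial.voxels & core.voxels).any()
        np.testing.assert_array_equal(medial.voxels | core.voxels, mask.voxels)

    def test_medial_direction_sign_respected(self, stack_geometry):
        m = np.zeros((2, 4, 60), dtype=bool)
        m[:, :, 25:35] = True
        m[0, 0, 0:2] = True  # lateral outlier (low x)
        flipped = VoxelGeometry(dx=0.22, dy=0.22, dz=1.0, medial_direction=-1)
        medial, _ = partition_medial(BinaryMask(m, flipped), 1.0)
        got = set(zip(*np.nonzero(medial.voxels)))
        assert all(x < 25 for _, _, x in got) and medial.count() == 2

    def test_empty_mask_rejected(self, stack_geometry):
        with pytest.raises(ValueError):
            partition_medial(BinaryMask(np.zeros((2, 4, 4), dtype=bool), stack_geometry))


class TestNbCouplingArea:
    def _gf(self, shape=(30, 24, 24), tip=8, geometry=None):
        m = np.zeros(shape, dtype=bool)
        m[tip:25, 10:14, 10:14] = True
        return BinaryMask(m, geometry or VoxelGeometry(dx=0.22, dy=0.22, dz=1.0))

    def test_empty_nb_mask_zero(self):
        gf = self._gf()
        nb = BinaryMask(np.zeros(gf.shape, dtype=bool), gf.geometry)
        assert nb_coupling_area(nb, gf) == 0

    def test_cylinder_cross_section_close_to_analytic(self):
        # NB cylinder of radius 2 um spanning the window: mean area ~ pi * 4
        geometry = VoxelGeometry(dx=0.22, dy=0.22, dz=1.0)
        shape = (30, 48, 48)
        gf = np.zeros(shape, dtype=bool)
        gf[8:25, 22:26, 22:26] = True
        nb = np.zeros(shape, dtype=bool)
        yy, xx = np.ogrid[:48, :48]
        disc = ((yy - 24) * 0.22) ** 2 + ((xx - 24) * 0.22) ** 2 <= 2.0**2
        nb[:] = disc[None, :, :]
        area = nb_coupling_area(BinaryMask(nb, geometry), BinaryMask(gf, geometry), 10.0)
        assert area == pytest.approx(np.pi * 4.0, rel=0.10)

    def test_invariant_to_signal_outside_window(self):
        gf = self._gf(tip=10)
        nb1 = np.zeros(gf.shape, dtype=bool)
        nb1[5:20, 2:6, 2:6] = True
        nb2 = nb1.copy()
        nb2[25:, :, :] = True  # far posterior of the window
        a1 = nb_coupling_area(BinaryMask(nb1, gf.geometry), gf, 10.0)
        a2 = nb_coupling_area(BinaryMask(nb2, gf.geometry), gf, 10.0)
        assert a1 == a2

    def test_window_truncated_at_stack_edge(self):
        gf = self._gf(tip=2)  # window [tip-5, tip+5) clipped to [0, 7)
        nb = np.zeros(gf.shape, dtype=bool)
        nb[0:7, 0, 0] = True
        nb[7:, 1, 1] = True  # outside the truncated window
        area = nb_coupling_area(BinaryMask(nb, gf.geometry), gf, 10.0)
        assert area == pytest.approx(0.22 * 0.22)  # one voxel per window slice

    def test_empty_dendrite_rejected(self):
        gf = BinaryMask(np.zeros((10, 8, 8), dtype=bool), VoxelGeometry())
        nb = BinaryMask(np.ones((10, 8, 8), dtype=bool), VoxelGeometry())
        with pytest.raises(ValueError):
            nb_coupling_area(nb, gf)


class TestColocalization:
    def test_identical_masks_fully_colocalized(self, random_mask):
        shb = random_mask(p=0.4)
        region = BinaryMask(np.ones(shb.shape, dtype=bool), shb.geometry)
        out = colocalization(shb, shb, {"JO-A": region})
        assert out["JO-A"].percent_colocalized == pytest.approx(100.0)

    def test_disjoint_masks_zero_percent(self, cubic_geometry):
        a = np.zeros((2, 4, 4), dtype=bool)
        b = np.zeros((2, 4, 4), dtype=bool)
        a[0], b[1] = True, True
        region = BinaryMask(np.ones((2, 4, 4), dtype=bool), cubic_geometry)
        out = colocalization(
            BinaryMask(a, cubic_geometry), BinaryMask(b, cubic_geometry), {"r": region}
        )
        assert out["r"].percent_colocalized == 0

    def test_matches_triple_conjunction_oracle(self, random_mask):
        shb, brp, region = random_mask(p=0.5), random_mask(p=0.5), random_mask(p=0.6)
        out = colocalization(shb, brp, {"r": region})["r"]
        voxvol = shb.geometry.voxel_volume
        shb_n = ov_n = 0
        for z in range(3):
            for y in range(8):
                for x in range(8):
                    if shb.voxels[z, y, x] and region.voxels[z, y, x]:
                        shb_n += 1
                        if brp.voxels[z, y, x]:
                            ov_n += 1
        assert out.shb_volume == pytest.approx(shb_n * voxvol)
        assert out.overlap_volume == pytest.approx(ov_n * voxvol)
        expected_pct = 100 * ov_n / shb_n if shb_n else 0.0
        assert out.percent_colocalized == pytest.approx(expected_pct)
        assert out.overlap_volume <= min(out.shb_volume, brp.volume()) + 1e-12

    def test_empty_region_denominator_warns_not_raises(self, cubic_geometry, caplog):
        shb = BinaryMask(np.zeros((2, 4, 4), dtype=bool), cubic_geometry)
        brp = BinaryMask(np.ones((2, 4, 4), dtype=bool), cubic_geometry)
        region = BinaryMask(np.ones((2, 4, 4), dtype=bool), cubic_geometry)
        with caplog.at_level("WARNING"):
            out = colocalization(shb, brp, {"r": region})
        assert out["r"].percent_colocalized == 0.0
        assert "no plaque signal" in caplog.text
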