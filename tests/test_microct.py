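import numpy as np
import pytest

from angioquant import microct
from angioquant.containers import VolumeImage
from _oracles import brute_force_dnv, brute_force_local_thickness
from conftest import random_vessel_mask


def cylinder_volume(n=48, r=4.0, fg=255.0, bg=50.0):
    z, y, x = np.mgrid[:n, :n, :n]
    mask = ((y - n // 2) ** 2 + (x - n // 2) ** 2) <= r * r
    return VolumeImage(np.where(mask, fg, bg), 9.0), mask


class TestVesselnessFilter:
    def test_constant_volume_gives_empty_mask(self):
        vol = VolumeImage(np.full((32, 32, 32), 7.0), 9.0)
        seg = microct.vesselness_filter(vol, scales_um=(9, 18))
        assert not seg.vesselness.any()
        assert not seg.vessel_mask.any()

    def test_cylinder_recovery(self):
        vol, mask = cylinder_volume()
        seg = microct.vesselness_filter(vol, scales_um=(9, 18, 36))
        sens = (seg.vessel_mask & mask).sum() / mask.sum()
        fpr = (seg.vessel_mask & ~mask).sum() / (~mask).sum()
        assert sens >= 0.90
        assert fpr <= 0.05

    def test_tube_outscores_blob(self):
        n = 48
        z, y, x = np.mgrid[:n, :n, :n]
        c = n // 2
        cyl = ((y - c) ** 2 + (x - c) ** 2) <= 16
        sph = ((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) <= 16
        v_cyl = microct.vesselness_filter(
            VolumeImage(np.where(cyl, 255.0, 50.0), 9.0),
            scales_um=(9, 18, 36))
        v_sph = microct.vesselness_filter(
            VolumeImage(np.where(sph, 255.0, 50.0), 9.0),
            scales_um=(9, 18, 36))
        assert v_cyl.raw_peak_response > v_sph.raw_peak_response
        assert v_cyl.vessel_mask.sum() > 0

    def test_subvoxel_scale_rejected(self):
        vol = VolumeImage(np.zeros((32, 32, 32)), 9.0)
        with pytest.raises(ValueError, match="below one voxel"):
            microct.vesselness_filter(vol, scales_um=(4.0,))


class TestFbv:
    def test_trivial_masks(self, tube_phantom):
        vol, gt = tube_phantom
        empty = microct.VesselSegmentation(np.zeros(vol.voxels.shape),
                                           np.zeros(vol.voxels.shape, bool),
                                           (9.0,), 0.5)
        assert microct.compute_fbv(empty, vol) == 0.0
        full = microct.VesselSegmentation(np.ones(vol.voxels.shape),
                                          vol.tumor_mask.copy(), (9.0,), 0.5)
        assert microct.compute_fbv(full, vol) == 1.0

    def test_injected_ground_truth_mask_is_exact(self, tube_phantom):
        vol, gt = tube_phantom
        seg = microct.VesselSegmentation(np.zeros(vol.voxels.shape),
                                         gt.vessel_mask, (9.0,), 0.5)
        assert microct.compute_fbv(seg, vol) == gt.true_fbv

    def test_empty_tumor_mask_rejected(self):
        vol = VolumeImage(np.zeros((32, 32, 32)), 9.0,
                          np.zeros((32, 32, 32), bool))
        seg = microct.VesselSegmentation(np.zeros((32, 32, 32)),
                                         np.zeros((32, 32, 32), bool),
                                         (9.0,), 0.5)
        with pytest.raises(ValueError):
            microct.compute_fbv(seg, vol)


class TestLocalThickness:
    def test_empty_mask(self):
        out = microct.local_thickness(np.zeros((8, 8, 8), bool), 9.0)
        assert not out.any()

    def test_digital_ball_center(self):
        n = 24
        z, y, x = np.mgrid[:n, :n, :n]
        c = n // 2
        ball = ((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) <= 25
        th = microct.local_thickness(ball, 9.0)
        oracle = brute_force_local_thickness(ball) * 9.0
        np.testing.assert_array_equal(th, oracle)
        # a radius-5 ball has central thickness ~10 voxels = 90 um
        assert th[c, c, c] == pytest.approx(90.0, abs=9.0)

    def test_cylinder_interior_caliber(self):
        n = 32
        z, y, x = np.mgrid[:n, :n, :n]
        cyl = ((y - 16) ** 2 + (x - 16) ** 2) <= 16
        th = microct.local_thickness(cyl, 1.0)
        # interior thickness within 1 voxel of the 2r = 8 voxel diameter
        assert abs(th[16, 16, 16] - 8.0) <= 1.0

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            mask = random_vessel_mask((20, 20, 20), rng)
            got = microct.local_thickness(mask, 1.0)
            np.testing.assert_array_equal(got,
                                          brute_force_local_thickness(mask))


class TestCaliberMetrics:
    def test_uniform_calibers(self):
        vc_p90, frac, (hist, _) = microct.caliber_metrics(
            np.full(50, 90.0), vc_large_um=150.0)
        assert vc_p90 == 90.0
        assert frac == 0.0
        assert hist.sum() == pytest.approx(1.0)

    def test_mixture_fraction(self):
        values = np.r_[np.full(80, 90.0), np.full(20, 180.0)]
        _, frac, _ = microct.caliber_metrics(values)
        assert frac == pytest.approx(0.20)

    def test_threshold_is_strict(self):
        _, frac, _ = microct.caliber_metrics(np.full(10, 150.0))
        assert frac == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            microct.caliber_metrics(np.zeros(5))


class TestDnv:
    def seg_for(self, vessel, shape):
        return microct.VesselSegmentation(np.zeros(shape), vessel, (9.0,),
                                          0.5)

    def test_face_adjacent_voxel(self):
        shape = (16, 16, 16)
        vessel = np.zeros(shape, bool)
        vessel[8, 8, 8] = True
        vol = VolumeImage(np.zeros(shape), 9.0)
        dnv, *_ = microct.dnv_metrics(self.seg_for(vessel, shape), vol)
        assert dnv[8, 8, 9] == pytest.approx(9.0)

    def test_straight_line_matches_point_line_distance(self):
        shape = (24, 24, 24)
        vessel = np.zeros(shape, bool)
        vessel[:, 12, 12] = True
        vol = VolumeImage(np.zeros(shape), 9.0)
        dnv, *_ = microct.dnv_metrics(self.seg_for(vessel, shape), vol)
        for k in (1, 3, 7):
            assert dnv[5, 12, 12 + k] == pytest.approx(9.0 * k)

    def test_constructed_far_fraction_is_exact(self):
        # vessel plane at z=0; exactly the voxels with z >= 23 sit more
        # than 200 um away at 9-um spacing (23*9 = 207)
        shape = (5, 5, 40)
        vessel = np.zeros(shape, bool)
        vessel[:, :, 0] = True
        vol = VolumeImage(np.zeros(shape), 9.0)
        _, _, _, frac = microct.dnv_metrics(self.seg_for(vessel, shape), vol)
        assert frac == pytest.approx((39 - 22) / 39)

    def test_empty_vessel_mask_rejected(self):
        shape = (8, 8, 8)
        vol = VolumeImage(np.zeros(shape), 9.0)
        with pytest.raises(ValueError, match="empty vessel mask"):
            microct.dnv_metrics(self.seg_for(np.zeros(shape, bool), shape),
                                vol)

    def test_dilating_vessels_never_increases_distances(self):
        from scipy import ndimage
        rng = np.random.default_rng(9)
        shape = (20, 20, 20)
        vessel = random_vessel_mask(shape, rng)
        vol = VolumeImage(np.zeros(shape), 9.0)
        d1, *_ = microct.dnv_metrics(self.seg_for(vessel, shape), vol)
        grown = ndimage.binary_dilation(vessel)
        d2, *_ = microct.dnv_metrics(self.seg_for(grown, shape), vol)
        assert (d2 <= d1 + 1e-12).all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(17)
        shape = (18, 18, 18)
        vessel = random_vessel_mask(shape, rng)
        vol = VolumeImage(np.zeros(shape), 9.0)
        dnv, *_ = microct.dnv_metrics(self.seg_for(vessel, shape), vol)
        np.testing.assert_array_equal(dnv, brute_force_dnv(vessel) * 9.0)


def test_full_chain_recovers_fbv_on_noise_free_phantom(tube_phantom):
    vol, gt = tube_phantom
    metrics = microct.vascular_metrics(vol, scales_um=(9, 18, 36))
    assert abs(metrics.fbv - gt.true_fbv) / gt.true_fbv <= 0.15
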