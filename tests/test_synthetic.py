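import numpy as np
import pytest

from angioquant import synthetic as syn


class TestVascularPhantom:
    def test_empty_tree(self):
        vol, gt = syn.generate_vascular_phantom(shape=(32, 32, 32),
                                                n_segments=0, seed=0)
        assert gt.true_fbv == 0.0
        assert not gt.vessel_mask.any()

    def test_seed_determinism(self):
        v1, g1 = syn.generate_vascular_phantom(seed=4, noise_sd=5.0)
        v2, g2 = syn.generate_vascular_phantom(seed=4, noise_sd=5.0)
        np.testing.assert_array_equal(v1.voxels, v2.voxels)
        np.testing.assert_array_equal(g1.vessel_mask, g2.vessel_mask)

    def test_ground_truth_fbv_is_exact_voxel_count(self):
        vol, gt = syn.generate_vascular_phantom(shape=(48, 48, 48),
                                                n_segments=10, seed=1)
        assert gt.true_fbv == gt.vessel_mask.sum() / gt.vessel_mask.size

    def test_axis_aligned_cylinder_matches_analytic_volume(self):
        mask = np.zeros((64, 64, 64), bool)
        syn.rasterize_tube(mask, (32, 32, 2), (32, 32, 62), 5.0)
        analytic = np.pi * 5.0 ** 2 * 60
        assert abs(mask.sum() - analytic) / analytic < 0.10

    def test_degenerate_radius_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            syn.generate_vascular_phantom(shape=(32, 32, 32),
                                          radius_range_um=(18.0, 90.0),
                                          seed=0)

    def test_minimum_shape_enforced(self):
        with pytest.raises(ValueError, match="32"):
            syn.generate_vascular_phantom(shape=(16, 16, 16), seed=0)


class TestDceSeriesPhantom:
    def test_no_enhancers_flat(self):
        series, gt = syn.generate_dce_series(enhancing_fraction=0.0,
                                             noise_sd=0.0, seed=0)
        assert gt.true_fev == 0.0
        assert np.ptp(series.signal) == 0.0

    def test_acquisition_defaults(self):
        series, _ = syn.generate_dce_series(seed=0)
        assert series.n_frames == 200
        assert series.frame_interval == 4.8
        assert series.injection_frame == 10

    def test_exact_enhancing_count(self):
        series, gt = syn.generate_dce_series(shape=(10, 10, 10),
                                             enhancing_fraction=0.4, seed=2)
        assert gt.enhancing_mask.sum() == 400
        assert gt.true_fev == 0.4

    def test_curve_reaches_designed_peak_and_is_monotone(self):
        series, gt = syn.generate_dce_series(shape=(4, 4, 1),
                                             enhancing_fraction=1.0,
                                             peak_enhancement=2.0,
                                             noise_sd=0.0, seed=3)
        curve = series.signal[0, 0, 0]
        assert curve[-1] == pytest.approx(2.0 * curve[0])
        assert (np.diff(curve[series.injection_frame:]) >= -1e-12).all()

    def test_weak_peak_warns(self):
        with pytest.warns(UserWarning, match="RSI"):
            syn.generate_dce_series(enhancing_fraction=0.5,
                                    peak_enhancement=1.2, seed=0)


class TestHistologyPhantom:
    def test_no_nuclei_empty_ki67(self):
        from angioquant import histology as hist
        fld, gt = syn.generate_histology_field(n_nuclei=0, seed=0)
        assert gt.nucleus_count_total == 0
        assert not hist.segment_stains(fld).ki67_mask.any()

    def test_designed_in_vessel_count(self):
        fld, gt = syn.generate_histology_field(n_nuclei=12,
                                               frac_in_vessel=0.5, seed=1)
        assert gt.nucleus_count_in_vessel == 6
        assert gt.nucleus_count_total == 12

    def test_all_vessels_rimmed_leaves_no_immature_area(self):
        _, gt = syn.generate_histology_field(with_sma=True, n_nuclei=0,
                                             frac_unrimmed=0.0,
                                             n_vessels=6, seed=2)
        assert gt.immature_area_px == 0

    def test_in_vessel_nuclei_require_vessels(self):
        with pytest.raises(ValueError, match="invalid design"):
            syn.generate_histology_field(n_nuclei=10, frac_in_vessel=0.5,
                                         n_vessels=0, seed=0)

    def test_too_coarse_scale_rejected(self):
        with pytest.raises(ValueError, match="3 px"):
            syn.generate_histology_field(um_per_px=4.0, seed=0)


class TestSpectraPhantom:
    def test_default_effect_peaks_present(self):
        ss = syn.generate_spectra_cohort(seed=0)
        assert 3.23 in set(p for p, _, _ in syn.DEFAULT_PEAKS.values())
        assert 3.24 in set(p for p, _, _ in syn.DEFAULT_PEAKS.values())
        assert ss.n_samples == 12
        assert set(ss.labels) == {"control", "treated"}

    def test_class_mean_ratio_matches_designed_mixture(self):
        # Monte-Carlo over n = 50 per class; the expected point ratio at
        # 3.23 ppm includes the overlap of the neighbouring lines, so the
        # oracle is the closed-form Lorentzian mixture
        ss = syn.generate_spectra_cohort(n_per_class=50, seed=3)
        i = int(np.argmin(np.abs(ss.ppm - 3.23)))

        def mixture(effects):
            total = 0.0
            for name, (pos, fwhm, amp) in syn.DEFAULT_PEAKS.items():
                g = fwhm / 2
                a = amp * effects.get(name, 1.0)
                total += a * g ** 2 / ((3.23 - pos) ** 2 + g ** 2)
            return total

        designed = mixture({"PCho": 1.5, "GPC": 0.6}) / mixture({})
        trt = ss.intensities[ss.labels == "treated", i]
        ctl = ss.intensities[ss.labels == "control", i]
        ratio = trt.mean() / ctl.mean()
        se = ratio * np.sqrt(trt.var() / (50 * trt.mean() ** 2)
                             + ctl.var() / (50 * ctl.mean() ** 2))
        assert abs(ratio - designed) <= 3 * se

    def test_unknown_effect_peak_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            syn.generate_spectra_cohort(class_effects={"Foo": 2.0}, seed=0)


@pytest.fixture(scope="module")
def small_design():
    return syn.StudyDesign(n_control=2, n_treated=2, timepoints=(0, 4),
                           microct_shape=(32, 32, 32),
                           microct_n_segments=8,
                           histology_size_px=(256, 256),
                           n_spectra_per_class=3)


class TestTwoGroupStudy:

    def test_manifest_byte_identical_per_seed(self, small_design):
        b1 = syn.generate_two_group_study(small_design, seed=7)
        b2 = syn.generate_two_group_study(small_design, seed=7)
        assert b1.manifest == b2.manifest
        b3 = syn.generate_two_group_study(small_design, seed=8)
        assert b1.manifest != b3.manifest

    def test_group_sizes_and_effects_recorded(self, small_design):
        b = syn.generate_two_group_study(small_design, seed=7)
        groups = [t.group for t in b.tumors]
        assert groups.count("control") == 2
        assert groups.count("treated") == 2
        assert b.spectra.n_samples == 6

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            syn.StudyDesign(n_control=0)
        with pytest.raises(ValueError):
            syn.StudyDesign(effect_sizes={"fbv": -1.0})
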