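import numpy as np
import pytest
from skimage.color import hsv2rgb
from skimage.draw import disk as draw_disk

from angioquant import histology as hist, synthetic as syn
from angioquant.containers import StainField


def paint(shape, spots, hsv_colors, background=(0.1, 0.02, 0.97)):
    """Render labeled regions to an 8-bit RGB StainField."""
    hsv = np.empty(shape + (3,), dtype=float)
    hsv[...] = background
    for region, color in zip(spots, hsv_colors):
        hsv[region] = color
    rgb = (hsv2rgb(hsv) * 255).round().astype(np.uint8)
    return StainField(rgb, um_per_px=1.0)


LECTIN_HSV = (0.62, 0.7, 0.8)
KI67_HSV = (0.08, 0.7, 0.6)
SMA_HSV = (0.92, 0.7, 0.7)


class TestSegmentStains:
    def test_white_field_is_empty(self):
        fld = paint((64, 64), [], [])
        masks = hist.segment_stains(fld)
        assert not masks.lectin_mask.any()
        assert not masks.ki67_mask.any()
        assert not masks.sma_mask.any()

    def test_painted_area_recovered_exactly(self):
        region = np.zeros((128, 128), bool)
        region[10:60, 20:120] = True        # 5000 px
        fld = paint((128, 128), [region], [LECTIN_HSV])
        masks = hist.segment_stains(fld)
        assert masks.lectin_mask.sum() == 5000
        np.testing.assert_array_equal(masks.lectin_mask, region)

    def test_generator_ground_truth_area(self, histology_field):
        fld, gt = histology_field
        masks = hist.segment_stains(fld)
        assert masks.lectin_mask.sum() == gt.vessel_area_px

    def test_thresholds_recorded_for_provenance(self):
        fld = paint((16, 16), [], [])
        masks = hist.segment_stains(fld)
        assert set(masks.thresholds_used) == {"lectin", "ki67", "sma"}

    def test_invalid_band_rejected(self):
        fld = paint((16, 16), [], [])
        with pytest.raises(ValueError, match="outside"):
            hist.segment_stains(fld, {"lectin": (0.5, 1.2, 0.2, 1.0),
                                      "ki67": (0.03, 0.13, 0.3, 1.0),
                                      "sma": (0.86, 0.98, 0.3, 1.0)})


class TestSeparateNuclei:
    def test_single_disk(self):
        mask = np.zeros((64, 64), bool)
        rr, cc = draw_disk((32, 32), 10)
        mask[rr, cc] = True
        labels = hist.separate_nuclei(mask, nucleus_diameter_px=20)
        assert labels.max() == 1

    def test_two_overlapping_disks_split(self):
        mask = np.zeros((64, 64), bool)
        for center in ((32, 25), (32, 39)):   # 14 px apart, radius 10
            rr, cc = draw_disk(center, 10)
            mask[rr, cc] = True
        labels = hist.separate_nuclei(mask, nucleus_diameter_px=20)
        assert labels.max() == 2

    def test_empty_mask(self):
        labels = hist.separate_nuclei(np.zeros((32, 32), bool))
        assert labels.max() == 0

    def test_generator_field_count_exact(self, histology_field):
        fld, gt = histology_field
        masks = hist.segment_stains(fld)
        labels = hist.separate_nuclei(masks.ki67_mask,
                                      8.0 / fld.um_per_px)
        assert labels.max() == gt.nucleus_count_total


class TestPecDensity:
    def build(self):
        """5 nuclei inside a 200x100 px vessel, 7 outside; 0.02 mm^2."""
        lectin = np.zeros((300, 300), bool)
        lectin[20:120, 50:250] = True      # 20000 px = 0.02 mm^2 at 1 um/px
        labels = np.zeros((300, 300), np.int32)
        k = 0
        for c in [(40, 80), (60, 120), (90, 160), (50, 200), (100, 100)]:
            k += 1
            rr, cc = draw_disk(c, 6)
            labels[rr, cc] = k
        for c in [(160, 40), (200, 80), (240, 120), (160, 200),
                  (200, 240), (250, 250), (280, 30)]:
            k += 1
            rr, cc = draw_disk(c, 6)
            labels[rr, cc] = k
        masks = hist.StainMasks(lectin, labels > 0,
                                np.zeros((300, 300), bool))
        return labels, masks

    def test_constructed_density(self):
        labels, masks = self.build()
        res = hist.pec_density(labels, masks, um_per_px=1.0)
        assert res.n_pec == 5
        assert res.n_ki67_total == 12
        assert res.vessel_area_mm2 == pytest.approx(0.02)
        assert res.pec_density == pytest.approx(250.0)

    def test_no_nuclei(self):
        _, masks = self.build()
        res = hist.pec_density(np.zeros((300, 300), np.int32), masks, 1.0)
        assert res.n_pec == 0

    def test_nucleus_occluding_vessel_still_counts(self):
        # a nucleus painted over the vessel removes lectin pixels under
        # it; hole filling restores the membership test
        lectin = np.zeros((100, 100), bool)
        lectin[20:80, 20:80] = True
        labels = np.zeros((100, 100), np.int32)
        rr, cc = draw_disk((50, 50), 8)
        labels[rr, cc] = 1
        lectin[rr, cc] = False
        masks = hist.StainMasks(lectin, labels > 0,
                                np.zeros((100, 100), bool))
        assert hist.pec_density(labels, masks, 1.0).n_pec == 1

    def test_pooling_invariant_to_field_partition(self):
        labels, masks = self.build()
        whole = hist.pec_density(labels, masks, 1.0)
        halves = []
        for sl in (np.s_[:, :150], np.s_[:, 150:]):
            sub = hist.StainMasks(masks.lectin_mask[sl],
                                  masks.ki67_mask[sl],
                                  masks.sma_mask[sl])
            halves.append(hist.pec_density(labels[sl], sub, 1.0))
        pooled = hist.pool_pec_results(halves)
        assert pooled.vessel_area_mm2 == pytest.approx(whole.vessel_area_mm2)
        assert pooled.pec_density == pytest.approx(
            (halves[0].n_pec + halves[1].n_pec) / pooled.vessel_area_mm2)


class TestImmatureFraction:
    def test_no_sma_means_fully_immature(self):
        lectin = np.zeros((50, 50), bool)
        lectin[10:20, 10:40] = True
        masks = hist.StainMasks(lectin, np.zeros((50, 50), bool),
                                np.zeros((50, 50), bool))
        assert hist.immature_vessel_fraction(masks, 1.0).immature_fraction \
            == 1.0

    def test_all_vessels_touching_sma(self):
        lectin = np.zeros((50, 50), bool)
        lectin[10:20, 10:40] = True
        sma = np.zeros((50, 50), bool)
        sma[20:22, 10:40] = True   # adjacent -> distance 1 um < 5 um
        masks = hist.StainMasks(lectin, np.zeros((50, 50), bool), sma)
        assert hist.immature_vessel_fraction(masks, 1.0).immature_fraction \
            == 0.0

    def test_two_component_construction(self):
        # components of 300 and 700 px; only the 300-px one is >= 5 um
        # from any alpha-SMA pixel
        lectin = np.zeros((100, 200), bool)
        lectin[10:40, 10:20] = True      # 300 px, far from SMA
        lectin[10:80, 100:110] = True    # 700 px, SMA adjacent
        sma = np.zeros((100, 200), bool)
        sma[10:80, 111:113] = True
        masks = hist.StainMasks(lectin, np.zeros((100, 200), bool), sma)
        res = hist.immature_vessel_fraction(masks, 1.0, min_dist_um=5.0)
        assert res.immature_area_px == 300
        assert res.immature_fraction == pytest.approx(0.30)

    def test_adding_sma_never_increases_fraction(self):
        rng = np.random.default_rng(8)
        lectin = rng.random((60, 60)) > 0.8
        sma = np.zeros((60, 60), bool)
        masks = hist.StainMasks(lectin, np.zeros((60, 60), bool), sma)
        prev = hist.immature_vessel_fraction(masks, 1.0).immature_fraction
        for _ in range(4):
            extra = rng.random((60, 60)) > 0.97
            sma = sma | extra
            masks = hist.StainMasks(lectin, np.zeros((60, 60), bool), sma)
            cur = hist.immature_vessel_fraction(masks, 1.0).immature_fraction
            assert cur <= prev + 1e-12
            prev = cur

    def test_empty_lectin_is_undefined(self):
        masks = hist.StainMasks(np.zeros((10, 10), bool),
                                np.zeros((10, 10), bool),
                                np.zeros((10, 10), bool))
        assert np.isnan(
            hist.immature_vessel_fraction(masks, 1.0).immature_fraction)

    def test_generator_ground_truth_recovered(self):
        fld, gt = syn.generate_histology_field(with_sma=True, n_nuclei=0,
                                               frac_unrimmed=0.4,
                                               n_vessels=8, seed=13)
        masks = hist.segment_stains(fld)
        res = hist.immature_vessel_fraction(masks, fld.um_per_px)
        assert res.immature_area_px == gt.immature_area_px
        assert res.immature_fraction == pytest.approx(gt.immature_fraction)
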