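"""Nucleus/lamina segmentation pipeline against synthetic ground truth."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from nucleomech import synthetic as syn
from nucleomech.images import ImageStack, LabelMask, RasterImage
from nucleomech.segmentation import (SegmentationConfig, detect_lamina,
                                     measure_intensities, segment_nuclei,
                                     split_and_assign_laminae)
from _oracles import match_dice


class TestSegmentNuclei:
    def test_five_disjoint_nuclei_recovered(self, noisy_five_nucleus_scene):
        scene = noisy_five_nucleus_scene
        labels = segment_nuclei(scene.image.plane(0, "dapi"))
        assert len(labels.ids) == 5
        dices = match_dice(scene.nucleus_labels.labels, labels.labels)
        assert min(dices) >= 0.90

    def test_touching_ellipses_split_by_watershed(self):
        img = np.full((160, 260), 100.0)
        yy, xx = np.mgrid[0:160, 0:260]
        # two ellipses tangent at x = 130
        e1 = ((xx - 90) / 40.0) ** 2 + ((yy - 80) / 30.0) ** 2 <= 1
        e2 = ((xx - 170) / 40.0) ** 2 + ((yy - 80) / 30.0) ** 2 <= 1
        img[e1 | e2] = 1200.0
        labels = segment_nuclei(RasterImage(img, 0.2))
        assert len(labels.ids) == 2

    def test_blank_image_yields_zero_labels(self):
        labels = segment_nuclei(RasterImage(np.zeros((64, 64)), 0.2))
        assert len(labels.ids) == 0

    def test_labels_partition_no_pixel_double_labeled(self,
                                                     noisy_five_nucleus_scene):
        labels = segment_nuclei(
            noisy_five_nucleus_scene.image.plane(0, "dapi"))
        # by construction of a label image; check ids are contiguous 1..n
        assert list(labels.ids) == list(range(1, len(labels.ids) + 1))

    def test_deterministic_bit_for_bit(self, noisy_five_nucleus_scene):
        dapi = noisy_five_nucleus_scene.image.plane(0, "dapi")
        l1 = segment_nuclei(dapi)
        l2 = segment_nuclei(dapi)
        assert np.array_equal(l1.labels, l2.labels)

    def test_min_area_filter_removes_small_objects(self):
        img = np.full((128, 128), 100.0)
        img[60:64, 60:64] = 1200.0          # 16 px = 0.64 µm² at 0.2 µm/px
        yy, xx = np.mgrid[0:128, 0:128]
        img[(xx - 40) ** 2 + (yy - 40) ** 2 <= 20 ** 2] = 1200.0
        labels = segment_nuclei(RasterImage(img, 0.2),
                                SegmentationConfig(min_area_um2=10.0))
        assert len(labels.ids) == 1


class TestDetectLamina:
    def test_ring_covered_and_interior_clean(self, noisy_five_nucleus_scene):
        scene = noisy_five_nucleus_scene
        mask = detect_lamina(scene.image.plane(0, "lamin"))
        rim = scene.lamina_mask
        interior = (scene.nucleus_labels.labels > 0) & ~rim
        assert (mask & rim).sum() / rim.sum() >= 0.80
        assert (mask & interior).sum() / interior.sum() <= 0.10

    def test_uniform_bright_disc_degenerate_input(self):
        img = np.full((128, 128), 50.0)
        yy, xx = np.mgrid[0:128, 0:128]
        img[(xx - 64) ** 2 + (yy - 64) ** 2 <= 30 ** 2] = 500.0
        mask = detect_lamina(RasterImage(img, 0.2))
        assert mask.dtype == bool and mask.shape == img.shape

    def test_low_noise_does_not_change_component_count(self):
        spec = syn.SyntheticNucleusSpec(center=(80, 80), noise_sd=0.0)
        base = syn.render_nucleus_image(spec, (160, 160), seed=0)
        m0 = detect_lamina(base.image.plane(0, "lamin"))
        rng = np.random.default_rng(0)
        noisy = base.image.plane(0, "lamin").pixels + rng.normal(0, 20, (160, 160))
        m1 = detect_lamina(RasterImage(noisy, 0.2))
        assert ndi.label(m0)[1] == ndi.label(m1)[1]


class TestSplitAndAssign:
    def _ring(self, shape, center, r_out, r_in):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
        return (d2 <= r_out ** 2) & (d2 > r_in ** 2)

    def test_one_ring_one_nucleus(self):
        nuc = np.zeros((100, 100), np.int32)
        yy, xx = np.mgrid[0:100, 0:100]
        nuc[(xx - 50) ** 2 + (yy - 50) ** 2 <= 28 ** 2] = 1
        ring = self._ring((100, 100), (50, 50), 30, 25)
        assigned, unassigned = split_and_assign_laminae(ring, LabelMask(nuc))
        assert set(assigned) == {1}
        assert not unassigned.any()

    def test_multi_overlap_goes_to_max_overlap_nucleus(self):
        nuc = np.zeros((60, 120), np.int32)
        nuc[20:40, 10:50] = 1     # A
        nuc[20:40, 52:60] = 2     # B (small sliver near the component)
        comp = np.zeros((60, 120), bool)
        comp[28:31, 30:55] = True  # overlaps A by 3x20=60 px, B by 3x3=9 px
        assigned, _ = split_and_assign_laminae(comp, LabelMask(nuc), h=0)
        assert 1 in assigned and 2 not in assigned

    def test_disjoint_component_reported_unassigned(self):
        nuc = np.zeros((60, 60), np.int32)
        nuc[5:15, 5:15] = 1
        comp = np.zeros((60, 60), bool)
        comp[40:50, 40:50] = True
        assigned, unassigned = split_and_assign_laminae(comp, LabelMask(nuc))
        assert assigned == {}
        assert unassigned.sum() == 100


class TestMeasureIntensities:
    def _stack(self, arr):
        return ImageStack(np.asarray(arr)[None, None], ("ch0",), 0.2)

    def test_constant_image_means_equal_constant(self):
        nuc = np.zeros((40, 40), np.int32)
        nuc[10:30, 10:30] = 1
        lam = {1: np.pad(np.ones((10, 10), bool), 15)}
        recs = measure_intensities(LabelMask(nuc), lam,
                                   self._stack(np.full((40, 40), 7.0)))
        assert recs[0].mean_intensity_nucleus["ch0"] == pytest.approx(7.0)
        assert recs[0].mean_intensity_lamina["ch0"] == pytest.approx(7.0)

    def test_generating_intensities_recovered(self, clean_nucleus_scene):
        scene = clean_nucleus_scene
        assigned = {1: scene.lamina_mask}
        recs = measure_intensities(scene.nucleus_labels, assigned, scene.image)
        assert recs[0].mean_intensity_lamina["lamin"] == pytest.approx(3000, rel=0.1)
        assert 100 < recs[0].mean_intensity_nucleus["dapi"] <= 1200 * 1.01

    def test_scaling_image_scales_means(self, clean_nucleus_scene):
        scene = clean_nucleus_scene
        assigned = {1: scene.lamina_mask}
        r1 = measure_intensities(scene.nucleus_labels, assigned, scene.image)
        scaled = ImageStack(scene.image.planes * 3.0,
                            scene.image.channel_names, 0.2)
        r2 = measure_intensities(scene.nucleus_labels, assigned, scaled)
        for ch in ("dapi", "lamin"):
            assert r2[0].mean_intensity_nucleus[ch] == pytest.approx(
                3.0 * r1[0].mean_intensity_nucleus[ch])

    def test_empty_lamina_recorded_missing_not_zero(self):
        nuc = np.zeros((20, 20), np.int32)
        nuc[5:15, 5:15] = 1
        recs = measure_intensities(LabelMask(nuc), {},
                                   self._stack(np.ones((20, 20))))
        assert np.isnan(recs[0].mean_intensity_lamina["ch0"])
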