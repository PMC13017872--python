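"""Nucleus segmentation, DoG filtering, focus counting and micronucleus
frequency on synthetic rasters with known ground truth."""

import numpy as np
import pytest

from radcell import imaging as im
from radcell import synthetic as syn
from radcell.imaging import (
    DetectionParams,
    MicronucleusResult,
    bin_foci,
    detect_foci,
    detect_micronuclei,
    dog_subtract,
    segment_nuclei,
)


class TestBinFoci:
    @pytest.mark.parametrize("n, group", [
        (0, "0"), (1, "1-4"), (4, "1-4"), (5, "5-9"), (9, "5-9"),
        (10, ">=10"), (37, ">=10")])
    def test_grouping(self, n, group):
        assert bin_foci(n) == group

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bin_foci(-1)


class TestDogSubtract:
    def test_constant_image_maps_to_zero(self):
        out = dog_subtract(np.full((64, 64), 7.3), 1.0, 4.0)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_single_bright_pixel_has_positive_center(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        out = dog_subtract(img, 1.0, 4.0)
        assert out[32, 32] > 0
        assert out[32, 32] == out.max()

    def test_linearity_of_distant_spots(self):
        a = np.zeros((128, 128))
        b = np.zeros((128, 128))
        a[30, 30] = 2.0
        b[90, 100] = 3.0
        combined = dog_subtract(a + b, 1.0, 4.0)
        separate = dog_subtract(a, 1.0, 4.0) + dog_subtract(b, 1.0, 4.0)
        assert np.allclose(combined, separate, atol=1e-6)

    @pytest.mark.parametrize("s, l", [(0.0, 4.0), (4.0, 1.0), (2.0, 2.0)])
    def test_bad_sigmas_rejected(self, s, l):
        with pytest.raises(ValueError):
            dog_subtract(np.zeros((8, 8)), s, l)


class TestSegmentNuclei:
    def test_blank_image_yields_no_nuclei(self):
        labels, masks = segment_nuclei(np.zeros((64, 64)))
        assert masks == [] and labels.max() == 0

    def test_recovers_planted_ellipses(self):
        cfg = syn.ImageSimConfig(n_nuclei=10, seed=7, noise_sd=0.02)
        dapi, _, truth = syn.generate_image_pair(cfg)
        labels, masks = segment_nuclei(dapi)
        assert len(masks) == 10
        for _, nuc in truth.nuclei.iterrows():
            d = min(np.hypot(m.centroid[0] - nuc.row, m.centroid[1] - nuc.col)
                    for m in masks)
            assert d < 2.0

    def test_translation_equivariance(self):
        cfg = syn.ImageSimConfig(n_nuclei=6, seed=8, noise_sd=0.02,
                                 image_size=(400, 400))
        dapi, _, _ = syn.generate_image_pair(cfg)
        shifted = np.roll(dapi, (5, 7), axis=(0, 1))
        _, m1 = segment_nuclei(dapi)
        _, m2 = segment_nuclei(shifted)
        assert len(m1) == len(m2)
        c1 = sorted((m.centroid for m in m1))
        c2 = sorted(((m.centroid[0] - 5, m.centroid[1] - 7) for m in m2))
        for (r1, col1), (r2, col2) in zip(c1, c2):
            assert abs(r1 - r2) < 0.5 and abs(col1 - col2) < 0.5


class TestDetectFoci:
    def test_uniform_nuclei_have_zero_foci(self):
        # noiseless uniform interiors: nothing above any threshold
        cfg = syn.ImageSimConfig(n_nuclei=8, seed=9, noise_sd=0.0,
                                 foci_per_nucleus=0)
        dapi, focus, _ = syn.generate_image_pair(cfg)
        labels, masks = segment_nuclei(dapi)
        recs = detect_foci(focus, labels, masks)
        assert all(r.n_foci == 0 for r in recs)

    def test_planted_spots_recovered_exactly(self, standard_image):
        cfg, dapi, focus, truth = standard_image
        labels, masks = segment_nuclei(dapi)
        recs = detect_foci(focus, labels, masks)
        counts = np.array([r.n_foci for r in recs])
        assert len(counts) == cfg.n_nuclei
        assert np.mean(counts == cfg.foci_per_nucleus) >= 0.95

    def test_faint_spots_fall_below_threshold(self):
        # planted amplitude 1x the noise SD sits below the 3x-background
        # threshold after DoG attenuation: counts stay at the spot-free
        # noise floor instead of approaching the 7 planted spots
        base = dict(n_nuclei=12, seed=13, image_size=(400, 400))
        dapi0, focus0, _ = syn.generate_image_pair(
            syn.ImageSimConfig(foci_per_nucleus=0, **base))
        dapi1, focus1, _ = syn.generate_image_pair(
            syn.ImageSimConfig(foci_per_nucleus=7, focus_amplitude=1.0, **base))
        labels, masks = segment_nuclei(dapi0)
        c0 = [r.n_foci for r in detect_foci(focus0, labels, masks)]
        labels1, masks1 = segment_nuclei(dapi1)
        c1 = [r.n_foci for r in detect_foci(focus1, labels1, masks1)]
        assert abs(np.mean(c1) - np.mean(c0)) < 1.5
        assert np.mean(c1) < 3.5  # nowhere near the planted 7

    def test_constant_offset_invariance(self, standard_image):
        cfg, dapi, focus, _ = standard_image
        labels, masks = segment_nuclei(dapi)
        c1 = [r.n_foci for r in detect_foci(focus, labels, masks)]
        c2 = [r.n_foci for r in detect_foci(focus + 13.7, labels, masks)]
        assert c1 == c2

    def test_determinism(self, standard_image):
        cfg, dapi, focus, _ = standard_image
        labels, masks = segment_nuclei(dapi)
        r1 = detect_foci(focus, labels, masks)
        r2 = detect_foci(focus, labels, masks)
        assert r1 == r2

    def test_no_nuclei_empty_records(self):
        assert detect_foci(np.zeros((32, 32)), np.zeros((32, 32), int), []) == []

    def test_mae_at_five_sigma_amplitude(self):
        counts = []
        for seed in (31, 32):
            cfg = syn.ImageSimConfig(n_nuclei=50, image_size=(800, 800),
                                     foci_per_nucleus=7, focus_amplitude=5.0,
                                     seed=seed)
            dapi, focus, _ = syn.generate_image_pair(cfg)
            labels, masks = segment_nuclei(dapi)
            counts += [r.n_foci for r in detect_foci(focus, labels, masks)]
        mae = np.abs(np.array(counts) - 7).mean()
        assert len(counts) == 100
        assert mae <= 0.5


class TestMicronuclei:
    def test_no_planted_micronuclei(self):
        cfg = syn.ImageSimConfig(n_nuclei=10, seed=17, mn_frequency=0.0)
        dapi, _, _ = syn.generate_image_pair(cfg)
        labels, masks = segment_nuclei(dapi)
        result = detect_micronuclei(dapi, labels, masks)
        assert result.frequency == 0.0
        assert result.se == 0.0

    def test_planted_frequency_recovered(self, standard_image):
        cfg, dapi, _, truth = standard_image
        labels, masks = segment_nuclei(dapi)
        result = detect_micronuclei(dapi, labels, masks)
        planted = truth.nuclei.has_mn.mean()
        tol = 3 * np.sqrt(planted * (1 - planted) / cfg.n_nuclei)
        assert abs(result.frequency - planted) <= tol

    def test_large_objects_never_counted_as_micronuclei(self):
        cfg = syn.ImageSimConfig(n_nuclei=6, seed=19, mn_frequency=0.0,
                                 noise_sd=0.02)
        dapi, _, _ = syn.generate_image_pair(cfg)
        # blob well above the micronucleus size range, away from nuclei
        dapi[10:40, 200:230] += 1.0
        labels, masks = segment_nuclei(dapi)
        result = detect_micronuclei(dapi, labels, masks)
        assert result.n_micronuclei == 0

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            detect_micronuclei(np.zeros((32, 32)), np.zeros((32, 32), int), [])
        with pytest.raises(ValueError):
            MicronucleusResult.from_counts({})

    def test_se_zero_iff_degenerate_frequency(self):
        r_none = MicronucleusResult.from_counts({1: 0, 2: 0, 3: 0})
        r_all = MicronucleusResult.from_counts({1: 1, 2: 2})
        r_mid = MicronucleusResult.from_counts({1: 1, 2: 0})
        assert r_none.se == 0.0 and r_all.se == 0.0
        assert r_mid.se > 0.0


class TestDetectionParams:
    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            DetectionParams(dog_sigma_small=4.0, dog_sigma_large=1.0)

    def test_multiplier_positive(self):
        with pytest.raises(ValueError):
            DetectionParams(threshold_multiplier=0.0)
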