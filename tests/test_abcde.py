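"""Segmentation and the clinical ABCDE / TDS scores."""

import numpy as np
import pytest
from skimage.color import hsv2rgb

from conftest import disc_mask, ellipse_mask, square_mask
from lesionfuse.abcde import (
    LesionSegmentation,
    asymmetry_score,
    border_score,
    colour_score,
    diameter_score,
    evolution_score,
    segment_lesion,
    segmentation_from_mask,
    tds_classify,
    tds_score,
)
from lesionfuse.errors import NoLesionError, UndefinedScoreError
from lesionfuse.synthetic import LesionSpec, generate_lesion, generate_sequence


def lesion_image_from_mask(mask, lesion_value=40, background=200):
    img = np.full(mask.shape + (3,), background, dtype=np.uint8)
    img[mask] = lesion_value
    return img


def exhaustive_otsu(gray):
    """Independent oracle: maximise inter-class variance over all 256 bins."""
    hist = np.bincount(gray.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_var = 0, -1.0
    for t in range(1, 256):
        w0, w1 = hist[:t].sum(), hist[t:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (np.arange(t) * hist[:t]).sum() / w0
        mu1 = (np.arange(t, 256) * hist[t:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestSegmentLesion:
    def test_disc_iou_against_ground_truth(self):
        mask = disc_mask(50)
        seg = segment_lesion(lesion_image_from_mask(mask))
        full = seg.full_mask
        iou = (full & mask).sum() / (full | mask).sum()
        assert iou >= 0.95

    def test_two_valued_image_threshold_between_modes(self):
        mask = disc_mask(30)
        img = lesion_image_from_mask(mask, 40, 200)
        seg = segment_lesion(img)
        # Otsu must split strictly between the two populations: recovered
        # mask matches the disc almost exactly (morphology preserves it)
        assert (seg.full_mask ^ mask).sum() / mask.sum() < 0.02

    def test_constant_image_rejected(self):
        with pytest.raises(NoLesionError):
            segment_lesion(np.full((64, 64, 3), 99, dtype=np.uint8))

    def test_synthetic_lesion_iou(self, plain_lesion):
        seg = segment_lesion(plain_lesion.image)
        gt = plain_lesion.ground_truth.lesion_mask
        full = seg.full_mask
        assert (full & gt).sum() / (full | gt).sum() >= 0.9

    def test_otsu_matches_exhaustive_oracle(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(0)
        for _ in range(50):
            gray = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
            t_impl = threshold_otsu(gray, nbins=256)
            t_oracle = exhaustive_otsu(gray)
            # identical class partitions: implementation's darker class is
            # gray <= t, the oracle's is gray < t (bin-edge conventions)
            assert np.array_equal(gray <= t_impl, gray < t_oracle)


class TestScores:
    def seg(self, a_aff, a_non_aff, perimeter=100.0):
        return LesionSegmentation(mask=np.ones((1, 1), bool), frame_offset=(0, 0),
                                  image_shape=(1, 1), a_aff=a_aff, a_non_aff=a_non_aff,
                                  perimeter=perimeter, boundary=np.zeros((3, 2)))

    @pytest.mark.parametrize("aff,nonaff,expected", [
        (100, 100, 10.0), (100, 400, 2.5), (0, 100, 0.0),
    ])
    def test_asymmetry_values(self, aff, nonaff, expected):
        assert asymmetry_score(self.seg(aff, nonaff)) == pytest.approx(expected)

    def test_asymmetry_zero_unaffected_rejected(self):
        with pytest.raises(UndefinedScoreError):
            asymmetry_score(self.seg(100, 0))

    def test_border_disc_isoperimetric_identity(self):
        for radius in (30, 60, 100):
            seg = segmentation_from_mask(disc_mask(radius))
            assert border_score(seg) == pytest.approx(0.100, rel=0.05)

    def test_border_square_closed_form(self):
        seg = segmentation_from_mask(square_mask(120))
        assert border_score(seg) == pytest.approx(0.4 / np.pi, rel=0.02)

    def test_border_zero_area_rejected(self):
        with pytest.raises(UndefinedScoreError):
            border_score(self.seg(0, 10))

    def test_colour_uniform_lesion_zero(self):
        mask = disc_mask(20)
        seg = segmentation_from_mask(mask)
        assert colour_score(lesion_image_from_mask(mask), seg) == pytest.approx(0.0, abs=1e-12)

    def test_colour_two_tone_matches_pooled_std_oracle(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        hsv_a, hsv_b = (0.2, 0.5, 0.4), (0.6, 0.3, 0.8)
        img = np.zeros((40, 40, 3))
        img[:, :20] = hsv2rgb(np.array(hsv_a)[None, None, :])
        img[:, 20:] = hsv2rgb(np.array(hsv_b)[None, None, :])
        img = (img * 255).astype(np.uint8)
        seg = segmentation_from_mask(mask, margin_frac=0.0)
        # oracle: half the lesion pixels at each tone, pooled channel variance
        from skimage.color import rgb2hsv

        vals = rgb2hsv(img)[mask]
        expected = np.sqrt(vals.var(axis=0).mean()) / 10.0
        assert colour_score(img, seg) == pytest.approx(expected, rel=1e-9)

    def test_colour_empty_mask_rejected(self):
        with pytest.raises(UndefinedScoreError):
            colour_score(np.zeros((4, 4, 3), np.uint8), self.seg(0, 10))

    @pytest.mark.parametrize("radius,expected", [(20, 2.0), (5, 1.0)])
    def test_diameter_disc_closed_form(self, radius, expected):
        # 4a/(10p) = r/5 for a disc => D = sqrt(r/5)
        seg = segmentation_from_mask(disc_mask(radius))
        assert diameter_score(seg) == pytest.approx(expected, rel=0.05)

    def test_diameter_zero_area(self):
        assert diameter_score(self.seg(0, 10, perimeter=50.0)) == 0.0


class TestEvolution:
    def test_single_frame_zero(self):
        seg = segmentation_from_mask(disc_mask(20))
        assert evolution_score([seg]) == 0.0

    def test_identical_frames_zero(self):
        seg = segmentation_from_mask(disc_mask(20))
        assert evolution_score([seg, seg]) == 0.0

    def test_area_doubled_border_unchanged(self):
        a = segmentation_from_mask(disc_mask(40))
        b = segmentation_from_mask(disc_mask(int(round(40 * np.sqrt(2)))))
        # discs keep B ~ 0.1, area doubles => E ~ mean(1.0, ~0) ~ 0.5
        assert evolution_score([a, b]) == pytest.approx(0.5, abs=0.05)

    def test_temporal_series_from_generator(self):
        frames = generate_sequence(LesionSpec(seed=2, semi_axes=(20, 15)),
                                   timepoints=2, growth_rate=0.1)
        segs = [segmentation_from_mask(f.ground_truth.lesion_mask) for f in frames]
        assert evolution_score(segs) > 0.0


class TestTds:
    @pytest.mark.parametrize("abcd,expected", [
        ((0, 0, 0, 0), 0.0),
        ((3, 1, 1, 1), 5.0),
        ((10, 0, 0, 0), 13.0),
    ])
    def test_weighted_sum(self, abcd, expected):
        assert tds_score(*abcd) == pytest.approx(expected)

    def test_linearity_in_each_argument(self):
        base = tds_score(1.0, 1.0, 1.0, 1.0)
        for i, w in enumerate((1.3, 0.1, 0.5, 0.5)):
            args = [1.0] * 4
            args[i] = 2.0
            assert tds_score(*args) - base == pytest.approx(w)

    @pytest.mark.parametrize("tds,expected", [
        (4.74, "benign"), (4.75, "suspicious"), (5.0, "suspicious"),
        (5.45, "suspicious"), (5.46, "malignant"),
    ])
    def test_decision_boundaries(self, tds, expected):
        assert tds_classify(tds) == expected


class TestShapeProperties:
    def test_isoperimetric_median_over_random_discs(self):
        rng = np.random.default_rng(1)
        scores = [border_score(segmentation_from_mask(disc_mask(int(r))))
                  for r in rng.integers(30, 101, size=20)]
        assert 0.095 <= float(np.median(scores)) <= 0.105

    def test_waved_ellipse_border_exceeds_disc(self):
        spec = LesionSpec(seed=3, semi_axes=(35, 25), border_wave_amplitude=4.0,
                          border_wave_frequency=8)
        waved = generate_lesion(spec).ground_truth.lesion_mask
        b_waved = border_score(segmentation_from_mask(waved))
        assert b_waved > 0.105  # strictly above every disc of equal area

    def test_scale_invariance_of_border_and_growth_of_diameter(self):
        small = segmentation_from_mask(disc_mask(40))
        large = segmentation_from_mask(disc_mask(80))
        assert border_score(large) == pytest.approx(border_score(small), rel=0.03)
        assert diameter_score(large) > diameter_score(small)
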