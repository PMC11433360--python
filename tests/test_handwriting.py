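"""Unit tests for the handwriting pipeline on rendered fixtures."""

import numpy as np
import pytest

from pdnet.features import ValidationError, moving_average
from pdnet.handwriting import (
    BinaryPage,
    HandwritingConfig,
    PageImage,
    binarize_page,
    compute_baseline,
    extract_strokes,
    size_flags,
    slant_angles,
    tremor_series_writing,
    uniformity_series,
)
from pdnet.synth import PageProfile, synth_page


def _page_from_mask(mask, dpi=300.0):
    return BinaryPage(np.asarray(mask, dtype=bool), dpi)


def _blank(h=400, w=600):
    return np.zeros((h, w), dtype=bool)


class TestMovingAverage:
    def test_linear_ramp_reproduced_exactly_everywhere(self):
        x = np.linspace(3, 40, 37)
        assert np.allclose(moving_average(x, 9), x)

    def test_high_frequency_wobble_attenuated(self):
        n = np.arange(200)
        wobble = np.sin(2 * np.pi * n / 3)  # period << window
        out = moving_average(wobble, 15)
        assert np.max(np.abs(out[10:-10])) < 0.3


class TestBinarize:
    def test_all_white_page_empty_mask(self):
        page = PageImage(np.full((100, 100), 255.0), 300.0)
        assert binarize_page(page).mask.sum() == 0

    @pytest.mark.parametrize("offset", [-40, 0, 60])
    def test_otsu_invariant_to_brightness_offset(self, offset, healthy_page):
        page, _, _ = healthy_page
        ref = binarize_page(page).mask
        shifted = PageImage(
            np.clip(page.pixels.astype(float) + offset, 0, 255), page.dpi
        )
        assert np.array_equal(binarize_page(shifted).mask, ref)

    def test_inverted_polarity_same_ink_area(self, healthy_page):
        page, _, _ = healthy_page
        ref = binarize_page(page).mask
        inverted = PageImage(255.0 - page.pixels.astype(float), page.dpi)
        inv = binarize_page(inverted).mask
        assert inv.sum() == ref.sum()

    def test_dpi_metadata_required(self, tmp_path, healthy_page):
        from PIL import Image

        from pdnet.handwriting import load_and_binarize

        page, _, _ = healthy_page
        p = tmp_path / "page.png"
        Image.fromarray(page.pixels).save(p)  # no dpi metadata
        with pytest.raises(ValidationError, match="dpi"):
            load_and_binarize(p)
        assert load_and_binarize(p, dpi=300.0).dpi == 300.0


class TestStrokes:
    def test_two_squares_left_to_right(self):
        mask = _blank()
        mask[100:140, 50:90] = True
        mask[100:140, 200:240] = True
        strokes = extract_strokes(_page_from_mask(mask))
        assert len(strokes) == 2
        assert strokes.strokes[0].centroid[1] < strokes.strokes[1].centroid[1]

    def test_straight_bar_zero_curvature(self):
        mask = _blank()
        mask[200:204, 100:300] = True
        strokes = extract_strokes(_page_from_mask(mask))
        assert strokes.strokes[0].curvature < 0.05

    def test_two_line_reading_order(self):
        mask = _blank()
        for x in (300, 100, 200):  # deliberately shuffled x
            mask[80:120, x : x + 10] = True   # line 1
            mask[280:320, x : x + 10] = True  # line 2
        strokes = extract_strokes(_page_from_mask(mask))
        lines = [s.line_index for s in strokes.strokes]
        xs = [s.centroid[1] for s in strokes.strokes]
        assert lines == [0, 0, 0, 1, 1, 1]
        assert xs[:3] == sorted(xs[:3]) and xs[3:] == sorted(xs[3:])

    def test_empty_mask_empty_strokeset(self):
        assert len(extract_strokes(_page_from_mask(_blank()))) == 0


class TestBaseline:
    def test_flat_centroids_flat_track(self):
        mask = _blank()
        for x in range(5):
            mask[100:140, 50 + 60 * x : 70 + 60 * x] = True
        track = compute_baseline(extract_strokes(_page_from_mask(mask)))
        assert np.allclose(track.per_line[0][2], 119.5)

    def test_linear_ramp_track_equals_ramp(self):
        mask = _blank(600, 900)
        tops = 100 + 10 * np.arange(8)
        for i, top in enumerate(tops):
            mask[top : top + 40, 50 + 80 * i : 70 + 80 * i] = True
        cfg = HandwritingConfig(theta_baseline=np.inf)  # keep one line band
        strokes = extract_strokes(_page_from_mask(mask))
        for s in strokes.strokes:
            s.line_index = 0
        track = compute_baseline(strokes, window=5)
        ys = track.per_line[0][2]
        assert np.allclose(ys, tops + 19.5)

    def test_needs_at_least_one_stroke(self):
        with pytest.raises(ValidationError):
            compute_baseline(extract_strokes(_page_from_mask(_blank())))


class TestSlant:
    def test_rendered_ten_degree_slant_recovered(self):
        page, _, _ = synth_page(
            PageProfile(seed=2, slant_deg_mean=10.0, slant_deg_sd=0.0),
            n_lines=6, strokes_per_line=15, dpi=300.0,
        )
        res_page = binarize_page(page)
        strokes = extract_strokes(res_page, compute_curvature=False)
        baseline = compute_baseline(strokes)
        angles = slant_angles(res_page, baseline, strokes)
        assert abs(np.mean(angles.values) - 10.0) <= 2.0

    def test_vertical_strokes_near_zero(self):
        page, _, _ = synth_page(
            PageProfile(seed=2, slant_deg_mean=0.0, slant_deg_sd=0.0),
            n_lines=6, strokes_per_line=15, dpi=300.0,
        )
        bp = binarize_page(page)
        strokes = extract_strokes(bp, compute_curvature=False)
        angles = slant_angles(bp, compute_baseline(strokes), strokes)
        assert abs(np.mean(angles.values)) <= 1.0

    def test_horizontal_rules_all_excluded(self):
        mask = _blank(500, 800)
        for y in (100, 200, 300):
            mask[y : y + 4, 50:750] = True
        bp = _page_from_mask(mask)
        strokes = extract_strokes(bp, compute_curvature=False)
        angles = slant_angles(bp, compute_baseline(strokes), strokes)
        assert len(angles) == 0

    def test_rotation_equivariance(self):
        from skimage.transform import rotate

        prof = PageProfile(seed=4, slant_deg_mean=0.0, slant_deg_sd=0.0)
        page, _, _ = synth_page(prof, n_lines=4, strokes_per_line=12, dpi=300.0)
        bp0 = binarize_page(page)
        strokes0 = extract_strokes(bp0, compute_curvature=False)
        a0 = np.mean(slant_angles(bp0, compute_baseline(strokes0), strokes0).values)
        rot = rotate(page.pixels.astype(float), angle=-5.0, cval=235.0, resize=False)
        bp1 = binarize_page(PageImage(rot, page.dpi))
        strokes1 = extract_strokes(bp1, compute_curvature=False)
        # hold the baseline flat by construction: reuse the unrotated tracks
        baseline1 = compute_baseline(strokes1)
        for _ids, xs, ys in baseline1.per_line:
            ys[:] = ys.mean()
        a1 = np.mean(slant_angles(bp1, baseline1, strokes1).values)
        assert abs((a1 - a0) - 5.0) <= 1.0


class TestSizeFlags:
    def _grid_page(self, heights_per_line, gap=60, width=14, dpi=300.0):
        n_lines = len(heights_per_line)
        mask = _blank(500 * n_lines, 1200)
        for li, h in enumerate(heights_per_line):
            top = 150 + 500 * li
            for j in range(6):
                mask[top : top + int(h), 50 + gap * j : 50 + gap * j + width] = True
        return _page_from_mask(mask, dpi)

    def test_large_strokes_not_micrographia(self):
        page = self._grid_page([75, 75, 75])  # 5% of 1500 px page height
        strokes = extract_strokes(page)
        flags = size_flags(strokes, page)
        assert not flags.micrographia

    def test_declining_heights_progressive(self):
        page = self._grid_page([40, 30, 20])  # 50% decline
        flags = size_flags(extract_strokes(page), page)
        assert flags.progressive_micrographia

    def test_equal_gaps_not_spacing(self):
        page = self._grid_page([60, 60, 60])
        flags = size_flags(extract_strokes(page), page)
        assert not flags.spacing

    def test_under_three_strokes_undefined(self):
        mask = _blank()
        mask[100:150, 100:120] = True
        page = _page_from_mask(mask)
        flags = size_flags(extract_strokes(page), page)
        assert not flags.defined

    def test_flags_invariant_to_uniform_rescale(self, healthy_page):
        from skimage.transform import rescale

        page, _, _ = healthy_page
        bp1 = binarize_page(page)
        f1 = size_flags(extract_strokes(bp1), bp1)
        big = rescale(page.pixels.astype(float), 2.0, order=0)
        bp2 = binarize_page(PageImage(big, page.dpi * 2))
        f2 = size_flags(extract_strokes(bp2), bp2)
        for k in ("micrographia", "progressive_micrographia", "spacing"):
            assert getattr(f1, k) == getattr(f2, k)


class TestSeries:
    def test_identical_strokes_unit_series(self):
        mask = _blank()
        for j in range(8):
            mask[100:160, 50 + 60 * j : 62 + 60 * j] = True
        s = uniformity_series(extract_strokes(_page_from_mask(mask)))
        assert np.allclose(s.values, 1.0)

    def test_alternating_heights_around_median(self):
        mask = _blank(600, 900)
        for j in range(8):
            h = 40 if j % 2 == 0 else 80
            mask[300 - h : 300, 50 + 80 * j : 64 + 80 * j] = True
        s = uniformity_series(extract_strokes(_page_from_mask(mask)))
        assert np.allclose(np.sort(np.unique(s.values)), [40 / 60, 80 / 60])

    def test_monotone_shrinking_series_decreasing(self):
        mask = _blank(600, 1200)
        for j, h in enumerate(range(90, 30, -10)):
            mask[300 - h : 300, 50 + 120 * j : 70 + 120 * j] = True
        s = uniformity_series(extract_strokes(_page_from_mask(mask)))
        assert np.all(np.diff(s.values) < 0)

    def test_uniformity_median_one_on_any_page(self, healthy_page):
        page, _, _ = healthy_page
        s = uniformity_series(extract_strokes(binarize_page(page)))
        assert np.median(s.values) == pytest.approx(1.0)

    def test_straight_strokes_near_zero_residual(self):
        mask = _blank(600, 900)
        for j in range(6):
            mask[100:250, 50 + 80 * j : 54 + 80 * j] = True
        ts = tremor_series_writing(extract_strokes(_page_from_mask(mask)))
        assert np.all(ts.values < 0.1)

    def test_wobble_rms_and_linearity(self):
        def stave_rms(amp):
            prof = PageProfile(seed=5, tremor_amp_px=amp, tremor_freq=4.0,
                               slant_deg_sd=0.0)
            page, _, _ = synth_page(prof, 6, 15, 300.0)
            strokes = extract_strokes(binarize_page(page), compute_curvature=False)
            ts = tremor_series_writing(strokes, smooth_window=25)
            aspect = np.array([s.width_px / s.height_px for s in strokes.strokes])
            return ts.values[aspect < 0.45].mean()

        m1, m2 = stave_rms(1.5), stave_rms(3.0)
        assert abs(m1 - 1.5 / np.sqrt(2)) / (1.5 / np.sqrt(2)) <= 0.20
        assert abs(m2 / m1 - 2.0) <= 0.2
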