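"""Image-to-signal extraction: each stage's contract plus the round trip."""

import numpy as np
import pytest

from ecgfusion.digitize import (DigitizerConfig, NoTraceFoundError, binarize,
                                digitize, extract_trace, largest_contour,
                                to_grayscale)
from ecgfusion.synthetic import (ECGTrace, RenderSpec, make_dataset,
                                 render_image)


def matched_correlation(trace, digitized, render=RenderSpec()):
    """Pearson r between the ground truth (resampled to plot columns) and
    the digitized trace restricted to the plotting region."""
    m = render.margin
    cols = render.image_width - 2 * m
    x = trace.samples
    truth = np.interp(np.linspace(0, x.size - 1, cols), np.arange(x.size), x)
    return np.corrcoef(truth, digitized.samples[m:m + cols])[0, 1]


class TestGrayscale:
    def test_idempotent_on_single_channel(self):
        img = np.arange(12, dtype=np.uint8).reshape(3, 4)
        assert to_grayscale(img) is img

    @pytest.mark.parametrize("pixel,expected", [
        ((255, 255, 255), 255),   # weights sum to 1
        ((0, 255, 0), 150),       # 0.587 * 255 = 149.685, rounds to 150
        ((255, 0, 0), 76),        # 0.299 * 255 = 76.245
    ])
    def test_luminance_weights(self, pixel, expected):
        img = np.array([[pixel]], dtype=np.uint8)
        assert to_grayscale(img)[0, 0] == expected

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.empty((0, 0), dtype=np.uint8))


class TestBinarize:
    def test_uniform_image_all_background(self):
        assert binarize(np.full((64, 64), 140.0)).sum() == 0

    def test_polarity_symmetry(self, clean_image):
        cfg_dark = DigitizerConfig(trace_polarity="dark_on_light")
        cfg_light = DigitizerConfig(trace_polarity="light_on_dark")
        m1 = binarize(clean_image, cfg_dark)
        m2 = binarize(255.0 - clean_image, cfg_light)
        assert np.array_equal(m1, m2)

    def test_block_size_larger_than_image(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((16, 16)), DigitizerConfig(adaptive_block_size=31))

    def test_foreground_count_tracks_trace_thickness(self):
        """On a smooth slow trace the mask pixel count stays within +-50%
        of trace_thickness x image_width (steep strokes excluded by
        construction: a gentle 0.2 Hz sine)."""
        t = np.arange(1250) / 250
        trace = ECGTrace(0.5 * np.sin(2 * np.pi * 0.2 * t), 250.0)
        rs = RenderSpec(trace_thickness=3)
        img = render_image(trace, rs)
        count = binarize(to_grayscale(img)).sum()
        assert 0.5 * 3 * rs.image_width <= count <= 1.5 * 3 * rs.image_width

    @pytest.mark.parametrize("field,value", [
        ("blur_kernel", 4), ("blur_kernel", 1),
        ("adaptive_block_size", 10), ("column_reducer", "bogus"),
    ])
    def test_config_validation(self, field, value):
        with pytest.raises(ValueError):
            DigitizerConfig(**{field: value})


class TestLargestContour:
    def test_speck_removed(self):
        mask = np.zeros((20, 40), dtype=np.uint8)
        mask[10, 5:25] = 1            # 20-px line
        mask[2, 30:33] = 1            # 3-px speck
        out = largest_contour(mask)
        assert out.sum() == 20
        assert out[10, 5:25].all() and not out[2, 30:33].any()

    def test_tie_break_row_major(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[8, 0:3] = 1              # later in row-major order
        mask[1, 5:8] = 1              # earlier first pixel
        out = largest_contour(mask)
        assert out[1, 5:8].all() and not out[8, 0:3].any()

    def test_empty_mask_raises(self):
        with pytest.raises(NoTraceFoundError):
            largest_contour(np.zeros((5, 5), dtype=np.uint8))

    def test_diagonal_connectivity_is_8(self):
        mask = np.eye(6, dtype=np.uint8)
        assert largest_contour(mask).sum() == 6


class TestExtractTrace:
    def test_horizontal_line_coordinate_map(self):
        comp = np.zeros((50, 30), dtype=np.uint8)
        comp[12, :] = 1
        trace = extract_trace(comp)
        np.testing.assert_allclose(trace.samples, 50 - 1 - 12)

    def test_gap_linear_interpolation(self):
        comp = np.zeros((40, 3), dtype=np.uint8)
        comp[40 - 1 - 10, 0] = 1
        comp[40 - 1 - 12, 2] = 1
        trace = extract_trace(comp)
        np.testing.assert_allclose(trace.samples, [10, 11, 12])

    def test_gap_hold_last(self):
        comp = np.zeros((40, 3), dtype=np.uint8)
        comp[40 - 1 - 10, 0] = 1
        comp[40 - 1 - 12, 2] = 1
        cfg = DigitizerConfig(gap_fill="hold_last")
        np.testing.assert_allclose(extract_trace(comp, cfg).samples, [10, 10, 12])

    def test_sampling_rate_from_calibration(self):
        comp = np.ones((4, 8), dtype=np.uint8)
        assert extract_trace(comp, columns_per_second=125.0).sampling_rate == 125.0

    def test_empty_component_raises(self):
        with pytest.raises(NoTraceFoundError):
            extract_trace(np.zeros((5, 5), dtype=np.uint8))


class TestPipelineProperties:
    def test_round_trip_median_correlation(self):
        recs = make_dataset(6, seed=13)
        rs = [matched_correlation(r.trace, digitize(r.image)) for r in recs]
        assert np.median(rs) >= 0.95

    def test_determinism(self, clean_image):
        t1 = digitize(clean_image)
        t2 = digitize(clean_image)
        assert np.array_equal(t1.samples, t2.samples)

    def test_vertical_flip_negates_trace(self, clean_image):
        h = clean_image.shape[0]
        t = digitize(clean_image)
        t_flip = digitize(clean_image[::-1])
        np.testing.assert_allclose(t_flip.samples, (h - 1) - t.samples,
                                   atol=1.0)

    def test_speck_robustness(self, clean_image, rng):
        # specks disjoint from the trace and outside its local-mean
        # blocks (farther than the 31-px adaptive window)
        from scipy import ndimage

        base = binarize(to_grayscale(clean_image))
        far = ndimage.distance_transform_edt(1 - base) >= 24
        rows, cols = np.where(far)
        pick = rng.choice(rows.size, size=40, replace=False)
        noisy = clean_image.copy()
        noisy[rows[pick], cols[pick]] = 0
        np.testing.assert_array_equal(digitize(noisy).samples,
                                      digitize(clean_image).samples)
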