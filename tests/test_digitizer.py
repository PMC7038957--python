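"""Chart-image digitization: grid removal, scanning, trace extraction."""

import numpy as np
import pytest
from PIL import Image

from afscreen import digitizer as dig
from afscreen import signal as sig
from afscreen import synthetic as syn
from afscreen.core import ChartRenderConfig


def white_image(rows=40, cols=40, dpi=600.0):
    return dig.RasterImage(np.full((rows, cols, 3), 255, np.uint8), dpi)


class TestRasterize:
    def test_png_pixels_pass_through(self, tmp_path):
        arr = np.random.default_rng(0).integers(0, 255, (20, 30, 3)).astype(np.uint8)
        p = tmp_path / "img.png"
        Image.fromarray(arr).save(p)
        raster = dig.rasterize(p, dpi=600)
        assert np.array_equal(raster.pixels, arr)

    def test_dpi_metadata_wins(self, tmp_path):
        p = tmp_path / "img.png"
        Image.fromarray(np.zeros((5, 5, 3), np.uint8)).save(p, dpi=(300, 300))
        # PNG stores resolution as pixels/metre, so 300 dpi round-trips
        # with a small conversion error
        assert dig.rasterize(p, dpi=600).dpi == pytest.approx(300, abs=0.01)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            dig.rasterize(tmp_path / "absent.png")


class TestCrop:
    def test_identity_and_subregion(self):
        img = white_image(600, 600)
        assert dig.crop(img, (0, 0, 600, 600)).shape == (600, 600)
        assert dig.crop(img, (0, 0, 10, 10)).shape == (10, 10)

    @pytest.mark.parametrize("region", [(-1, 0, 5, 5), (0, 0, 700, 5), (5, 5, 0, 5)])
    def test_bad_regions(self, region):
        with pytest.raises(ValueError):
            dig.crop(white_image(), region)


class TestRemoveGrid:
    def test_pure_grid_becomes_white(self):
        img = dig.RasterImage(np.full((10, 10, 3), (255, 182, 193), np.uint8), 600)
        out = dig.remove_grid(img, (200, 100, 100), (255, 220, 220))
        assert np.all(out.pixels == 255)

    def test_trace_untouched(self, rendered_chart):
        img, cfg, *_ = rendered_chart
        raster = dig.RasterImage(img, cfg.dpi)
        out = dig.remove_grid(raster, (100, 100, 100), (255, 255, 255))
        nonwhite = np.any(out.pixels != 255, axis=2)
        trace = np.all(img == 0, axis=2)
        assert np.array_equal(nonwhite, trace)

    def test_empty_box_identity(self):
        img = dig.RasterImage(
            np.random.default_rng(1).integers(0, 200, (8, 8, 3)).astype(np.uint8), 600
        )
        out = dig.remove_grid(img, (250, 250, 250), (240, 240, 240))  # empty box
        assert np.array_equal(out.pixels, img.pixels)


class TestBinarize:
    def test_white_gives_empty_mask(self):
        assert not dig.binarize(white_image()).mask.any()

    def test_threshold_is_strict(self):
        img = dig.RasterImage(np.full((4, 4, 3), 128, np.uint8), 600)
        assert not dig.binarize(img, 128).mask.any()
        assert dig.binarize(img, 129).mask.all()

    def test_black_line_on_white(self):
        px = np.full((10, 10, 3), 255, np.uint8)
        px[4, :] = 0
        mask = dig.binarize(dig.RasterImage(px, 600)).mask
        assert mask[4].all() and mask.sum() == 10


class TestDespeckle:
    def test_small_blob_removed_large_kept(self):
        mask = np.zeros((200, 200), bool)
        mask[:10, :10] = True  # 100 px speck
        mask[50:100, 50:90] = True  # 2000 px blob
        out = dig.despeckle(dig.BinaryImage(mask, 600), min_area=1260)
        assert not out.mask[:10, :10].any()
        assert out.mask[50:100, 50:90].all()

    def test_exact_area_retained(self):
        mask = np.zeros((100, 100), bool)
        mask[10:45, 20:56] = True  # 35*36 = 1260 px exactly
        out = dig.despeckle(dig.BinaryImage(mask, 600), min_area=1260)
        assert out.mask.sum() == 1260

    def test_default_scales_with_dpi(self):
        mask = np.zeros((60, 60), bool)
        mask[10:30, 10:30] = True  # 400 px
        # at 300 dpi the default area is 1260/4 = 315 < 400 -> kept
        assert dig.despeckle(dig.BinaryImage(mask, 300.0)).mask.any()
        # at 600 dpi, 400 < 1260 -> removed
        assert not dig.despeckle(dig.BinaryImage(mask, 600.0)).mask.any()

    def test_empty_mask(self):
        out = dig.despeckle(dig.BinaryImage(np.zeros((5, 5), bool), 600))
        assert not out.mask.any()


class TestShrink:
    def test_zero_iterations_identity(self):
        mask = np.zeros((10, 10), bool)
        mask[4:6, 2:8] = True
        out = dig.shrink(dig.BinaryImage(mask, 600), 0)
        assert np.array_equal(out.mask, mask)

    def test_thick_line_thins_but_stays_connected(self):
        from scipy.ndimage import label

        mask = np.zeros((20, 40), bool)
        mask[8:13, 5:35] = True  # 5 px thick line
        out = dig.shrink(dig.BinaryImage(mask, 600), 2)
        assert out.mask.sum() < mask.sum()
        assert out.mask[:, 10].sum() <= mask[:, 10].sum()
        n_components = label(out.mask, structure=np.ones((3, 3)))[1]
        assert n_components == 1

    def test_never_adds_pixels(self):
        rng = np.random.default_rng(8)
        mask = rng.random((30, 30)) < 0.4
        out = dig.shrink(dig.BinaryImage(mask, 600), 2)
        assert not (out.mask & ~mask).any()

    def test_isolated_pixel_survives(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        assert dig.shrink(dig.BinaryImage(mask, 600), 3).mask[4, 4]


class TestVerticalScan:
    def test_paper_worked_record(self):
        """A span over rows 27-28 in column 12 yields the record (12, 27, 28)."""
        mask = np.zeros((50, 50), bool)
        mask[27:29, :] = True
        spans = dig.vertical_scan(dig.BinaryImage(mask, 600))
        assert (12, 27, 28) in spans.records
        assert len(spans.records) == 50

    def test_single_pixel_column(self):
        mask = np.zeros((10, 3), bool)
        mask[5, 1] = True
        spans = dig.vertical_scan(dig.BinaryImage(mask, 600))
        assert spans.records == [(1, 5, 5)]

    def test_blank_columns_skipped(self):
        mask = np.zeros((10, 5), bool)
        mask[3, 0] = mask[3, 4] = True
        spans = dig.vertical_scan(dig.BinaryImage(mask, 600))
        assert [r[0] for r in spans.records] == [0, 4]

    def test_disjoint_runs_follow_previous_trace(self):
        mask = np.zeros((30, 3), bool)
        mask[20, 0] = True  # trace at row 20
        mask[19:22, 1] = True
        mask[5, 2] = True  # residual grid remnant far away
        mask[21, 2] = True  # true trace continuation
        spans = dig.vertical_scan(dig.BinaryImage(mask, 600))
        assert spans.records[2] == (2, 21, 21)


class TestSpansToTrace:
    def test_flat_line_modal_thickness(self):
        spans = dig.ColumnSpans([(c, 27, 28) for c in range(20)])
        trace = dig.spans_to_trace(spans)
        assert trace.mu == 1
        assert np.all(trace.y == 28)

    def test_steep_column_takes_far_edge(self):
        spans = dig.ColumnSpans([(0, 39, 40), (1, 39, 40), (2, 39, 40), (3, 10, 40)])
        trace = dig.spans_to_trace(spans)
        assert trace.y[3] == 10  # |10-40| > |40-40|

    def test_single_column(self):
        trace = dig.spans_to_trace(dig.ColumnSpans([(4, 7, 9)]))
        assert trace.y.tolist() == [9.0]

    def test_empty_spans_error(self):
        with pytest.raises(ValueError):
            dig.spans_to_trace(dig.ColumnSpans([]))


class TestInterpolateGaps:
    def test_midpoint(self):
        t = dig.TraceVector(np.array([10.0, np.nan, 20.0]), mu=1)
        assert dig.interpolate_gaps(t).y.tolist() == [10.0, 15.0, 20.0]

    def test_no_gap_identity(self):
        t = dig.TraceVector(np.array([1.0, 2.0, 3.0]), mu=1)
        assert dig.interpolate_gaps(t).y.tolist() == [1.0, 2.0, 3.0]

    def test_edge_extension(self):
        t = dig.TraceVector(np.array([np.nan, 10.0, 20.0]), mu=1)
        assert dig.interpolate_gaps(t).y.tolist() == [10.0, 10.0, 20.0]

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            dig.interpolate_gaps(dig.TraceVector(np.array([np.nan, 5.0]), mu=1))


class TestTraceToSignal:
    def test_flat_trace_zero_signal(self):
        t = dig.TraceVector(np.full(100, 33.0), mu=1)
        out = dig.trace_to_signal(t, ChartRenderConfig(), target_rate=300)
        assert np.allclose(out.samples, 0.0)

    def test_unit_deflection_is_one_mv(self):
        cfg = ChartRenderConfig()
        px_per_mv = cfg.px_per_mv
        y = np.full(200, 100.0)
        y[:90] = 100.0 + px_per_mv  # half below: median row = 100
        t = dig.TraceVector(y, mu=1)
        out = dig.trace_to_signal(t, cfg, target_rate=cfg.px_per_second)
        assert out.samples.min() == pytest.approx(-1.0, abs=1e-6)

    def test_row_shift_only_offsets_signal(self):
        rng = np.random.default_rng(2)
        y = rng.integers(40, 60, 150).astype(float)
        cfg = ChartRenderConfig()
        a = dig.trace_to_signal(dig.TraceVector(y, mu=1), cfg)
        b = dig.trace_to_signal(dig.TraceVector(y + 7, mu=1), cfg)
        # same baseline convention (median shifts along) => identical signal
        assert np.allclose(a.samples, b.samples)

    def test_bad_rate(self):
        with pytest.raises(ValueError):
            dig.trace_to_signal(dig.TraceVector(np.ones(10), mu=1), target_rate=0)


class TestRoundTrip:
    def test_waveform_recovery(self, rendered_chart):
        img, cfg, signal, peaks, rr = rendered_chart
        raster = dig.RasterImage(img, cfg.dpi)
        rec = dig.digitize(raster, cfg)
        n = min(rec.samples.size, signal.samples.size)
        corr = np.corrcoef(rec.samples[:n], signal.samples[:n])[0, 1]
        assert corr >= 0.99

    def test_r_peak_columns_within_one(self, rendered_chart):
        img, cfg, signal, peaks, rr = rendered_chart
        raster = dig.RasterImage(img, cfg.dpi)
        rec = dig.digitize(raster, cfg, target_rate=cfg.px_per_second)
        found = sig.detect_r_peaks(rec)
        true_cols = np.round(
            peaks / signal.sampling_rate * cfg.px_per_second - 0.5
        ).astype(int)
        assert len(found) == len(true_cols)
        assert np.max(np.abs(found.indices - true_cols)) <= 1

    def test_pipeline_deterministic(self, rendered_chart):
        img, cfg, *_ = rendered_chart
        raster = dig.RasterImage(img, cfg.dpi)
        a = dig.digitize(raster, cfg)
        b = dig.digitize(raster, cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_rr_recovery_through_full_chain(self, rendered_chart):
        img, cfg, signal, peaks, rr = rendered_chart
        rec = dig.digitize(dig.RasterImage(img, cfg.dpi), cfg)
        found = sig.detect_r_peaks(sig.smooth(rec))
        recovered = sig.compute_rr(found)
        assert len(recovered) == len(rr)
        assert np.max(np.abs(recovered.values - rr.values)) <= 2 / rec.sampling_rate
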