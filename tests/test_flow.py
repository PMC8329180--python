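"""Flow quantification: arrival maps, lobule segmentation, widths, cycles."""

import numpy as np
import pytest

from ccflow import flow
from ccflow.errors import EmptySelectionError, NoUnitsError
from ccflow.subtraction import SubtractionParams, SubtractionStack


def _stack(frames, fps=15.0):
    frames = np.asarray(frames)
    ts = (1 + np.arange(len(frames))) / fps
    return SubtractionStack(
        frames=frames, params=SubtractionParams(), timestamps_s=ts, fps=fps
    )


class TestArrivalMap:
    def test_first_exceedance_time(self):
        frames = np.zeros((20, 4, 4), dtype=np.uint8)
        frames[12:, 1, 2] = 200  # first exceeds at frame index 12
        sub = _stack(frames)
        amap = flow.arrival_time_map(sub, 0.5)
        assert amap.arrival_s[1, 2] == pytest.approx(13 / 15)
        assert not np.isfinite(amap.arrival_s[0, 0])

    def test_all_dark_is_all_sentinel(self):
        frames = np.zeros((5, 4, 4), dtype=np.uint8)
        frames[0, 0, 0] = 100  # defines the max; threshold = 50
        sub = _stack(frames)
        amap = flow.arrival_time_map(sub, 0.5)
        assert amap.detected.sum() == 1

    def test_radial_correlation_on_simulation(self, reference_run):
        assert reference_run["report"].radial_spearman > 0.6


class TestSegmentation:
    @pytest.mark.parametrize("k", [1, 5, 12])
    def test_counts_separated_discs(self, k):
        rng = np.random.default_rng(k)
        frame = np.zeros((200, 200), dtype=np.uint8)
        yy, xx = np.indices(frame.shape)
        centers = [(30 + 50 * (i % 4), 30 + 50 * (i // 4)) for i in range(k)]
        for cx, cy in centers:
            frame[(yy - cy) ** 2 + (xx - cx) ** 2 < 15**2] = 200
        frame = frame + rng.integers(0, 10, frame.shape).astype(np.uint8)
        seg = flow.segment_functional_units(frame, 1000.0, 10.0)
        assert seg.n_units == k

    def test_constant_frame_raises(self):
        with pytest.raises(NoUnitsError):
            flow.segment_functional_units(np.zeros((32, 32), np.uint8), 100.0, 10.0)

    def test_zone_mask_disjoint_from_units(self):
        frame = np.zeros((64, 64), np.uint8)
        frame[10:30, 10:30] = 200
        seg = flow.segment_functional_units(frame, 100.0, 10.0)
        assert not np.any(seg.zone_mask & (seg.labels > 0))

    def test_unit_recovery_on_simulation(self, reference_run):
        report = reference_run["report"]
        n_art = reference_run["vmap"].n_arterioles
        assert abs(report.n_units - n_art) <= 0.2 * n_art
        assert report.frac_units_single_arteriole >= 0.8


class TestZoneWidths:
    @staticmethod
    def _two_blocks(gap_px):
        frame = np.zeros((60, 60), np.uint8)
        frame[5:55, 5:25] = 200
        frame[5:55, 25 + gap_px : 55] = 200
        return frame

    def test_straight_gap_width(self):
        pitch = 11.72
        seg = flow.segment_functional_units(self._two_blocks(10), 1000.0, pitch)
        stats = flow.measure_zone_widths(seg, pitch)
        assert abs(stats.median - 117.2) <= pitch

    def test_touching_blocks_give_empty_stats(self):
        pitch = 11.72
        with pytest.raises((EmptySelectionError, NoUnitsError)):
            seg = flow.segment_functional_units(self._two_blocks(0), 1000.0, pitch)
            flow.measure_zone_widths(seg, pitch)

    def test_rotation_invariance(self):
        pitch = 11.72
        frame = self._two_blocks(10)
        s1 = flow.measure_zone_widths(
            flow.segment_functional_units(frame, 1000.0, pitch), pitch
        )
        s2 = flow.measure_zone_widths(
            flow.segment_functional_units(np.rot90(frame), 1000.0, pitch), pitch
        )
        assert s1.median == pytest.approx(s2.median)

    def test_widths_scale_with_pixel_pitch(self):
        frame = self._two_blocks(8)
        seg = flow.segment_functional_units(frame, 100.0, 10.0)
        w1 = flow.measure_zone_widths(seg, 10.0)
        w2 = flow.measure_zone_widths(seg, 20.0)
        assert w2.median == pytest.approx(2 * w1.median)

    def test_percentiles_ordered(self, reference_run):
        r = reference_run["report"]
        assert 0 < r.zone_width_p5_um <= r.zone_width_median_um <= r.zone_width_p95_um


class TestOverlay:
    def test_equal_frames_equal_channels(self):
        f = np.arange(16, dtype=np.uint8).reshape(4, 4)
        out = flow.overlay_consecutive(f, f)
        assert np.array_equal(out[..., 0], out[..., 2])
        assert out[..., 1].sum() == 0

    def test_disjoint_sets_stay_disjoint(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0, 0] = 255
        b[3, 3] = 255
        out = flow.overlay_consecutive(a, b)
        red = (out[..., 0] > 0) & (out[..., 2] == 0)
        blue = (out[..., 2] > 0) & (out[..., 0] == 0)
        assert red[0, 0] and blue[3, 3] and not np.any(red & blue)

    def test_blue_pixels_fill_later_than_red(self, reference_run):
        """Slow (blue) regions have later true arrival than fast (red) ones."""
        sub = reference_run["sub"]
        seq = reference_run["sequence"]
        idx = reference_run["report"].segmented_frame_index
        a, b = sub.frames[idx], sub.frames[idx + 3]
        arr = seq.ground_truth["arrival_s"]
        red = (a > 128) & (b < 64)
        blue = (b > 128) & (a < 64)
        if red.sum() > 50 and blue.sum() > 50:
            fin = np.isfinite(arr)
            assert arr[blue & fin].mean() > arr[red & fin].mean()


class TestCycles:
    def test_monotone_trace_has_no_peaks(self):
        frames = np.linspace(0, 200, 30)[:, None, None] * np.ones((1, 8, 8))
        sub = _stack(frames.astype(np.uint8))
        trace = flow.count_filling_cycles(sub, (0, 0, 8, 8), 0.1)
        assert trace.n_cycles == 0

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_recovers_k_periods(self, k):
        t = np.linspace(0, k, 40 * k, endpoint=False)
        value = 100 + 90 * np.sin(2 * np.pi * t - np.pi / 2)
        frames = np.tile(value[:, None, None], (1, 6, 6)).astype(np.uint8)
        trace = flow.count_filling_cycles(_stack(frames), (0, 0, 6, 6), 0.3)
        assert trace.n_cycles == k

    def test_preset_counts_three_cycles(self, reference_run):
        assert reference_run["report"].n_cycles == 3
        assert np.all(np.diff(reference_run["report"].cycle_times_s) > 0)

    def test_degenerate_roi_rejected(self):
        frames = np.zeros((10, 8, 8), np.uint8)
        with pytest.raises(ValueError):
            flow.count_filling_cycles(_stack(frames), (0, 0, 0, 4), 0.1)


class TestRadialWave:
    @staticmethod
    def _map_from(arr):
        return flow.ArrivalMap(arrival_s=arr, threshold=1.0)

    def test_arrival_equal_distance_is_plus_one(self):
        yy, xx = np.indices((50, 50))
        dist = np.hypot(xx + 20, yy - 25.0)
        rho = flow.radial_wave_stat(self._map_from(dist.copy()), (-20.0, 25.0))
        assert rho == pytest.approx(1.0)

    def test_arrival_negative_distance_is_minus_one(self):
        yy, xx = np.indices((50, 50))
        dist = np.hypot(xx + 20, yy - 25.0)
        rho = flow.radial_wave_stat(self._map_from(-dist), (-20.0, 25.0))
        assert rho == pytest.approx(-1.0)

    def test_shuffled_arrivals_uncorrelated(self):
        rng = np.random.default_rng(0)
        arr = rng.permutation(np.arange(10000.0)).reshape(100, 100)
        rho = flow.radial_wave_stat(self._map_from(arr), (-30.0, 50.0))
        assert abs(rho) < 0.1

    def test_too_few_detections_raises(self):
        arr = np.full((20, 20), np.inf)
        arr[0, :5] = 1.0
        with pytest.raises(EmptySelectionError):
            flow.radial_wave_stat(self._map_from(arr), (0.0, 0.0))
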