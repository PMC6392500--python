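"""Tests of ROI quantification: decile background, tracking, ratio, calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormquant.calcium import (
    Roi,
    TwoChannelStack,
    call_response,
    compute_ratio_trace,
    roi_fluorescence,
    track_roi,
)
from wormquant.errors import BaselineError, ParameterError, TrackingLostError
from wormquant.synthetic import StackParams, gen_image_stack, linear_drift_path

from conftest import gaussian_frame, static_cell_stack


def brute_force_fluorescence(pixels: np.ndarray) -> float:
    """Independent oracle: explicit sort, explicit decile mean, full-area subtraction."""
    flat = sorted(pixels.ravel().tolist())
    n = len(flat)
    k = max(1, int(np.floor(0.10 * n)))
    bg = sum(flat[:k]) / k
    return sum(flat) - n * bg


class TestRoiFluorescence:
    def test_uniform_roi_is_zero(self):
        frame = np.full((30, 30), 37.5)
        roi = Roi(center=(15, 15), half_height=4, half_width=4)
        assert roi_fluorescence(frame, roi) == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_roi_is_zero(self):
        frame = np.zeros((30, 30))
        roi = Roi(center=(15, 15), half_height=4, half_width=4)
        assert roi_fluorescence(frame, roi) == 0.0

    def test_worked_decile_example(self):
        # 100-pixel ROI: 90 pixels at 110, 10 at 10 -> k=10, bg=10, F=9000
        vals = np.array([110.0] * 90 + [10.0] * 10)
        np.random.default_rng(1).shuffle(vals)
        frame = np.zeros((20, 20))
        frame[5:15, 5:15] = vals.reshape(10, 10)
        roi = Roi(center=(9.5, 9.5), half_height=5, half_width=5)
        assert roi.n_pixels == 100
        assert roi_fluorescence(frame, roi) == pytest.approx(9000.0)

    def test_literal_mode_subtracts_only_decile_sum(self):
        vals = np.array([110.0] * 90 + [10.0] * 10)
        frame = np.zeros((20, 20))
        frame[5:15, 5:15] = vals.reshape(10, 10)
        roi = Roi(center=(9.5, 9.5), half_height=5, half_width=5)
        # sum = 10000, decile sum = 100 -> F = 9900
        assert roi_fluorescence(frame, roi, mode="literal") == pytest.approx(9900.0)

    def test_matches_brute_force_oracle_on_random_rois(self):
        rng = np.random.default_rng(2024)
        frame_shape = (60, 60)
        for _ in range(250):
            frame = rng.gamma(2.0, 40.0, frame_shape)
            hh = rng.integers(2, 8)
            hw = rng.integers(2, 8)
            if (2 * hh + 1) * (2 * hw + 1) < 10:
                continue
            r = rng.uniform(hh + 1, frame_shape[0] - hh - 2)
            c = rng.uniform(hw + 1, frame_shape[1] - hw - 2)
            roi = Roi(center=(r, c), half_height=hh, half_width=hw)
            pixels = frame[roi.slices(frame_shape)]
            assert roi_fluorescence(frame, roi) == pytest.approx(
                brute_force_fluorescence(pixels), rel=1e-12
            )

    @given(offset=st.floats(min_value=-50, max_value=500))
    @settings(max_examples=30, deadline=None)
    def test_offset_invariance(self, offset):
        # adding a constant to every pixel leaves F unchanged
        rng = np.random.default_rng(7)
        frame = rng.gamma(2.0, 40.0, (30, 30))
        roi = Roi(center=(14.2, 15.8), half_height=5, half_width=4)
        f0 = roi_fluorescence(frame, roi)
        f1 = roi_fluorescence(frame + offset, roi)
        assert f1 == pytest.approx(f0, abs=1e-6 * max(1.0, abs(f0)))

    def test_tiny_roi_rejected(self):
        with pytest.raises(ParameterError):
            Roi(center=(5, 5), half_height=1, half_width=1)


class TestTrackRoi:
    def test_stationary_symmetric_spot(self, gaussian_spot_stack):
        roi = Roi(center=(20, 20), half_height=6, half_width=6)
        path = track_roi(gaussian_spot_stack, roi)
        centers = np.array([r.center for r in path])
        assert np.max(np.abs(centers - 20.0)) < 0.05

    def test_two_symmetric_lobes_centroid_at_midpoint(self):
        frame = (
            gaussian_frame((41, 41), (20.0, 16.0), sigma=2.0)
            + gaussian_frame((41, 41), (20.0, 24.0), sigma=2.0)
        )
        frames = np.stack([frame] * 3)
        stack = TwoChannelStack(cyan=frames, yellow=frames, frame_rate=10.0)
        path = track_roi(stack, Roi(center=(20, 20), half_height=8, half_width=8))
        assert path[-1].center[0] == pytest.approx(20.0, abs=0.05)
        assert path[-1].center[1] == pytest.approx(20.0, abs=0.05)

    def test_recovers_linear_drift(self):
        n = 100
        params = StackParams(
            duration=10.0, image_shape=(64, 64),
            cell_path=linear_drift_path(n, (10.0, 12.0), (0.3, 0.4)),
        )
        stack, truth = gen_image_stack(params, seed=21)
        roi = Roi(center=tuple(truth.centroid_path[0]), half_height=6, half_width=6)
        path = track_roi(stack, roi)
        centers = np.array([r.center for r in path])
        rms = np.sqrt(np.mean(np.sum((centers - truth.centroid_path) ** 2, axis=1)))
        assert rms < 0.5

    def test_tracking_lost_on_black_frames(self):
        frames = np.zeros((5, 32, 32))
        stack = TwoChannelStack(cyan=frames, yellow=frames, frame_rate=10.0)
        with pytest.raises(TrackingLostError) as err:
            track_roi(stack, Roi(center=(16, 16), half_height=4, half_width=4))
        assert err.value.frame == 1

    def test_roi_dimensions_constant_along_path(self):
        n = 50
        params = StackParams(
            duration=5.0, transient_onset=2.0, image_shape=(64, 64),
            cell_path=linear_drift_path(n, (20.0, 20.0), (0.37, 0.11)),
        )
        stack, truth = gen_image_stack(params, seed=8)
        path = track_roi(stack, Roi(center=(20, 20), half_height=5.5, half_width=6))
        shapes = {r.block_shape for r in path}
        assert len(shapes) == 1


class TestComputeRatioTrace:
    def test_constant_channels_give_zero_drr0(self, flat_stack, center_roi):
        trace = compute_ratio_trace(flat_stack, [center_roi] * flat_stack.n_frames)
        assert np.allclose(np.nan_to_num(trace.dRR0), 0.0, atol=1e-9)

    def test_baseline_averages_exactly_30_frames_at_10hz(self):
        # R varies frame by frame; R0 must be the mean of frames 0..29
        rng = np.random.default_rng(5)
        n = 60
        scale = 1.0 + 0.05 * rng.standard_normal(n)
        stack = static_cell_stack(n, yellow_scale=scale)
        roi = Roi(center=(15.5, 15.5), half_height=5, half_width=5)
        trace = compute_ratio_trace(stack, [roi] * n, baseline_window=3.0)
        assert trace.baseline_frames == 30
        assert trace.R0 == pytest.approx(np.mean(trace.R[:30]), rel=1e-12)

    def test_hand_arithmetic_bleed_through_example(self):
        # raw F_yellow=100, F_cyan=50, alpha=0.5 -> corrected 75, R=1.5
        f_y_raw, f_c, alpha = 100.0, 50.0, 0.5
        corrected = f_y_raw - alpha * f_c
        assert corrected == pytest.approx(75.0)
        r = corrected / f_c
        assert r == pytest.approx(1.5)
        r0 = 1.0
        assert 100.0 * (r - r0) / r0 == pytest.approx(50.0)

    def test_alpha_correction_in_trace(self, flat_stack, center_roi):
        path = [center_roi] * flat_stack.n_frames
        t0 = compute_ratio_trace(flat_stack, path, alpha=0.0)
        t5 = compute_ratio_trace(flat_stack, path, alpha=0.5)
        np.testing.assert_allclose(t5.F_yellow, t0.F_yellow - 0.5 * t0.F_cyan)

    def test_scaling_both_channels_leaves_ratio_unchanged(self):
        params = StackParams(duration=5.0, transient_onset=2.0, transient_peak_dRR0=20.0)
        stack, _ = gen_image_stack(params, seed=3)
        roi = Roi(center=(31.5, 31.5), half_height=6, half_width=6)
        path = track_roi(stack, roi)
        t1 = compute_ratio_trace(stack, path)
        scaled = TwoChannelStack(
            cyan=stack.cyan * 3.7, yellow=stack.yellow * 3.7, frame_rate=stack.frame_rate
        )
        t2 = compute_ratio_trace(scaled, path)
        np.testing.assert_allclose(t2.R, t1.R, rtol=1e-9)
        np.testing.assert_allclose(t2.dRR0, t1.dRR0, rtol=1e-7, atol=1e-9)

    def test_zero_cyan_in_baseline_raises(self):
        cyan = np.zeros((40, 32, 32))
        yellow = np.full((40, 32, 32), 10.0)
        stack = TwoChannelStack(cyan=cyan, yellow=yellow, frame_rate=10.0)
        roi = Roi(center=(15.5, 15.5), half_height=5, half_width=5)
        with pytest.raises(BaselineError):
            compute_ratio_trace(stack, [roi] * 40)


class TestCallResponse:
    def _flat_trace(self, n=300):
        stack = static_cell_stack(n)
        roi = Roi(center=(15.5, 15.5), half_height=5, half_width=5)
        return compute_ratio_trace(stack, [roi] * n)

    def test_flat_trace_is_nonresponder(self):
        call = call_response(self._flat_trace(), stimulus_onset=10.0, stimulus_kind="buzz")
        assert not call.responder
        assert call.peak_dRR0 == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("kind,duration", [("press", 1.0), ("buzz", 3.7)])
    def test_stimulus_durations_recorded(self, kind, duration):
        call = call_response(self._flat_trace(), stimulus_onset=10.0, stimulus_kind=kind)
        assert call.stimulus_duration == duration

    def test_synthetic_transient_recovered(self):
        params = StackParams(transient_peak_dRR0=30.0)
        stack, truth = gen_image_stack(params, seed=17)
        roi = Roi(center=tuple(truth.centroid_path[0]), half_height=6, half_width=6)
        trace = compute_ratio_trace(stack, track_roi(stack, roi))
        call = call_response(trace, stimulus_onset=10.0, stimulus_kind="buzz")
        assert call.responder
        assert call.sigma_base < 2.0
        assert call.peak_dRR0 == pytest.approx(truth.dRR0.max(), rel=0.10)

    def test_window_truncation_warns(self):
        trace = self._flat_trace(n=120)  # 12 s recording
        with pytest.warns(UserWarning, match="truncated"):
            call = call_response(trace, stimulus_onset=10.0, stimulus_kind="buzz")
        assert call.response_window[1] == pytest.approx(12.0)

    def test_onset_before_baseline_rejected(self):
        with pytest.raises(ParameterError):
            call_response(self._flat_trace(), stimulus_onset=1.0, stimulus_kind="press")
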