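"""FRET pipeline: ratio computation, two-point calibration, Delta% series,
protocol metrics, and saturation QC."""

import numpy as np
import pytest

from oscilact.errors import CalibrationError, InputError, ParameterError
from oscilact.fret import (
    calibrate_two_point,
    compute_ratio,
    delta_percent,
    qc_exclude_saturated,
    roi_mean_trace,
    stimulation_metrics,
    transport_stop_metrics,
)
from oscilact.simulate import (
    FretSimParams,
    gen_fret_trace,
    occupancy,
    stimulation_protocol,
    transport_stop_protocol,
)
from oscilact.traces import CalibrationResult, FretTrace


def make_trace(ratio, bg=20.0, fret_level=200.0, dt=1.0):
    ratio = np.asarray(ratio, dtype=float)
    return FretTrace(
        time=np.arange(ratio.size) * dt,
        mtfp=ratio * fret_level + bg,
        fret=np.full(ratio.size, fret_level + bg),
        background_mtfp=bg,
        background_fret=bg,
    )


class TestRoiMeanTrace:
    def test_uniform_roi_and_background(self):
        stack = np.full((5, 4, 4), 10.0)
        roi = np.zeros((4, 4), bool)
        bg = np.zeros((4, 4), bool)
        roi[:2] = True
        bg[3:] = True
        stack[:, roi] = 100.0
        roi_trace, bg_trace = roi_mean_trace(stack, roi, bg)
        np.testing.assert_allclose(roi_trace, 100.0)
        np.testing.assert_allclose(bg_trace, 10.0)

    def test_single_pixel_roi_returns_its_time_course(self):
        stack = np.arange(3 * 2 * 2, dtype=float).reshape(3, 2, 2)
        roi = np.zeros((2, 2), bool)
        roi[0, 1] = True
        bg = np.zeros((2, 2), bool)
        bg[1, 1] = True
        roi_trace, _ = roi_mean_trace(stack, roi, bg)
        np.testing.assert_allclose(roi_trace, stack[:, 0, 1])

    def test_checkerboard_roi_averages(self):
        stack = np.zeros((2, 4, 4))
        checker = np.zeros((4, 4), bool)
        checker[::2, ::2] = True
        checker[1::2, 1::2] = True
        checker[3, 3] = False
        # alternate {0, 200} over the roi pixels in raster order
        coords = np.argwhere(checker)
        for i, (r, c) in enumerate(coords):
            stack[:, r, c] = 200.0 if i % 2 == 0 else 0.0
        bg = np.zeros((4, 4), bool)
        bg[3, 3] = True
        roi_trace, _ = roi_mean_trace(stack, checker, bg)
        expected = 200.0 * np.ceil(len(coords) / 2) / len(coords)
        np.testing.assert_allclose(roi_trace, expected)

    def test_overlapping_masks_rejected(self):
        stack = np.zeros((2, 3, 3))
        mask = np.ones((3, 3), bool)
        with pytest.raises(ParameterError):
            roi_mean_trace(stack, mask, mask)


class TestComputeRatio:
    def test_background_subtracted_arithmetic(self):
        trace = FretTrace(
            time=[0.0], mtfp=[120.0], fret=[220.0], background_mtfp=20.0, background_fret=20.0
        )
        compute_ratio(trace)
        assert trace.ratio[0] == pytest.approx(0.5)

    def test_nonpositive_denominator_flagged_not_dropped(self):
        trace = FretTrace(
            time=[0.0, 1.0], mtfp=[120.0, 120.0], fret=[220.0, 20.0],
            background_mtfp=20.0, background_fret=20.0,
        )
        compute_ratio(trace)
        assert trace.valid.tolist() == [True, False]
        assert np.isnan(trace.ratio[1]) and trace.ratio.size == 2

    def test_all_invalid_raises(self):
        trace = FretTrace(time=[0.0], mtfp=[5.0], fret=[5.0],
                          background_mtfp=0.0, background_fret=10.0)
        with pytest.raises(InputError):
            compute_ratio(trace)

    def test_joint_rescaling_invariance(self, rng):
        ratio = 1.0 + 0.1 * rng.random(50)
        t1 = make_trace(ratio)
        c = 7.3
        t2 = FretTrace(
            time=t1.time, mtfp=c * t1.mtfp, fret=c * t1.fret,
            background_mtfp=c * 20.0, background_fret=c * 20.0,
        )
        np.testing.assert_allclose(compute_ratio(t2).ratio, compute_ratio(t1).ratio, rtol=1e-12)


class TestCalibration:
    def test_noiseless_piecewise_constant_is_exact(self):
        ratio = np.concatenate([np.full(100, 1.2), np.full(100, 1.0)])
        trace = make_trace(ratio)
        cal = calibrate_two_point(trace, (0.0, 100.0), (100.0, 200.0))
        assert (cal.r_max, cal.r_min) == (pytest.approx(1.2), pytest.approx(1.0))
        assert cal.dynamic_range_pct == pytest.approx(20.0)

    def test_swapped_windows_raise(self):
        ratio = np.concatenate([np.full(100, 1.2), np.full(100, 1.0)])
        with pytest.raises(CalibrationError):
            calibrate_two_point(make_trace(ratio), (100.0, 200.0), (0.0, 100.0))

    def test_overlapping_windows_rejected(self):
        trace = make_trace(np.ones(100) * 1.1)
        with pytest.raises(ParameterError):
            calibrate_two_point(trace, (0.0, 60.0), (50.0, 100.0))

    def test_recovered_dynamic_range_near_generated(self, calibration_run):
        assert calibration_run["cal"].dynamic_range_pct == pytest.approx(20.0, abs=1.0)

    def test_idempotence(self, calibration_run):
        trace = calibration_run["trace"]
        a = calibrate_two_point(trace, (120.0, 390.0), (390.0, 660.0))
        b = calibrate_two_point(trace, (120.0, 390.0), (390.0, 660.0))
        assert (a.r_max, a.r_min) == (b.r_max, b.r_min)


class TestDeltaPercent:
    def setup_method(self):
        self.cal = CalibrationResult(r_max=1.2, r_min=1.0)

    def test_ratio_at_rmin_is_zero(self):
        d = delta_percent(make_trace(np.ones(10)), self.cal)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_ratio_at_rmax_equals_dynamic_range(self):
        d = delta_percent(make_trace(np.full(10, 1.2)), self.cal)
        np.testing.assert_allclose(d, self.cal.dynamic_range_pct, rtol=1e-12)

    def test_linearity_in_ratio(self, rng):
        r1, r2 = 1.0 + 0.2 * rng.random(30), 1.0 + 0.2 * rng.random(30)
        d_mean = delta_percent(make_trace((r1 + r2) / 2), self.cal)
        mean_d = (delta_percent(make_trace(r1), self.cal) + delta_percent(make_trace(r2), self.cal)) / 2
        np.testing.assert_allclose(d_mean, mean_d, rtol=1e-9)

    def test_end_to_end_occupancy_recovery(self, calibration_run):
        """Delta% of the calibrated trace tracks the generator's ground-truth
        occupancy curve within a noise-scaled bound."""
        run = calibration_run
        params, cal = run["params"], run["cal"]
        d = delta_percent(run["trace"], cal)
        theta = occupancy(run["lactate"], params.kd)
        predicted = 100.0 * (params.r_min + (params.r_max - params.r_min) * theta - cal.r_min) / cal.r_min
        noise_bound = 100.0 * 6 * params.noise_sd / params.r_min + 0.2
        assert np.max(np.abs(d - predicted)) < noise_bound


class TestTransportStop:
    def test_first_order_rise_closed_form(self):
        """time-to-90% of a first-order rise is tau*ln(10) ~ 2.303*tau:
        tau = 52 s gives ~120 s, i.e. saturation in about two minutes."""
        t = np.arange(0.0, 520.0, 1.0)
        tau = 52.0
        dpct = np.where(t >= 60.0, 2.0 * (1.0 - np.exp(-(t - 60.0) / tau)), 0.0)
        m = transport_stop_metrics(t, dpct, 60.0)
        assert m["time_to_90pct"] == pytest.approx(tau * np.log(10.0), abs=2.0)
        assert m["saturated"]

    def test_generator_rise_near_closed_form(self):
        params = FretSimParams(
            protocol=transport_stop_protocol(plateau_drive=0.12),
            rise_tau=52.0, noise_sd=0.0, seed=2,
        )
        trace, _ = gen_fret_trace(params)
        cal = CalibrationResult(r_max=params.r_max, r_min=params.r_min)
        m = transport_stop_metrics(trace.time, delta_percent(trace, cal), 120.0)
        # the saturable sensor readout slightly compresses the rise
        assert m["time_to_90pct"] == pytest.approx(2.303 * 52.0, rel=0.15)
        assert m["saturated"] and m["plateau_delta"] > 0

    def test_flat_trace_has_zero_plateau(self):
        t = np.arange(0.0, 300.0, 1.0)
        m = transport_stop_metrics(t, np.zeros_like(t), 100.0)
        assert m["plateau_delta"] == pytest.approx(0.0)

    def test_step_reaches_90pct_immediately(self):
        t = np.arange(0.0, 300.0, 1.0)
        dpct = np.where(t >= 100.0, 5.0, 0.0)
        m = transport_stop_metrics(t, dpct, 100.0, smooth_frames=1)
        assert m["time_to_90pct"] == pytest.approx(0.0)

    def test_still_rising_flagged_unsaturated(self):
        t = np.arange(0.0, 200.0, 1.0)
        dpct = np.where(t >= 100.0, 0.1 * (t - 100.0), 0.0)  # linear ramp, no plateau
        m = transport_stop_metrics(t, dpct, 100.0)
        assert not m["saturated"]

    def test_insufficient_post_onset_data_rejected(self):
        t = np.arange(0.0, 120.0, 1.0)
        with pytest.raises(InputError):
            transport_stop_metrics(t, np.zeros_like(t), 100.0)


class TestStimulation:
    def test_transient_orders_timepoints(self):
        params = FretSimParams(protocol=stimulation_protocol(), seed=3)
        trace, _ = gen_fret_trace(params)
        cal = CalibrationResult(r_max=params.r_max, r_min=params.r_min)
        vals = stimulation_metrics(trace.time, delta_percent(trace, cal), 120.0)
        assert vals[20.0] > vals[60.0] > vals[120.0]
        assert vals[20.0] == pytest.approx(2.0, abs=1.0)  # ~2 Delta% transient

    def test_flat_trace_gives_zeros(self):
        t = np.arange(0.0, 300.0, 1.0)
        vals = stimulation_metrics(t, np.zeros_like(t), 120.0)
        assert all(v == pytest.approx(0.0) for v in vals.values())

    def test_timepoint_zero_is_zero_by_construction(self):
        t = np.arange(0.0, 300.0, 1.0)
        vals = stimulation_metrics(t, np.sin(t / 10), 120.0, timepoints=(0.0,))
        assert vals[0.0] == 0.0

    def test_timepoint_beyond_trace_rejected(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(ParameterError):
            stimulation_metrics(t, np.zeros_like(t), 90.0, timepoints=(60.0,))


class TestSaturationQC:
    def setup_method(self):
        self.cal = CalibrationResult(r_max=1.2, r_min=1.0)

    @pytest.mark.parametrize(
        "baseline_ratio,excluded",
        [(1.0, False), (1.2, True), (1.0 + 0.9 * 0.2, False)],  # boundary: strict inequality
        ids=["at-rmin", "at-rmax", "exact-boundary"],
    )
    def test_exclusion_rule(self, baseline_ratio, excluded):
        trace = make_trace(np.full(50, baseline_ratio))
        assert qc_exclude_saturated(trace, self.cal, (0.0, 50.0)) is excluded
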