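"""Laconic FRET lactate-trace analysis.

Turns two-channel (mTFP, FRET) fluorescence intensities into the
background-subtracted mTFP/FRET ratio, calibrates the sensor with the
two-point lactate-saturation / pyruvate-depletion protocol, and expresses
traces as Delta% relative to the calibration minimum:

    Delta%(t) = 100 * (R(t) - r_min) / r_min

The Delta% convention (division by r_min) is declared in every output.
Protocol metrics cover the transport-stop experiment (plateau rise after
MCT1/2 blockade) and electrical field stimulation (Delta% at fixed
timepoints after stimulus onset).
"""

from __future__ import annotations

import numpy as np

from .errors import CalibrationError, InputError, ParameterError
from .traces import CalibrationResult, FretTrace

__all__ = [
    "roi_mean_trace",
    "compute_ratio",
    "calibrate_two_point",
    "delta_percent",
    "transport_stop_metrics",
    "stimulation_metrics",
    "qc_exclude_saturated",
]

DELTA_PCT_CONVENTION = "100*(R - r_min)/r_min"


def roi_mean_trace(
    stack: np.ndarray, roi: np.ndarray, background_roi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean intensity over a pixel mask and a background mask.

    ``stack`` is a (n_frames, height, width) grayscale image sequence for
    one channel; masks are boolean (height, width) arrays and must be
    non-empty and non-overlapping. Returns ``(roi_trace, background_trace)``.
    """
    stack = np.asarray(stack, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    background_roi = np.asarray(background_roi, dtype=bool)
    if stack.ndim != 3:
        raise ParameterError("stack must be a (frames, height, width) array")
    if roi.shape != stack.shape[1:] or background_roi.shape != stack.shape[1:]:
        raise ParameterError("mask shape must match frame shape")
    if not roi.any() or not background_roi.any():
        raise ParameterError("roi and background_roi must be non-empty")
    if (roi & background_roi).any():
        raise ParameterError("roi and background_roi must not overlap")
    return stack[:, roi].mean(axis=1), stack[:, background_roi].mean(axis=1)


def compute_ratio(trace: FretTrace) -> FretTrace:
    """Populate ``trace.ratio`` = (mtfp - bg_mtfp) / (fret - bg_fret).

    Frames with a non-positive denominator are flagged invalid in
    ``trace.valid`` (ratio NaN there), never dropped silently. Raises if
    every frame is invalid.
    """
    mtfp_net = trace.mtfp - np.asarray(trace.background_mtfp, dtype=float)
    fret_net = trace.fret - np.asarray(trace.background_fret, dtype=float)
    valid = fret_net > 0
    if not valid.any():
        raise InputError("all frames have non-positive background-subtracted FRET intensity")
    ratio = np.full(trace.n_frames, np.nan)
    ratio[valid] = mtfp_net[valid] / fret_net[valid]
    trace.ratio = ratio
    trace.valid = valid
    return trace


def _require_ratio(trace: FretTrace) -> np.ndarray:
    if trace.ratio is None:
        compute_ratio(trace)
    return trace.ratio


def _running_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centred running median; edges keep the raw values."""
    if window <= 1 or values.size < window:
        return values
    from scipy.ndimage import median_filter

    out = median_filter(values, size=window, mode="nearest")
    return out


def _window_values(time: np.ndarray, values: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    sel = (time >= window[0]) & (time < window[1])
    if not sel.any():
        raise ParameterError(f"window {window} contains no frames")
    return values[sel]


def calibrate_two_point(
    trace: FretTrace,
    lactate_window: tuple[float, float],
    pyruvate_window: tuple[float, float],
) -> CalibrationResult:
    """Two-point calibration from a lactate-then-pyruvate superfusion trace.

    ``r_max`` is the robust plateau (median of the final third) of the ratio
    inside ``lactate_window`` (sensor saturation), ``r_min`` the same inside
    ``pyruvate_window`` (lactate depletion by transacceleration). Raises
    :class:`CalibrationError` when r_max <= r_min — swapped windows or an
    unresponsive sensor.
    """
    if max(lactate_window[0], pyruvate_window[0]) < min(lactate_window[1], pyruvate_window[1]):
        raise ParameterError("lactate and pyruvate windows must not overlap")
    ratio = _require_ratio(trace)

    def plateau(window):
        vals = _window_values(trace.time, ratio, window)
        tail = vals[-max(len(vals) // 3, 1):]
        return float(np.nanmedian(tail))

    r_max, r_min = plateau(lactate_window), plateau(pyruvate_window)
    if not r_max > r_min:
        raise CalibrationError(
            f"r_max ({r_max:.4f}) <= r_min ({r_min:.4f}): windows swapped or sensor unresponsive"
        )
    return CalibrationResult(r_max=r_max, r_min=r_min)


def delta_percent(trace: FretTrace, cal: CalibrationResult) -> np.ndarray:
    """Delta% time series: 100 * (ratio - r_min) / r_min."""
    ratio = _require_ratio(trace)
    return 100.0 * (ratio - cal.r_min) / cal.r_min


def transport_stop_metrics(
    time: np.ndarray,
    dpct: np.ndarray,
    drug_onset: float,
    baseline_duration: float = 60.0,
    plateau_fraction: float = 0.2,
    slope_tolerance: float = 0.01,
    smooth_frames: int = 5,
) -> dict:
    """Plateau rise and time-to-90% for a transport-stop Delta% series.

    Baseline is the median of ``baseline_duration`` s before ``drug_onset``;
    the plateau is the median of the final ``plateau_fraction`` of the
    post-onset window. ``time_to_90pct`` (s from onset) is the first time
    the series exceeds baseline + 0.9 * plateau_delta, evaluated on a
    ``smooth_frames``-frame running median so frame noise does not trigger
    the crossing early. ``saturated`` is False when the signal is still
    rising at the window end (tail slope above ``slope_tolerance`` Delta%/s).
    """
    time = np.asarray(time, dtype=float)
    dpct = _running_median(np.asarray(dpct, dtype=float), smooth_frames)
    post = time >= drug_onset
    if not post.any() or time[post][-1] - drug_onset < 60.0:
        raise InputError("transport-stop metrics need >= 60 s of post-onset data")

    baseline = float(
        np.nanmedian(_window_values(time, dpct, (drug_onset - baseline_duration, drug_onset)))
    )
    t_post, y_post = time[post], dpct[post]
    n_tail = max(int(round(plateau_fraction * t_post.size)), 1)
    plateau = float(np.nanmedian(y_post[-n_tail:]))
    plateau_delta = plateau - baseline

    tail_t, tail_y = t_post[-n_tail:], y_post[-n_tail:]
    slope = float(np.polyfit(tail_t, tail_y, 1)[0]) if n_tail >= 2 else 0.0
    saturated = abs(slope) <= slope_tolerance

    crossed = np.flatnonzero(y_post >= baseline + 0.9 * plateau_delta)
    time_to_90 = float(t_post[crossed[0]] - drug_onset) if crossed.size else float("nan")

    return {
        "baseline_dpct": baseline,
        "plateau_delta": plateau_delta,
        "time_to_90pct": time_to_90,
        "saturated": saturated,
        "tail_slope": slope,
    }


def stimulation_metrics(
    time: np.ndarray,
    dpct: np.ndarray,
    stim_onset: float,
    timepoints: tuple[float, ...] = (20.0, 60.0, 120.0),
    baseline_duration: float = 60.0,
) -> dict[float, float]:
    """Baseline-subtracted Delta% at fixed delays after stimulation onset.

    Each value is read at the frame nearest ``stim_onset + delay`` after a
    3-frame running-median smoothing; the pre-stimulus baseline (median of
    ``baseline_duration`` s before onset) is subtracted. ``timepoint 0``
    is 0 by construction of the baseline subtraction only when the trace is
    flat; in general it reads the onset frame.
    """
    time = np.asarray(time, dtype=float)
    dpct = np.asarray(dpct, dtype=float)
    if time.size and max(timepoints, default=0.0) + stim_onset > time[-1]:
        raise ParameterError("requested timepoint lies beyond the trace")

    smoothed = _running_median(dpct, 3)

    baseline = float(
        np.nanmedian(_window_values(time, smoothed, (stim_onset - baseline_duration, stim_onset)))
    )
    out = {}
    for tp in timepoints:
        k = int(np.argmin(np.abs(time - (stim_onset + tp))))
        out[float(tp)] = float(smoothed[k] - baseline) if tp > 0 else 0.0
    return out


def qc_exclude_saturated(
    trace: FretTrace,
    cal_reference: CalibrationResult,
    baseline_window: tuple[float, float],
    fraction: float = 0.9,
) -> bool:
    """True (exclude) iff the baseline median ratio exceeds
    r_min + fraction*(r_max - r_min), strictly. Neurons whose sensor is
    already near saturation before any intervention carry no usable signal.
    """
    ratio = _require_ratio(trace)
    baseline = float(np.nanmedian(_window_values(trace.time, ratio, baseline_window)))
    threshold = cal_reference.r_min + fraction * (cal_reference.r_max - cal_reference.r_min)
    return baseline > threshold
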