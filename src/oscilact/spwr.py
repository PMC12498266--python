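"""Sharp wave-ripple detection and quantification.

The raw trace is split into a slow sharp-wave component (< 45 Hz, FFT
low-pass) used for event detection and amplitude, and a fast ripple
component (120-400 Hz, FFT band-pass) from which a per-event ripple
frequency is estimated. Detection thresholds are relative (robust SD of
the slow trace), so the pipeline is equivariant under amplitude rescaling.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .errors import InputError, ParameterError
from .filters import fft_filter
from .traces import LFPRecording, SPWREvent, SPWRSummary

__all__ = ["fft_filter", "detect_sharp_waves", "measure_ripple_frequency", "analyze_spwr"]

logger = logging.getLogger(__name__)

LOWPASS_CUT = 45.0  # Hz, sharp-wave component
RIPPLE_BAND = (120.0, 400.0)  # Hz
EVENT_HALF_WINDOW = 0.05  # s either side of the peak


def detect_sharp_waves(
    slow: LFPRecording,
    threshold_sd: float = 4.0,
    min_interval: float = 0.03,
) -> list[SPWREvent]:
    """Detect sharp-wave events on the low-pass (< 45 Hz) component.

    A candidate is a local maximum of the absolute deflection from the trace
    median exceeding ``threshold_sd`` robust standard deviations
    (1.4826 x median absolute deviation). Peaks closer than ``min_interval``
    are merged keeping the larger; events within 50 ms of either trace edge
    are discarded (incomplete windows). Amplitude is |peak - median| in mV.
    """
    x = slow.samples
    if x.size == 0:
        return []
    med = float(np.median(x))
    robust_sd = 1.4826 * float(np.median(np.abs(x - med)))
    if robust_sd == 0:
        logger.warning("zero-variance trace: no sharp-wave detection possible")
        return []

    deviation = np.abs(x - med)
    distance = max(int(round(min_interval * slow.sampling_rate)), 1)
    peaks, _ = signal.find_peaks(deviation, height=threshold_sd * robust_sd, distance=distance)

    events = []
    margin = EVENT_HALF_WINDOW
    for k in peaks:
        t = slow.start_time + k / slow.sampling_rate
        if t - slow.start_time < margin or (slow.start_time + slow.duration) - t < margin:
            continue
        events.append(
            SPWREvent(
                peak_time=t,
                amplitude=float(deviation[k]),
                window=(t - EVENT_HALF_WINDOW, t + EVENT_HALF_WINDOW),
            )
        )
    return events


def _window_slice(rec: LFPRecording, window: tuple[float, float]) -> np.ndarray:
    i0 = int(round((window[0] - rec.start_time) * rec.sampling_rate))
    i1 = int(round((window[1] - rec.start_time) * rec.sampling_rate))
    if i0 < 0 or i1 > rec.n_samples:
        raise ParameterError(f"event window {window} lies outside the recording")
    return rec.samples[i0:i1]


def ripple_band_baseline(ripple: LFPRecording, events: list[SPWREvent]) -> float:
    """Mean square of the ripple-band trace over event-free stretches."""
    mask = np.ones(ripple.n_samples, dtype=bool)
    for ev in events:
        i0 = max(int(round((ev.window[0] - ripple.start_time) * ripple.sampling_rate)), 0)
        i1 = min(int(round((ev.window[1] - ripple.start_time) * ripple.sampling_rate)), ripple.n_samples)
        mask[i0:i1] = False
    if not mask.any():  # recording saturated with events; fall back to global power
        mask[:] = True
    return float(np.mean(ripple.samples[mask] ** 2))


def measure_ripple_frequency(
    ripple: LFPRecording,
    event: SPWREvent,
    baseline_power: float | None = None,
    power_gate: float = 2.0,
) -> float | None:
    """Ripple frequency (Hz) of one event, or None if ripple power is too low.

    Within the event window, a Hann-windowed periodogram of the 120-400 Hz
    component is computed; the peak bin inside the ripple band is refined by
    parabolic interpolation. The estimate is returned only when the
    window's ripple-band mean square power is at least ``power_gate`` times
    ``baseline_power`` (event-free power; gate skipped when None).
    """
    seg = _window_slice(ripple, event.window)
    if seg.size < 8:
        return None
    if baseline_power is not None:
        if float(np.mean(seg**2)) < power_gate * baseline_power:
            return None

    win = np.hanning(seg.size)
    spectrum = np.abs(np.fft.rfft((seg - seg.mean()) * win)) ** 2
    freqs = np.fft.rfftfreq(seg.size, d=1.0 / ripple.sampling_rate)
    in_band = np.flatnonzero((freqs >= RIPPLE_BAND[0]) & (freqs <= RIPPLE_BAND[1]))
    if in_band.size == 0:
        return None
    k = in_band[np.argmax(spectrum[in_band])]

    # parabolic interpolation around the maximum bin for sub-bin precision
    if 0 < k < spectrum.size - 1:
        a, b, c = spectrum[k - 1], spectrum[k], spectrum[k + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df = freqs[1] - freqs[0]
    return float(freqs[k] + delta * df)


def analyze_spwr(
    rec: LFPRecording,
    threshold_sd: float = 4.0,
    min_interval: float = 0.03,
    power_gate: float = 2.0,
) -> tuple[list[SPWREvent], SPWRSummary]:
    """Full sharp wave-ripple analysis of one recording.

    Composes the component split (45 Hz low-pass / 120-400 Hz band-pass FFT
    filters), sharp-wave detection, and per-event ripple-frequency
    measurement. ``duration_analyzed`` is the full trace duration.
    """
    if rec.duration < 10:
        raise InputError(f"recording lasts {rec.duration:.1f} s; SPW-R analysis needs >= 10 s")

    slow = fft_filter(rec, "lowpass", LOWPASS_CUT)
    ripple = fft_filter(rec, "bandpass", RIPPLE_BAND)

    events = detect_sharp_waves(slow, threshold_sd=threshold_sd, min_interval=min_interval)
    baseline = ripple_band_baseline(ripple, events) if events else None
    for ev in events:
        ev.ripple_frequency = measure_ripple_frequency(
            ripple, ev, baseline_power=baseline, power_gate=power_gate
        )

    ripple_freqs = [ev.ripple_frequency for ev in events if ev.ripple_frequency is not None]
    summary = SPWRSummary(
        n_events=len(events),
        incidence=len(events) / rec.duration,
        mean_amplitude=float(np.mean([ev.amplitude for ev in events])) if events else float("nan"),
        mean_ripple_frequency=float(np.mean(ripple_freqs)) if ripple_freqs else float("nan"),
        duration_analyzed=rec.duration,
        params={
            "threshold_sd": threshold_sd,
            "min_interval_s": min_interval,
            "lowpass_cut_hz": LOWPASS_CUT,
            "ripple_band_hz": list(RIPPLE_BAND),
            "power_gate": power_gate,
        },
    )
    return events, summary
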