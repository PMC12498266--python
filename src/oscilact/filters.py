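"""Zero-phase filters shared by the oscillation pipelines.

Two families are used: an IIR Butterworth applied forward-backward for
broadband conditioning of gamma recordings, and frequency-domain (FFT mask)
filters with raised-cosine transition bands for the sharp wave / ripple
component split, where an ideal brick-wall mask would ring.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import ParameterError
from .traces import LFPRecording

__all__ = ["lowpass_butterworth", "fft_filter"]


def lowpass_butterworth(rec: LFPRecording, corner: float = 200.0, order: int = 4) -> LFPRecording:
    """Zero-phase low-pass Butterworth filter (default 200 Hz corner, order 4).

    Applied forward-backward (``sosfiltfilt``) so event timing is preserved;
    the effective magnitude response is the squared one-pass response.
    """
    nyq = rec.sampling_rate / 2.0
    if not 0 < corner < nyq:
        raise ParameterError(f"corner frequency {corner} Hz must lie in (0, {nyq}) Hz")
    sos = signal.butter(order, corner, btype="low", fs=rec.sampling_rate, output="sos")
    return rec.with_samples(signal.sosfiltfilt(sos, rec.samples))


def _raised_cosine_mask(freqs: np.ndarray, kind: str, edges: tuple, transition: float) -> np.ndarray:
    """Frequency-domain gain with cosine ramps of half-width ``transition`` Hz
    centred on each edge."""

    def ramp_up(f, edge):
        # 0 below edge-transition, 1 above edge+transition
        x = np.clip((f - (edge - transition)) / (2 * transition), 0.0, 1.0)
        return 0.5 * (1 - np.cos(np.pi * x))

    if kind == "lowpass":
        (cut,) = edges
        return 1.0 - ramp_up(freqs, cut)
    if kind == "highpass":
        (cut,) = edges
        return ramp_up(freqs, cut)
    if kind == "bandpass":
        lo, hi = edges
        return ramp_up(freqs, lo) * (1.0 - ramp_up(freqs, hi))
    raise ParameterError(f"unknown filter kind {kind!r}")


def fft_filter(
    rec: LFPRecording,
    kind: str,
    edges: float | tuple[float, float],
    transition: float = 5.0,
) -> LFPRecording:
    """Zero-phase FFT filter with raised-cosine transitions.

    Parameters
    ----------
    kind : {"lowpass", "highpass", "bandpass"}
    edges : float or (float, float)
        Cut frequency (lowpass/highpass) or pass-band edges (bandpass), Hz.
    transition : float
        Half-width of the cosine transition band in Hz (default 5). A hard
        mask rings; the ramp confines edge artefacts to ~2x this width.
    """
    edges_t = (float(edges),) if np.isscalar(edges) else tuple(float(e) for e in edges)
    nyq = rec.sampling_rate / 2.0
    for e in edges_t:
        if not 0 < e < nyq:
            raise ParameterError(f"filter edge {e} Hz must lie in (0, {nyq}) Hz")
    if kind == "bandpass":
        if len(edges_t) != 2 or not edges_t[0] < edges_t[1]:
            raise ParameterError("bandpass requires edges (low, high) with low < high")
    elif len(edges_t) != 1:
        raise ParameterError(f"{kind} takes a single cut frequency")

    spectrum = np.fft.rfft(rec.samples)
    freqs = np.fft.rfftfreq(rec.n_samples, d=1.0 / rec.sampling_rate)
    spectrum *= _raised_cosine_mask(freqs, kind, edges_t, transition)
    return rec.with_samples(np.fft.irfft(spectrum, n=rec.n_samples))
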