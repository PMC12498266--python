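"""Synthetic LFP and Laconic FRET traces with known ground truth.

Every analysis stage in the package is validated by parameter recovery on
these generators, so their structure mirrors the signals the pipelines are
built for:

* gamma oscillations — a phase-diffusion oscillator on a 1/f background.
  Amplitude and phase jitter are independent knobs for spectral peak power
  and line width (FWHM), matching the interpretation that power tracks the
  number/synchrony of postsynaptic currents while FWHM tracks jitter in
  their timing. A Wiener phase with diffusion rate D (rad^2/s) yields a
  Lorentzian line of FWHM = D/(2*pi) Hz and an autocorrelation envelope
  decaying with time constant 2/D s.
* sharp wave-ripples — a refractory-thinned Poisson train of
  Gaussian-envelope deflections carrying an envelope-windowed ripple
  sinusoid (~250 Hz).
* Laconic traces — intracellular lactate relaxing first-order toward each
  protocol segment's drive level, read out through a single-site saturable
  sensor R = r_min + (r_max - r_min) * L/(L + kd).

All generators are pure functions of their parameters; the integer ``seed``
fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .traces import FretTrace, LFPRecording

__all__ = [
    "GammaSimParams",
    "SPWRSimParams",
    "FretSimParams",
    "gen_gamma_lfp",
    "gen_spwr_lfp",
    "gen_nonoscillatory_lfp",
    "gen_fret_trace",
    "calibration_protocol",
    "transport_stop_protocol",
    "stimulation_protocol",
]


def pink_noise(n: int, sampling_rate: float, noise_sd: float, rng: np.random.Generator,
               slope: float = -1.0) -> np.ndarray:
    """1/f-shaped Gaussian noise with exact standard deviation ``noise_sd``.

    White noise is shaped in the frequency domain by |f|^(slope/2) (power
    spectral slope ``slope``); the DC bin is zeroed and the result rescaled
    to the requested SD.
    """
    if noise_sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (slope / 2.0)
    out = np.fft.irfft(spec * shape, n=n)
    sd = out.std()
    return out * (noise_sd / sd) if sd > 0 else out


# ---------------------------------------------------------------------------
# gamma


@dataclass(frozen=True)
class GammaSimParams:
    """Phase-diffusion gamma oscillation on a pink-noise background.

    Defaults emulate a cholinergically induced ~40 Hz oscillation recorded
    at 10 kHz: phase_jitter 20 rad^2/s gives a Lorentzian FWHM of
    20/(2*pi) ~ 3.2 Hz, in the few-Hz range typical of slice gamma.
    """

    duration: float = 300.0  # s
    sampling_rate: float = 10000.0  # Hz
    center_frequency: float = 40.0  # Hz
    amplitude: float = 0.1  # mV
    phase_jitter: float = 20.0  # rad^2/s phase-diffusion rate
    noise_sd: float = 0.05  # mV of 1/f background
    seed: int = 0

    def __post_init__(self):
        if min(self.amplitude, self.phase_jitter, self.noise_sd) < 0:
            raise ParameterError("amplitudes and rates must be >= 0")
        if not self.center_frequency < self.sampling_rate / 2:
            raise ParameterError("center_frequency must be below Nyquist")
        if self.duration < 1.0:
            raise ParameterError("duration must be >= 1 s")


def gen_gamma_lfp(params: GammaSimParams) -> LFPRecording:
    """Simulate a gamma-band LFP: amplitude * cos(phi(t)) + 1/f background,
    where dphi = 2*pi*f0*dt + Wiener increments of variance phase_jitter*dt."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sampling_rate))
    dt = 1.0 / params.sampling_rate
    dphi = 2 * np.pi * params.center_frequency * dt + rng.normal(
        0.0, np.sqrt(params.phase_jitter * dt), n
    )
    phase = np.cumsum(dphi)
    samples = params.amplitude * np.cos(phase)
    samples += pink_noise(n, params.sampling_rate, params.noise_sd, rng)
    return LFPRecording(samples, params.sampling_rate, label="sim-gamma")


def gen_nonoscillatory_lfp(
    duration: float, sampling_rate: float, noise_sd: float, seed: int
) -> LFPRecording:
    """Pink-noise-only control trace (no oscillatory component)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    return LFPRecording(
        pink_noise(n, sampling_rate, noise_sd, rng), sampling_rate, label="sim-control"
    )


# ---------------------------------------------------------------------------
# sharp wave-ripples


@dataclass(frozen=True)
class SPWRSimParams:
    """Poisson sharp wave-ripple train.

    ``incidence`` is the realized (post-refractory) event rate: candidates
    are drawn at the dead-time-corrected rate incidence/(1 - incidence *
    refractory) and pairs closer than ``refractory`` thinned, so a 3/s
    setting yields about 3 detected-able events per second, as in acute
    slice recordings.
    """

    duration: float = 300.0  # s
    sampling_rate: float = 10000.0  # Hz
    incidence: float = 3.0  # events/s
    sharp_wave_amplitude: float = 0.3  # mV
    sharp_wave_width: float = 0.05  # s, envelope FWHM
    ripple_frequency: float = 250.0  # Hz
    ripple_amplitude: float = 0.06  # mV
    refractory: float = 0.05  # s
    noise_sd: float = 0.02  # mV
    seed: int = 0

    def __post_init__(self):
        if self.incidence < 0 or self.refractory < 0 or self.noise_sd < 0:
            raise ParameterError("rates and amplitudes must be >= 0")
        if not 120 < self.ripple_frequency < 400:
            raise ParameterError("ripple_frequency must lie in (120, 400) Hz")
        if self.duration < 10:
            raise ParameterError("duration must be >= 10 s")
        if self.incidence * self.refractory >= 1:
            raise ParameterError("incidence * refractory must be < 1")


def gen_spwr_lfp(params: SPWRSimParams) -> tuple[LFPRecording, np.ndarray]:
    """Simulate a sharp wave-ripple train; returns (recording, true event times).

    Each event is a Gaussian-envelope sharp wave (peak
    ``sharp_wave_amplitude``, envelope FWHM ``sharp_wave_width``) plus the
    same envelope windowing a sinusoid at ``ripple_frequency``.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sampling_rate))
    t = np.arange(n) / params.sampling_rate

    event_times = np.empty(0)
    if params.incidence > 0:
        # dead-time-corrected candidate rate so the thinned rate == incidence
        lam = params.incidence / (1.0 - params.incidence * params.refractory)
        n_cand = rng.poisson(lam * params.duration)
        cand = np.sort(rng.uniform(0.0, params.duration, n_cand))
        kept = []
        last = -np.inf
        for tc in cand:
            if tc - last >= params.refractory:
                kept.append(tc)
                last = tc
        # events too close to the edges would have truncated waveforms
        margin = 2 * params.sharp_wave_width
        event_times = np.array([tk for tk in kept if margin < tk < params.duration - margin])

    samples = pink_noise(n, params.sampling_rate, params.noise_sd, rng)
    sigma = params.sharp_wave_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(round(4 * sigma * params.sampling_rate))
    tt = np.arange(-half, half + 1) / params.sampling_rate
    envelope = np.exp(-0.5 * (tt / sigma) ** 2)
    ripple = envelope * np.sin(2 * np.pi * params.ripple_frequency * tt)
    waveform = params.sharp_wave_amplitude * envelope + params.ripple_amplitude * ripple
    for tk in event_times:
        k = int(round(tk * params.sampling_rate))
        lo, hi = k - half, k + half + 1
        samples[max(lo, 0) : min(hi, n)] += waveform[max(lo, 0) - lo : len(tt) - (hi - min(hi, n))]

    return LFPRecording(samples, params.sampling_rate, label="sim-spwr"), event_times


# ---------------------------------------------------------------------------
# Laconic FRET


@dataclass(frozen=True)
class FretSimParams:
    """Laconic sensor trace through a superfusion protocol.

    ``protocol`` is an ordered list of ``(label, duration_s, drive_mM)``
    segments; the intracellular lactate level relaxes first-order toward
    each segment's drive (``rise_tau`` up, ``decay_tau`` down). The sensor
    is single-site saturable with half-saturation ``kd``; ratio bounds
    ``r_min``/``r_max`` default to a 20 Delta% dynamic range.
    """

    r_min: float = 1.0
    r_max: float = 1.2
    kd: float = 0.2  # mM half-saturation of the sensor readout
    baseline_lactate: float = 0.08  # mM resting intracellular lactate
    protocol: tuple[tuple[str, float, float], ...] = ()
    rise_tau: float = 20.0  # s
    decay_tau: float = 15.0  # s; depletion by transacceleration is fast
    noise_sd: float = 0.001  # ratio units
    frame_interval: float = 1.0  # s
    seed: int = 0

    def __post_init__(self):
        if not (self.r_max > self.r_min > 0):
            raise ParameterError("require r_max > r_min > 0")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ParameterError("time constants must be > 0")
        if not self.protocol:
            raise ParameterError("protocol must be non-empty")
        for seg in self.protocol:
            if len(seg) != 3 or seg[1] <= 0:
                raise ParameterError(f"malformed protocol segment {seg!r}")


def occupancy(lactate: np.ndarray | float, kd: float) -> np.ndarray | float:
    """Fractional sensor occupancy L/(L + kd)."""
    lac = np.asarray(lactate, dtype=float)
    return lac / (lac + kd)


def gen_fret_trace(params: FretSimParams) -> tuple[FretTrace, np.ndarray]:
    """Simulate a two-channel Laconic trace; returns (trace, lactate(t) in mM).

    Channel intensities are synthesized so that background-subtracted
    mTFP/FRET reproduces the noisy sensor ratio exactly: the FRET channel is
    held constant and the mTFP channel carries the ratio.
    """
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval

    drives, times = [], []
    t_cursor = 0.0
    for _, seg_dur, drive in params.protocol:
        n_seg = int(round(seg_dur / dt))
        drives.extend([float(drive)] * n_seg)
        times.extend(t_cursor + dt * np.arange(n_seg))
        t_cursor += n_seg * dt
    drives = np.asarray(drives)
    time = np.asarray(times)

    lactate = np.empty_like(drives)
    level = params.baseline_lactate
    for i, target in enumerate(drives):
        tau = params.rise_tau if target > level else params.decay_tau
        level += (target - level) * (1.0 - np.exp(-dt / tau))
        lactate[i] = level

    ratio = params.r_min + (params.r_max - params.r_min) * occupancy(lactate, params.kd)
    ratio = ratio + rng.normal(0.0, params.noise_sd, ratio.size)

    bg_mtfp, bg_fret, fret_level = 20.0, 20.0, 200.0
    fret_net = np.full_like(ratio, fret_level)
    trace = FretTrace(
        time=time,
        mtfp=ratio * fret_net + bg_mtfp,
        fret=fret_net + bg_fret,
        background_mtfp=bg_mtfp,
        background_fret=bg_fret,
        label="sim-fret",
    )
    return trace, lactate


def calibration_protocol(
    glucose_duration: float = 120.0,
    lactate_duration: float = 270.0,
    pyruvate_duration: float = 270.0,
    lactate_drive: float = 10.0,
    baseline_drive: float = 0.08,
) -> tuple[tuple[str, float, float], ...]:
    """Two-point calibration: glucose baseline, then saturating lactate
    (10 mM superfusion drives the sensor to ~98% occupancy at kd 0.2 mM),
    then pyruvate, whose transacceleration depletes intracellular lactate
    (drive 0)."""
    return (
        ("glucose", glucose_duration, baseline_drive),
        ("lactate", lactate_duration, lactate_drive),
        ("pyruvate", pyruvate_duration, 0.0),
    )


def transport_stop_protocol(
    baseline_duration: float = 120.0,
    blocker_duration: float = 420.0,
    plateau_drive: float = 0.8,
    baseline_drive: float = 0.08,
) -> tuple[tuple[str, float, float], ...]:
    """MCT1/2 transport stop: baseline in glucose, then blocker application
    under which exported lactate accumulates toward a plateau."""
    return (
        ("glucose", baseline_duration, baseline_drive),
        ("blocker", blocker_duration, plateau_drive),
    )


def stimulation_protocol(
    baseline_duration: float = 120.0,
    stim_duration: float = 10.0,
    post_duration: float = 200.0,
    stim_drive: float = 0.22,
    baseline_drive: float = 0.08,
) -> tuple[tuple[str, float, float], ...]:
    """Electrical field stimulation (10 s train): a brief rise in lactate
    production followed by relaxation back to baseline."""
    return (
        ("glucose", baseline_duration, baseline_drive),
        ("stim", stim_duration, stim_drive),
        ("post", post_duration, baseline_drive),
    )
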