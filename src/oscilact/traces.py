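"""Core data types for LFP and FRET time series and their analysis results.

Unit conventions, fixed throughout the package: extracellular potentials in
mV, time in s, frequency in Hz, spectral density in mV^2/Hz, fluorescence
intensities in arbitrary units (A.U.). Traces are uniformly sampled; the
first sample sits at ``start_time`` and a segment ``[t0, t0 + T)`` is
half-open so adjacent segments never share a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError

__all__ = [
    "LFPRecording",
    "FretTrace",
    "SpectralEstimate",
    "AcfFitResult",
    "GammaMetrics",
    "SPWREvent",
    "SPWRSummary",
    "ContingencyTable2x2",
    "CalibrationResult",
]


@dataclass
class LFPRecording:
    """A uniformly sampled extracellular local field potential trace.

    Parameters
    ----------
    samples : ndarray
        Potential values in mV. Must be finite.
    sampling_rate : float
        Sampling frequency in Hz (default 10000, i.e. the 10 kHz
        digitization rate typical of interface-chamber LFP recordings).
    temperature : float, optional
        Bath temperature in deg C, carried as metadata only.
    label : str
        Free-text condition tag, e.g. ``"Glc"`` or ``"Glc + AR-C"``.
    start_time : float
        Time of the first sample in s.
    """

    samples: np.ndarray
    sampling_rate: float = 10000.0
    temperature: float | None = None
    label: str = ""
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ParameterError("samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise ParameterError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise InputError(f"non-finite sample at index {bad}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Trace duration in s (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in s."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def segment(self, t0: float, t1: float) -> "LFPRecording":
        """Return the half-open time slice ``[t0, t1)`` relative to start_time."""
        i0 = int(np.ceil(round(t0 * self.sampling_rate, 9)))
        i1 = int(np.ceil(round(t1 * self.sampling_rate, 9)))
        i0, i1 = max(i0, 0), min(i1, self.n_samples)
        return LFPRecording(
            self.samples[i0:i1],
            sampling_rate=self.sampling_rate,
            temperature=self.temperature,
            label=self.label,
            start_time=self.start_time + i0 / self.sampling_rate,
        )

    def with_samples(self, samples: np.ndarray) -> "LFPRecording":
        """Copy of this recording with ``samples`` replaced (same metadata)."""
        return LFPRecording(
            samples,
            sampling_rate=self.sampling_rate,
            temperature=self.temperature,
            label=self.label,
            start_time=self.start_time,
        )


@dataclass
class FretTrace:
    """Two-channel Laconic fluorescence intensity trace.

    The sensor readout is the mTFP/FRET intensity ratio after background
    subtraction; ``ratio`` is ``None`` until :func:`oscilact.fret.compute_ratio`
    populates it. Backgrounds may be scalars or per-frame arrays.
    """

    time: np.ndarray
    mtfp: np.ndarray
    fret: np.ndarray
    background_mtfp: float | np.ndarray = 0.0
    background_fret: float | np.ndarray = 0.0
    label: str = ""
    ratio: np.ndarray | None = None
    valid: np.ndarray | None = None  # per-frame flag, False where ratio undefined

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.mtfp = np.asarray(self.mtfp, dtype=float)
        self.fret = np.asarray(self.fret, dtype=float)
        if not (self.time.shape == self.mtfp.shape == self.fret.shape):
            raise ParameterError("time, mtfp and fret must have equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            bad = int(np.flatnonzero(np.diff(self.time) <= 0)[0]) + 1
            raise InputError(f"time must be strictly increasing; violation at index {bad}")

    @property
    def n_frames(self) -> int:
        return int(self.time.size)


@dataclass
class SpectralEstimate:
    """One-sided Welch power spectral density with exact bin geometry.

    ``bin_width`` equals ``sampling_rate / window_length`` exactly, so a
    10 kHz recording analysed with an 8192-point window yields the canonical
    1.220703125 Hz bin. ``frequencies[k] == k * bin_width``.
    """

    frequencies: np.ndarray
    power: np.ndarray
    bin_width: float
    window_length: int
    sampling_rate: float

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ParameterError("frequencies and power must have equal length")
        if self.bin_width != self.sampling_rate / self.window_length:
            raise ParameterError("bin_width must equal sampling_rate / window_length")

    def band_indices(self, low: float, high: float) -> np.ndarray:
        """Indices of bins with ``low <= f <= high``."""
        return np.flatnonzero((self.frequencies >= low) & (self.frequencies <= high))


@dataclass
class AcfFitResult:
    """Damped-cosine fit to the autocorrelation of one 30-s segment.

    The fitted model is ``r(tau) = amplitude * exp(-tau/decay_time) *
    cos(2*pi*oscillation_frequency*tau)``; ``goodness`` is the coefficient of
    determination of the fit and ``accepted`` records whether the segment
    counts as oscillatory under the configured criteria.
    """

    segment_index: int
    converged: bool
    amplitude: float = float("nan")
    decay_time: float = float("nan")  # s
    oscillation_frequency: float = float("nan")  # Hz
    goodness: float = float("nan")
    accepted: bool = False


@dataclass
class GammaMetrics:
    """Spectral metrics plus the segment-wise presence verdict for one recording.

    ``present`` is True iff at least ``min_accepted_segments`` of the ten 30-s
    segments yield an accepted autocorrelation-decay fit and the spectral peak
    lies at or above ``frequency_threshold_hz``. ``fwhm`` is NaN when a
    half-maximum flank is never crossed inside the search band
    (``fwhm_defined`` False).
    """

    peak_frequency: float  # Hz
    peak_power: float  # mV^2/Hz
    fwhm: float  # Hz, NaN if undefined
    fwhm_defined: bool
    present: bool
    segment_fits: list[AcfFitResult]
    n_accepted_segments: int
    params: dict = field(default_factory=dict)  # thresholds used, logged verbatim


@dataclass
class SPWREvent:
    """A single detected sharp wave-ripple event.

    ``amplitude`` is the magnitude of the sharp-wave deflection from the trace
    median (mV, always positive by convention); ``ripple_frequency`` is None
    when ripple-band power inside the window fails the power gate.
    """

    peak_time: float  # s
    amplitude: float  # mV
    window: tuple[float, float]  # [start, end] s
    ripple_frequency: float | None = None

    def __post_init__(self):
        lo, hi = self.window
        if not (lo <= self.peak_time <= hi):
            raise ParameterError("event window must contain peak_time")
        if not self.amplitude > 0:
            raise ParameterError("amplitude must be > 0 (magnitude convention)")


@dataclass
class SPWRSummary:
    """Recording-level sharp wave-ripple statistics."""

    n_events: int
    incidence: float  # events/s
    mean_amplitude: float  # mV
    mean_ripple_frequency: float  # Hz, NaN if no event passed the ripple gate
    duration_analyzed: float  # s
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of positive/negative outcomes in two independent groups.

    Example: slices exhibiting gamma oscillations (positive) versus not,
    under two superfusion conditions.
    """

    group1_positive: int
    group1_negative: int
    group2_positive: int
    group2_negative: int

    def __post_init__(self):
        cells = self.as_tuple()
        if any(c < 0 or c != int(c) for c in cells):
            raise ParameterError("cell counts must be non-negative integers")
        if sum(cells) == 0:
            raise ParameterError("table must contain at least one observation")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.group1_positive,
            self.group1_negative,
            self.group2_positive,
            self.group2_negative,
        )

    @property
    def total(self) -> int:
        return sum(self.as_tuple())

    def has_zero_margin(self) -> bool:
        r1 = self.group1_positive + self.group1_negative
        r2 = self.group2_positive + self.group2_negative
        c1 = self.group1_positive + self.group2_positive
        c2 = self.group1_negative + self.group2_negative
        return 0 in (r1, r2, c1, c2)


@dataclass
class CalibrationResult:
    """Two-point Laconic calibration: sensor ratio at lactate saturation
    (r_max) and at pyruvate-driven depletion (r_min)."""

    r_max: float
    r_min: float

    def __post_init__(self):
        if not (self.r_max > self.r_min > 0):
            from .errors import CalibrationError

            raise CalibrationError(
                f"calibration requires r_max > r_min > 0, got r_max={self.r_max}, r_min={self.r_min}"
            )

    @property
    def dynamic_range_pct(self) -> float:
        """Sensor dynamic range as percent of r_min: 100*(r_max - r_min)/r_min."""
        return 100.0 * (self.r_max - self.r_min) / self.r_min
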