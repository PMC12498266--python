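"""CSV/JSON file exchange for traces and analysis results.

Traces travel as comma-separated text (``.`` decimal, UTF-8, header
required): a ``time`` column in seconds plus one signal column (LFP, mV)
or the two columns ``mtfp``/``fret`` (fluorescence, A.U.). An optional
JSON sidecar with the same stem supplies ``sampling_rate``, ``temperature``,
``label``, ``start_time`` and FRET backgrounds; without a sidecar the
sampling rate is inferred from the time column, which must be uniform to a
relative tolerance of 1e-6.

Results are written as JSON documents with explicit units in the key names
(``peak_frequency_hz``, ``mean_amplitude_mv``, ...) and round-trip
losslessly through :func:`read_results`.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MalformedInputError, SchemaError
from .traces import (
    AcfFitResult,
    CalibrationResult,
    ContingencyTable2x2,
    FretTrace,
    GammaMetrics,
    LFPRecording,
    SPWREvent,
    SPWRSummary,
)

__all__ = ["read_trace", "write_trace", "write_results", "read_results"]

TIME_TOLERANCE = 1e-6  # relative non-uniformity allowed in the time column


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _load_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def _infer_sampling_rate(time: np.ndarray) -> float:
    dt = np.diff(time)
    if dt.size == 0:
        raise MalformedInputError("time column needs at least two samples")
    ref = float(np.median(dt))
    if ref <= 0:
        bad = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise MalformedInputError(f"time column not strictly increasing at row {bad}", index=bad)
    off = np.flatnonzero(np.abs(dt - ref) > TIME_TOLERANCE * ref)
    if off.size:
        bad = int(off[0]) + 1
        raise MalformedInputError(
            f"non-uniform time column: spacing at row {bad} is {dt[off[0]]:.9g} s "
            f"(expected {ref:.9g} s)",
            index=bad,
        )
    return 1.0 / ref


def read_trace(path: str | Path) -> LFPRecording | FretTrace:
    """Read a trace CSV, dispatching on its columns.

    ``time`` + one signal column yields an :class:`LFPRecording`;
    ``time`` + ``mtfp`` + ``fret`` yields a :class:`FretTrace`.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in frame.columns}
    if "time" not in cols:
        raise SchemaError(f"{path}: missing required column 'time' (found {list(frame.columns)})")
    meta = _load_sidecar(path)
    time = frame[cols["time"]].to_numpy(dtype=float)

    if "mtfp" in cols and "fret" in cols:
        _infer_sampling_rate(time)  # structural validation only
        return FretTrace(
            time=time,
            mtfp=frame[cols["mtfp"]].to_numpy(dtype=float),
            fret=frame[cols["fret"]].to_numpy(dtype=float),
            background_mtfp=meta.get("background_mtfp", 0.0),
            background_fret=meta.get("background_fret", 0.0),
            label=meta.get("label", ""),
        )

    signal_cols = [c for c in frame.columns if c != cols["time"]]
    if len(signal_cols) != 1:
        raise SchemaError(
            f"{path}: expected one signal column (LFP) or 'mtfp'+'fret' (FRET), "
            f"found {signal_cols}"
        )
    sampling_rate = meta.get("sampling_rate", _infer_sampling_rate(time))
    return LFPRecording(
        samples=frame[signal_cols[0]].to_numpy(dtype=float),
        sampling_rate=float(sampling_rate),
        temperature=meta.get("temperature"),
        label=meta.get("label", ""),
        start_time=meta.get("start_time", float(time[0])),
    )


def write_trace(trace: LFPRecording | FretTrace, path: str | Path) -> None:
    """Write a trace as CSV plus a JSON metadata sidecar (same stem)."""
    path = Path(path)
    if isinstance(trace, LFPRecording):
        pd.DataFrame({"time": trace.time, "lfp_mv": trace.samples}).to_csv(
            path, index=False, float_format="%.10g"
        )
        meta = {
            "sampling_rate": trace.sampling_rate,
            "temperature": trace.temperature,
            "label": trace.label,
            "start_time": trace.start_time,
            "units": {"time": "s", "lfp_mv": "mV", "sampling_rate": "Hz"},
        }
    elif isinstance(trace, FretTrace):
        pd.DataFrame({"time": trace.time, "mtfp": trace.mtfp, "fret": trace.fret}).to_csv(
            path, index=False, float_format="%.10g"
        )
        meta = {
            "background_mtfp": _scalar_or_list(trace.background_mtfp),
            "background_fret": _scalar_or_list(trace.background_fret),
            "label": trace.label,
            "units": {"time": "s", "mtfp": "A.U.", "fret": "A.U."},
        }
    else:
        raise TypeError(f"cannot write trace of type {type(trace).__name__}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _scalar_or_list(value):
    arr = np.asarray(value)
    return arr.tolist() if arr.ndim else float(arr)


def _none_if_nan(x):
    if x is None:
        return None
    x = float(x)
    return None if math.isnan(x) else x


def _nan_if_none(x):
    return float("nan") if x is None else float(x)


def _encode(result) -> dict:
    if isinstance(result, GammaMetrics):
        return {
            "type": "GammaMetrics",
            "units": {"peak_frequency": "Hz", "peak_power": "mV^2/Hz", "fwhm": "Hz"},
            "peak_frequency_hz": result.peak_frequency,
            "peak_power": result.peak_power,
            "fwhm_hz": _none_if_nan(result.fwhm),
            "fwhm_defined": result.fwhm_defined,
            "present": result.present,
            "n_accepted_segments": result.n_accepted_segments,
            "segment_fits": [_encode(f) for f in result.segment_fits],
            "params": result.params,
        }
    if isinstance(result, AcfFitResult):
        return {
            "type": "AcfFitResult",
            "units": {"decay_time": "s", "oscillation_frequency": "Hz"},
            "segment_index": result.segment_index,
            "converged": result.converged,
            "amplitude": _none_if_nan(result.amplitude),
            "decay_time_s": _none_if_nan(result.decay_time),
            "oscillation_frequency_hz": _none_if_nan(result.oscillation_frequency),
            "goodness": _none_if_nan(result.goodness),
            "accepted": result.accepted,
        }
    if isinstance(result, SPWRSummary):
        return {
            "type": "SPWRSummary",
            "units": {
                "incidence": "events/s",
                "mean_amplitude": "mV",
                "mean_ripple_frequency": "Hz",
                "duration_analyzed": "s",
            },
            "n_events": result.n_events,
            "incidence_per_s": result.incidence,
            "mean_amplitude_mv": _none_if_nan(result.mean_amplitude),
            "mean_ripple_frequency_hz": _none_if_nan(result.mean_ripple_frequency),
            "duration_analyzed_s": result.duration_analyzed,
            "params": result.params,
        }
    if isinstance(result, SPWREvent):
        return {
            "type": "SPWREvent",
            "units": {"peak_time": "s", "amplitude": "mV", "ripple_frequency": "Hz"},
            "peak_time_s": result.peak_time,
            "amplitude_mv": result.amplitude,
            "window_s": list(result.window),
            "ripple_frequency_hz": result.ripple_frequency,
        }
    if isinstance(result, CalibrationResult):
        return {
            "type": "CalibrationResult",
            "units": {"r_max": "ratio", "r_min": "ratio", "dynamic_range": "Delta%"},
            "r_max": result.r_max,
            "r_min": result.r_min,
            "dynamic_range_pct": result.dynamic_range_pct,
        }
    if isinstance(result, ContingencyTable2x2):
        return {
            "type": "ContingencyTable2x2",
            "units": {"counts": "slices"},
            "group1_positive": result.group1_positive,
            "group1_negative": result.group1_negative,
            "group2_positive": result.group2_positive,
            "group2_negative": result.group2_negative,
        }
    if isinstance(result, list):
        return {"type": "ResultList", "items": [_encode(r) for r in result]}
    raise TypeError(f"cannot serialize result of type {type(result).__name__}")


def _decode(doc: dict):
    kind = doc.get("type")
    if kind == "GammaMetrics":
        return GammaMetrics(
            peak_frequency=doc["peak_frequency_hz"],
            peak_power=doc["peak_power"],
            fwhm=_nan_if_none(doc["fwhm_hz"]),
            fwhm_defined=doc["fwhm_defined"],
            present=doc["present"],
            segment_fits=[_decode(f) for f in doc["segment_fits"]],
            n_accepted_segments=doc["n_accepted_segments"],
            params=doc.get("params", {}),
        )
    if kind == "AcfFitResult":
        return AcfFitResult(
            segment_index=doc["segment_index"],
            converged=doc["converged"],
            amplitude=_nan_if_none(doc["amplitude"]),
            decay_time=_nan_if_none(doc["decay_time_s"]),
            oscillation_frequency=_nan_if_none(doc["oscillation_frequency_hz"]),
            goodness=_nan_if_none(doc["goodness"]),
            accepted=doc["accepted"],
        )
    if kind == "SPWRSummary":
        return SPWRSummary(
            n_events=doc["n_events"],
            incidence=doc["incidence_per_s"],
            mean_amplitude=_nan_if_none(doc["mean_amplitude_mv"]),
            mean_ripple_frequency=_nan_if_none(doc["mean_ripple_frequency_hz"]),
            duration_analyzed=doc["duration_analyzed_s"],
            params=doc.get("params", {}),
        )
    if kind == "SPWREvent":
        return SPWREvent(
            peak_time=doc["peak_time_s"],
            amplitude=doc["amplitude_mv"],
            window=tuple(doc["window_s"]),
            ripple_frequency=doc["ripple_frequency_hz"],
        )
    if kind == "CalibrationResult":
        return CalibrationResult(r_max=doc["r_max"], r_min=doc["r_min"])
    if kind == "ContingencyTable2x2":
        return ContingencyTable2x2(
            doc["group1_positive"],
            doc["group1_negative"],
            doc["group2_positive"],
            doc["group2_negative"],
        )
    if kind == "ResultList":
        return [_decode(item) for item in doc["items"]]
    raise TypeError(f"unknown result document type {kind!r}")


def write_results(result, path: str | Path) -> None:
    """Serialize an analysis result (or list of results) to a JSON file."""
    Path(path).write_text(json.dumps(_encode(result), indent=1))


def read_results(path: str | Path):
    """Read back a result document written by :func:`write_results`."""
    return _decode(json.loads(Path(path).read_text()))
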