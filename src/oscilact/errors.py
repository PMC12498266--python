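"""Exception hierarchy shared by all analysis stages."""


class OscilactError(Exception):
    """Base class for all package errors."""


class ParameterError(OscilactError, ValueError):
    """An argument is outside its admissible range (e.g. a filter edge at or
    above Nyquist, an empty search band, a negative rate)."""


class InputError(OscilactError, ValueError):
    """The supplied data cannot be analysed as requested (too short, all
    frames invalid, zero variance where variance is required)."""


class SchemaError(InputError):
    """A delimited-text input is missing required columns."""


class MalformedInputError(InputError):
    """A delimited-text input violates a structural requirement, e.g. a
    non-uniform or duplicated time column. ``index`` names the first
    offending row."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class CalibrationError(OscilactError, ValueError):
    """Two-point FRET calibration failed (r_max <= r_min: swapped windows or
    an unresponsive sensor)."""
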