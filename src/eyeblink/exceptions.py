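"""Package-wide exception types."""


class EyeblinkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EyeblinkError, ValueError):
    """A parameter value is outside its allowed domain."""


class InputError(EyeblinkError, ValueError):
    """Inconsistent inputs (mismatched grids, overlapping trials, ...)."""


class UnlearnableISIError(EyeblinkError, ValueError):
    """The requested inter-stimulus interval is below the minimum learnable ISI."""


class DegenerateCalibrationError(EyeblinkError, ValueError):
    """The calibration system is rank deficient (e.g. no depression events at all)."""
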