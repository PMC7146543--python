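"""Exception hierarchy and CLI exit codes."""


class LiftkinError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(LiftkinError):
    """Invalid configuration or parameter value."""

    exit_code = 2


class FormatError(LiftkinError):
    """Malformed or missing input data file."""

    exit_code = 3


class InputError(LiftkinError):
    """Structurally valid file but inconsistent in-memory input."""

    exit_code = 3


class CalibrationError(LiftkinError):
    """Functional-calibration capture violates its static/pose assumptions."""

    exit_code = 4


class SegmentationError(LiftkinError):
    """No movement detected when bracketing a task cycle."""

    exit_code = 4


class NumericError(LiftkinError):
    """Numerical failure (non-orthonormal rotation, degenerate window, ...)."""

    exit_code = 4
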