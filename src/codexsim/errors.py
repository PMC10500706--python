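"""Exception hierarchy shared across the package.

Each error class maps to a distinct CLI exit code (see :mod:`codexsim.cli`).
"""


class CodexError(Exception):
    """Base class for all package errors."""


class ConfigError(CodexError):
    """Invalid configuration: bad parameter value, malformed pulse train,
    unknown scheme/scenario, schema violation."""


class DomainError(CodexError, ValueError):
    """Physical parameter outside its admissible domain (e.g. asymmetry
    outside [0, 1], negative relaxation time, singular phase)."""


class DataError(CodexError):
    """Malformed or inconsistent tabular data (non-monotone mixing-time
    grid, grid mismatch, zero denominator in a normalization)."""


class FormatError(DataError):
    """Structural problem in a curve file (missing header, bad column)."""


class ConvergenceError(CodexError):
    """A fit failed to converge and no usable result can be reported."""
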