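"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class GbplsError(Exception):
    """Base class for all package errors."""


class ConfigError(GbplsError):
    """Invalid or inconsistent run configuration."""


class DataError(GbplsError):
    """Malformed or misaligned input data."""


class NumericalError(GbplsError):
    """Numerical failure: non-convergence, rank deficiency, degenerate fit."""
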