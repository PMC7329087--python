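"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericError -> 4.
"""


class FsopaError(Exception):
    """Base class for all package errors."""


class ConfigError(FsopaError):
    """Invalid or inconsistent configuration (unknown column, bad role, ...)."""


class DataError(FsopaError):
    """Invalid input data (ragged rows, duplicate headers, empty subsets, ...)."""


class NumericError(FsopaError):
    """Numerical failure (non-convergence, singular design, non-finite input)."""
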