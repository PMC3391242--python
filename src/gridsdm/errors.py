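"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigurationError -> 2,
DataError (and subclasses) -> 3, NumericalError -> 4.
"""


class GridSDMError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GridSDMError):
    """Invalid configuration value (fractions, caps, lattice dims, ...)."""


class DataError(GridSDMError):
    """Invalid or inconsistent input data."""


class ValidationError(DataError):
    """A table or spec violates a declared invariant."""


class AlignmentError(DataError):
    """Two grid-aligned objects do not share the same cell set/order."""


class UndefinedMetricError(DataError):
    """A metric is undefined for the given input (e.g. single-class truth)."""


class NumericalError(GridSDMError):
    """A numerical routine failed to produce a usable result."""
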