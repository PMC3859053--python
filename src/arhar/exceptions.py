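"""Exception hierarchy for arhar.

All errors derive from :class:`ArharError` so callers can catch the package's
failures with a single except clause. Parameter misuse raises
:class:`ParameterError` (a ``ValueError``), malformed input files raise
:class:`FormatError`, and semantically invalid data (e.g. non-monotone
timestamps) raises :class:`DataError`.
"""


class ArharError(Exception):
    """Base class for all arhar errors."""


class ParameterError(ArharError, ValueError):
    """An argument violates an operation's contract."""


class DataError(ArharError, ValueError):
    """Input data violates a semantic invariant (e.g. timestamp order)."""


class FormatError(ArharError, ValueError):
    """A file could not be parsed as the expected format."""


class DegenerateSignalError(DataError):
    """A signal is constant/zero where variability is required."""


class StabilityError(ArharError, ValueError):
    """An autoregressive model has roots on or outside the unit circle."""


class NumericalError(ArharError, RuntimeError):
    """A numerical routine failed even after regularization."""


class ProtocolError(ArharError, ValueError):
    """An evaluation protocol constraint was violated (e.g. subject overlap)."""


class GenerationError(ArharError, RuntimeError):
    """The synthetic-data generator could not produce a valid signal."""
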