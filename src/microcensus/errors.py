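"""Exception hierarchy.

``ParameterError`` flags invalid arguments (bad thresholds, identities outside
[0, 100], malformed specs); ``DataError`` flags defective input data (unknown
dataset types, missing hits, non-IUPAC characters); ``UsageError`` flags calls
that are invalid in context (e.g. asking for the alignment fraction of a
no-hit result).
"""


class MicrocensusError(Exception):
    """Base class for all package errors."""


class ParameterError(MicrocensusError, ValueError):
    """An argument violates its contract."""


class DataError(MicrocensusError, ValueError):
    """Input data are malformed or incomplete."""


class UsageError(MicrocensusError, RuntimeError):
    """An operation was invoked in an invalid state."""
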