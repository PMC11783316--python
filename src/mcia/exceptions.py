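"""Exception hierarchy."""


class MCIAError(Exception):
    """Base class for all package errors."""


class ValidationError(MCIAError):
    """Invalid multi-block input (unaligned samples, non-finite values, ...)."""


class SchemaMismatchError(MCIAError):
    """Feature schema of new data does not match the fitted model."""


class DegenerateBlockError(MCIAError):
    """A block has no variance left where a positive block weight is required."""


class NoVarianceError(MCIAError):
    """All blocks are (numerically) zero; nothing left to decompose."""


class PredictionModeError(MCIAError):
    """Out-of-sample prediction requested for a mode that does not support it."""
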