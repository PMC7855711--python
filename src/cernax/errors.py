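"""Exception hierarchy.

Parse errors name the offending file/line; validation errors name the
violated invariant; the two statistical degeneracies (too few paired
observations vs. zero variance) are distinct types so callers can react
differently.
"""


class CernaxError(Exception):
    """Base class for all package errors."""


class ParseError(CernaxError):
    """A file could not be parsed (malformed header, non-numeric cell, ...)."""


class ValidationError(CernaxError):
    """An in-memory object violates a domain invariant."""


class InsufficientDataError(CernaxError):
    """Fewer than the minimum number of observations (n < 3 for correlation)."""


class DegenerateInputError(CernaxError):
    """A vector with zero variance where variability is required."""


class PipelineError(CernaxError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
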