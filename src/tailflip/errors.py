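"""Exception hierarchy.

All package errors derive from :class:`TailflipError` so callers can catch a
single base class; most also derive from ``ValueError`` to behave naturally in
generic code.
"""


class TailflipError(Exception):
    """Base class for all tailflip errors."""


class ParameterError(TailflipError, ValueError):
    """A model or generator parameter is invalid (non-finite, out of range)."""


class DesignError(TailflipError, ValueError):
    """A study design is internally inconsistent (e.g. duplicate group labels)."""


class ConfigurationError(TailflipError, ValueError):
    """A processing configuration is incompatible with the data it is applied to."""


class InputError(TailflipError, ValueError):
    """Input data violate a precondition of an operation."""


class NormalizationError(TailflipError, ValueError):
    """A fish cannot be baseline-normalized (non-positive baseline median)."""


class EstimationError(TailflipError, ValueError):
    """A statistical quantity cannot be estimated from the given data."""


class PipelineError(TailflipError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
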