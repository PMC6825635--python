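"""Exception hierarchy for the pipeline.

All domain errors derive from :class:`MicrovascError` so callers can catch
pipeline failures without swallowing programming errors.
"""


class MicrovascError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MicrovascError, ValueError):
    """A parameter violates its documented constraints."""


class FormatError(MicrovascError, ValueError):
    """An input file is malformed (unequal page shapes, zero pages, ...)."""


class InputError(MicrovascError, OSError):
    """An input path is missing or unreadable."""


class DegenerateInputError(MicrovascError, ValueError):
    """The input is formally valid but carries no usable information
    (constant volume, all sections dropped, too few sections)."""


class ConsistencyError(MicrovascError, ValueError):
    """Two objects that must describe the same geometry disagree
    (shape mismatch, graph points outside the mask)."""


class StageError(MicrovascError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
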