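"""Exception types shared across the pipeline.

Readers reject malformed input rather than silently repairing it; format
errors carry the offending line number whenever one exists.
"""


class SyntenyMapError(Exception):
    """Base class for all package errors."""


class FormatError(SyntenyMapError):
    """A file does not conform to its declared format."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(SyntenyMapError):
    """Parsed content violates a domain invariant (duplicate ids, bad spans)."""


class SizingError(SyntenyMapError):
    """A simulation config demands more material than the reference provides."""


class StageError(SyntenyMapError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage}: {message}")
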