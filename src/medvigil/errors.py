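"""Exception hierarchy shared across the pipeline stages."""


class MedvigilError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MedvigilError, ValueError):
    """Malformed input data or configuration."""


class ParseError(MedvigilError, ValueError):
    """A corpus or data file could not be parsed; message names the line."""


class GenerationError(MedvigilError, RuntimeError):
    """The synthetic generator could not satisfy its quotas."""


class ConvergenceError(MedvigilError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EmptyWindowError(MedvigilError, ValueError):
    """A user has no posts in the requested pre/post window."""


class StageError(MedvigilError, RuntimeError):
    """A pipeline stage failed; names the stage and wraps the cause."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
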