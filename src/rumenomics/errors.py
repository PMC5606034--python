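"""Exception hierarchy shared across the package."""


class RumenomicsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RumenomicsError, ValueError):
    """An input table or value violates a structural invariant."""


class ConfigurationError(RumenomicsError, ValueError):
    """A configuration object holds an invalid field value."""


class UndefinedCorrelationError(RumenomicsError, ValueError):
    """A rank correlation is requested for a constant vector."""


class PipelineStageError(RumenomicsError, RuntimeError):
    """A pipeline stage failed; carries the stage name for attribution."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
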