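"""Exception hierarchy shared across the pipeline."""


class GazeFusionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GazeFusionError):
    """An invalid configuration value; ``field`` names the offender."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DataError(GazeFusionError):
    """Malformed or unusable input data."""


class PreconditionError(GazeFusionError):
    """An operation was called on input violating its declared precondition."""


class AlignmentError(GazeFusionError):
    """Score sets that must share sample ids do not."""


class StageError(GazeFusionError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
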