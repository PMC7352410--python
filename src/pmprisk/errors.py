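"""Exception hierarchy shared across the package."""


class PmpriskError(Exception):
    """Base class for all package errors."""


class ValidationError(PmpriskError, ValueError):
    """Invalid input data, configuration, or violated precondition."""


class StageError(PmpriskError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
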