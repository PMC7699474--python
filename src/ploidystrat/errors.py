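"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when inputs or parameters violate a documented contract."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name as context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
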