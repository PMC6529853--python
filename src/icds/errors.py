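"""Exception hierarchy shared across the pipeline stages."""


class IcdsError(RuntimeError):
    """Base class for all errors raised by this package."""


class ValidationError(IcdsError):
    """An input file or matrix violates a structural invariant."""


class StageError(IcdsError):
    """A pipeline stage failed; the message is prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")
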