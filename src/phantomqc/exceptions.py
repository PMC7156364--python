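"""Exception hierarchy shared across the package."""


class PhantomQCError(Exception):
    """Base class for all package errors."""


class InputError(PhantomQCError, ValueError):
    """A runtime input (array, scalar, path contents) violates a precondition."""


class ConfigurationError(PhantomQCError, ValueError):
    """A configuration object (geometry, design, ROI, run config) is invalid."""


class FormatError(PhantomQCError, ValueError):
    """A file on disk is not a readable instance of the expected format."""


class PipelineError(PhantomQCError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
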