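"""Exception hierarchy for linrelax."""


class LinrelaxError(Exception):
    """Base class for all linrelax errors."""


class ValidationError(LinrelaxError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(LinrelaxError, IOError):
    """A file could not be parsed as the expected format (e.g. NIfTI-1)."""


class CollinearityError(LinrelaxError, ValueError):
    """The design matrix is rank deficient beyond the condition tolerance."""


class PipelineError(LinrelaxError, RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""
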