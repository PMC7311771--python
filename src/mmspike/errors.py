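"""Structured exceptions raised across the pipeline."""


class MMSpikeError(Exception):
    """Base class for all library errors."""


class ParseError(MMSpikeError):
    """A motion or metadata file could not be parsed."""


class ValidationError(MMSpikeError):
    """An input violated a documented precondition or invariant."""


class FitError(MMSpikeError):
    """A distribution fit was degenerate or failed to converge."""
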