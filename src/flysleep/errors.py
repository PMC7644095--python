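"""Exception types shared across the package."""


class FlysleepError(ValueError):
    """Base class for all package-specific errors."""


class ParseError(FlysleepError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(FlysleepError):
    """Input violated a documented invariant (gaps, ranges, missing arms...)."""


class DIUndefinedError(FlysleepError):
    """The defasciculation index is undefined: the arbor produced no ring crossings."""
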