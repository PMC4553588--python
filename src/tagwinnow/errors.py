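"""Exception types shared across the pipeline."""


class TagwinnowError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(TagwinnowError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class FormatError(TagwinnowError, ValueError):
    """A malformed input file; the message names the offending row/line."""


class ConsistencyError(TagwinnowError, ValueError):
    """Inputs that are individually valid but mutually inconsistent."""
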