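"""Exception hierarchy shared across the pipeline stages."""


class SemgMapError(Exception):
    """Base class for all package errors."""


class ValidationError(SemgMapError, ValueError):
    """A parameter or input violates a stage precondition."""


class DegenerateInputError(SemgMapError, ValueError):
    """Input is structurally valid but carries no usable signal (e.g. all-zero map)."""


class EmptySegmentError(SemgMapError, ValueError):
    """No samples satisfy the plateau criterion."""


class UnrecoverableChannelError(SemgMapError, ValueError):
    """A flagged channel has no unflagged neighbor to repair from."""


class FormatError(SemgMapError, ValueError):
    """A delimited-text artifact does not conform to the expected dialect."""
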