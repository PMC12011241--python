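"""Exception hierarchy shared across the pipeline stages."""


class GaitlatError(Exception):
    """Base class for all package errors."""


class MocapFormatError(GaitlatError):
    """A marker file could not be parsed (malformed header, bad column count...)."""


class ValidationError(GaitlatError):
    """Input data violates a contract (missing markers, incomplete design...)."""


class ParameterError(GaitlatError):
    """A numeric parameter is out of its admissible range."""


class InsufficientEventsError(GaitlatError):
    """Too few heel contacts were detected to segment the requested cycles."""


class AlternationError(GaitlatError):
    """Left/right heel contacts do not alternate over the selected span."""
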