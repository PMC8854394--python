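"""Exception hierarchy shared across the pipeline."""


class TaqingError(Exception):
    """Base class for all package errors."""


class ConfigError(TaqingError):
    """Invalid configuration value; the message names the offending field."""


class CoordinateError(TaqingError):
    """A position falls outside the coordinate bounds it is interpreted in."""


class BreakpointError(TaqingError):
    """A rearrangement breakpoint is not a TaqI site in strict mode."""


class EventConflictError(TaqingError):
    """An event overlaps a previously rearranged interval of the same molecule."""


class PlacementError(TaqingError):
    """Random event placement failed after the retry budget."""


class FormatError(TaqingError):
    """A file does not satisfy its format contract (sorting, header, ...)."""


class InputError(TaqingError):
    """Inputs are mutually inconsistent or missing."""


class VocabularyError(TaqingError):
    """An event type outside the closed report vocabulary."""
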