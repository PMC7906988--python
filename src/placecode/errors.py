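"""Exception hierarchy for the place-coding pipeline."""


class PlacecodeError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(PlacecodeError):
    """A simulation or analysis configuration violates its invariants."""


class AlignmentError(PlacecodeError):
    """Tracking and imaging time bases cannot be joined."""


class UnsupportedArenaError(PlacecodeError):
    """An operation was requested for the wrong arena geometry."""


class EmptyMapError(PlacecodeError):
    """A rate map has no occupied bins (e.g. no moving frames)."""


class NoFieldError(PlacecodeError):
    """Field detection on an all-zero rate map."""


class UndefinedInformationError(PlacecodeError):
    """Spatial information is undefined (mean rate is zero)."""


class InsufficientDataError(PlacecodeError):
    """Too few laps, points, or samples for the requested statistic."""


class ParseError(PlacecodeError):
    """An input file does not conform to the declared format."""
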