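"""Exception hierarchy shared across the pipeline stages."""


class AcromotionError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AcromotionError):
    """The input file does not conform to the documented schema."""


class ParseError(AcromotionError):
    """A cell could not be parsed as a number."""


class InsufficientDataError(AcromotionError):
    """Too few frames/rows for the requested computation."""


class InsufficientCyclesError(AcromotionError):
    """Not enough complete abduction/adduction cycles to segment."""


class DegenerateGeometryError(AcromotionError):
    """Point set admits no unique circle (collinear or coincident)."""


class ZeroArcError(AcromotionError):
    """Leftmost and rightmost trajectory points coincide."""


class UndefinedICCError(AcromotionError):
    """ICC is undefined (no between-target variance)."""


class PairingError(AcromotionError):
    """Paired sequences have mismatched lengths."""
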