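"""Exception hierarchy shared across the package."""


class BmassayError(Exception):
    """Base class for all bmassay errors."""


class ParseError(BmassayError):
    """A delimited-text file contained a row that could not be parsed."""


class StructureError(BmassayError):
    """A file or object violated a structural invariant (shape, length, raggedness)."""


class GeometryError(BmassayError):
    """A geometric precondition failed (degenerate extent, region out of bounds...)."""


class SampleSizeError(BmassayError):
    """Too few observations for the requested statistic."""


class CoverageError(BmassayError):
    """A trajectory does not cover the requested period layout."""


class DesignError(BmassayError):
    """An experiment-level analysis received an invalid or empty design."""
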