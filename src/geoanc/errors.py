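"""Exception types shared across the package."""


class GeoancError(Exception):
    """Base class for all package errors."""


class FormatError(GeoancError):
    """Malformed input tables or tree-sequence files."""


class DataError(GeoancError):
    """Structurally valid input with missing or inconsistent data."""


class ParameterError(GeoancError, ValueError):
    """An argument outside its documented domain."""


class DisconnectedGridError(GeoancError):
    """A computation reached a pair of grid cells with infinite cost."""


class SizeError(GeoancError):
    """A brute-force oracle was asked for an instance beyond its size guard."""
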