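"""Exception hierarchy for the interface-analytics pipeline."""


class ImmunogradientError(Exception):
    """Base class for all package errors."""


class InvalidResolutionError(ImmunogradientError):
    """Hexagon side is too small relative to the raster pixel size."""


class EmptyInputError(ImmunogradientError):
    """An input raster or table is empty."""


class GeometryError(ImmunogradientError):
    """Grid and raster geometries do not match."""


class VocabularyError(ImmunogradientError):
    """A categorical value is outside its fixed vocabulary."""


class NoInterfaceError(ImmunogradientError):
    """No tumor-stroma interface exists on the slide (e.g. all-tumor raster)."""


class ParameterError(ImmunogradientError):
    """A parameter is outside its valid range."""


class DegenerateTableError(ImmunogradientError):
    """A contingency table has a zero margin."""


class NoCutoffError(ImmunogradientError):
    """No admissible cutoff candidate exists for an indicator."""
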