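"""Exception hierarchy for the esdrought pipeline."""


class EsDroughtError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EsDroughtError):
    """Invalid configuration value; the message names the offending field."""


class DimensionError(EsDroughtError):
    """Co-registered inputs do not share shape / cell size / mask."""


class DomainError(EsDroughtError):
    """A physical input violates its admissible range on a valid cell."""


class DataError(EsDroughtError):
    """Non-finite or otherwise unusable data on a valid cell."""


class AllocationError(EsDroughtError):
    """Zonal mass cannot be allocated (e.g. yield with no cropland NDVI)."""


class InsufficientDataError(EsDroughtError):
    """Too few observations for the requested statistic."""


class FitError(EsDroughtError):
    """All candidate curve families failed to fit."""


class ChecksumError(EsDroughtError):
    """A fixture file does not match its manifest checksum."""


class AlignmentError(EsDroughtError):
    """Rasters in an input directory are not co-registered."""


class DependencyError(EsDroughtError):
    """A pipeline stage was requested before its upstream stage ran."""
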