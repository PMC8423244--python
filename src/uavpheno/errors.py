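"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`PhenoError`
so callers can catch the package's failures without swallowing programming
errors. Subclasses also derive from the closest builtin (ValueError /
RuntimeError) to behave well in generic code.
"""


class PhenoError(Exception):
    """Base class for all errors raised by uavpheno."""


class InvalidParameterError(PhenoError, ValueError):
    """A numeric parameter violates its domain (e.g. non-positive altitude)."""


class ConfigurationError(PhenoError, ValueError):
    """Inconsistent configuration: band mismatch, unknown config key, ..."""


class GeoreferencingError(PhenoError, ValueError):
    """A raster lacks the affine transform needed to place it in the world."""


class EmptyROIError(PhenoError, ValueError):
    """A region of interest covers no pixel centers (or no ROIs at all)."""


class GeometryError(PhenoError, ValueError):
    """A polygon is invalid (self-intersecting, empty, not a polygon)."""


class SchemaError(PhenoError, ValueError):
    """A GeoJSON feature or table is missing a required property/column."""


class UnderdeterminedFitError(PhenoError, ValueError):
    """Too few distinct calibration points to fit the model."""


class DomainError(PhenoError, ValueError):
    """A value is outside the mathematical domain of an operation
    (e.g. non-positive reflectance cannot be log-transformed)."""


class DegenerateInputError(PhenoError, ValueError):
    """Constant or otherwise degenerate input where variation is required."""


class InsufficientDataError(PhenoError, ValueError):
    """Fewer observations than the statistical procedure requires."""


class DataIntegrityError(PhenoError, ValueError):
    """Duplicate keys or an internally inconsistent table/relation."""


class GenerationError(PhenoError, RuntimeError):
    """The synthetic-scene generator was asked for an impossible scene."""


class PipelineStageError(PhenoError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
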