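"""Exception hierarchy for the QA pipeline.

All package-specific failures derive from :class:`HeteroQAError` so callers can
catch one base class at pipeline boundaries.
"""


class HeteroQAError(Exception):
    """Base class for all heteroqa errors."""


class GridFormatError(HeteroQAError):
    """A grid file (DGRID or DICOM) is structurally malformed."""


class GridSizeError(HeteroQAError):
    """Payload size does not match the declared dimensions."""


class GridDomainError(HeteroQAError):
    """Values violate a domain invariant (negative dose, non-binary mask, ...)."""


class GeometryError(HeteroQAError):
    """Incompatible or unsupported grid geometry."""


class UnsupportedGeometryError(GeometryError):
    """DICOM geometry outside the supported axis-aligned uniform class."""


class UnitError(HeteroQAError):
    """Dose stored in units other than Gy."""


class EmptyROIError(HeteroQAError):
    """An operation received (or produced) a region with no voxels to score."""


class SampleSizeError(HeteroQAError):
    """Too few observations for the requested statistic."""


class DegenerateDesignError(HeteroQAError):
    """Regression design has zero variance in the predictor."""


class NoCrossingError(HeteroQAError):
    """A fitted line with zero slope never crosses the requested level."""


class PairingError(HeteroQAError):
    """Case ids cannot be paired across algorithm labels."""


class ConfigurationError(HeteroQAError):
    """A run configuration references structures or options that do not exist."""


class SpecificationError(HeteroQAError):
    """A constraint references a metric the DVH summary does not contain."""
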