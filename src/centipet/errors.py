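"""Exception hierarchy for the centipet pipeline."""


class CentipetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CentipetError):
    """Unreadable or malformed image file."""


class DimensionalityError(CentipetError):
    """Input volume has the wrong number of dimensions."""


class ContractViolation(CentipetError):
    """An operation was called in a way that breaks its contract."""


class DomainError(CentipetError):
    """A scalar argument lies outside its valid domain."""


class GeometryError(CentipetError):
    """Requested grid cannot accommodate the phantom head model."""


class RegistrationError(CentipetError):
    """Image registration could not be performed or failed to converge."""


class SegmentationError(CentipetError):
    """Tissue segmentation diverged or produced invalid posteriors."""


class WarpError(CentipetError):
    """Deformation estimation produced a folding (non-diffeomorphic) field."""


class QuantificationError(CentipetError):
    """SUVR could not be computed (empty or non-positive reference)."""


class SampleSizeError(CentipetError):
    """Too few observations for the requested statistic."""
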