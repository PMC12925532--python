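"""Exception hierarchy shared across the package."""


class AneumorphError(Exception):
    """Base class for all package-specific errors."""


class ResolutionError(AneumorphError):
    """A grid is too coarse to represent the requested geometry."""


class EmptyMaskError(AneumorphError):
    """A mask has no foreground voxels."""


class MeshTopologyError(AneumorphError):
    """A mesh violates the closed 2-manifold contract."""


class DegenerateMaskError(AneumorphError):
    """Foreground voxels are collinear/coplanar; principal axes undefined."""


class UnreliableLocalShapeError(AneumorphError):
    """Too few valid vertices to aggregate local shape descriptors."""


class TransformError(AneumorphError):
    """A variable transform was applied to invalid input."""


class DesignError(AneumorphError):
    """A regression design matrix violates its preconditions."""


class SeparationError(DesignError):
    """Complete separation detected in a logistic model."""


class ImputationError(AneumorphError):
    """Missing-data pattern outside the imputation contract."""


class SchemaError(AneumorphError):
    """A cohort table violates the documented schema."""
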