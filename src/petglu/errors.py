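"""Exception hierarchy shared by all petglu modules."""


class PetgluError(Exception):
    """Base class for all petglu errors."""


class GeometryError(PetgluError):
    """Invalid or mismatched image geometry (spacing, direction, grid)."""


class FrameTimingMismatch(PetgluError):
    """Frame count of a dynamic volume disagrees with its timing sidecar."""


class NotDynamic(PetgluError):
    """A 4D dynamic series was expected but a 3D volume was given."""


class NotStatic(PetgluError):
    """A 3D static volume was expected but a 4D series was given."""


class ConfigError(PetgluError):
    """Invalid configuration value (unknown option, non-positive parameter...)."""


class RegistrationFailure(PetgluError):
    """Rigid registration could not be performed (e.g. no spatial overlap)."""


class SeedOutsideRange(PetgluError):
    """Seed point intensity falls outside the segmentation window."""


class LeakDetected(PetgluError):
    """Region growing escaped the expected vessel calibre."""


class EmptyVOI(PetgluError):
    """A VOI ended up with no usable voxels."""


class TimeGridMismatch(PetgluError):
    """Two time-activity curves are not sampled on the same frame mid-times."""


class DegenerateInput(PetgluError):
    """Not enough usable data points for the requested fit."""


class EmptyInput(PetgluError):
    """An empty collection was passed where at least one value is required."""


class PairingError(PetgluError):
    """Pre/post value lists cannot be paired (length mismatch)."""


class GroupEmpty(PetgluError):
    """A treatment group has too few records for the requested analysis."""


class SingularDesign(PetgluError):
    """Rank-deficient design matrix for a linear model."""


class SpecError(PetgluError):
    """Invalid phantom specification (overlapping organs, bad counts...)."""


class SchemaError(PetgluError):
    """A cohort table is missing or mistypes a required column."""
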