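"""Exception hierarchy shared across the package."""


class PetislError(Exception):
    """Base class for all petisl errors."""


class ValidationError(PetislError):
    """An input value violates a documented precondition."""


class GeometryError(PetislError):
    """A geometric object does not fit the volume it is applied to."""


class OutOfBoundsError(GeometryError):
    """A measurement VOI extends beyond the volume grid."""


class EmptySupportError(GeometryError):
    """A rasterized object covers no voxel of the grid."""


class InsufficientSupportError(PetislError):
    """A VOI contains too few voxel centres for a stable estimate."""


class RegistrationError(PetislError):
    """Two volumes expected to share a world frame do not."""


class InfeasibleError(PetislError):
    """A solve has no solution under the given operating point."""


class DegenerateLesionError(PetislError):
    """A lesion measurement region is empty or ill-defined."""
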