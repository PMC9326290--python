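"""Exception hierarchy for thermometric PMI estimation."""


class ThermoPMIError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ThermoPMIError):
    """A precondition on user-supplied data was violated."""


class VoxelizationError(ThermoPMIError):
    """The point cloud could not be turned into a closed voxel body."""


class LocalizationError(ThermoPMIError):
    """A logger position could not be snapped to a surface cube."""


class InvalidMaterialError(ThermoPMIError):
    """A thermal property is non-positive or missing."""


class StabilityViolationError(ThermoPMIError):
    """The requested time step exceeds the explicit-scheme stability bound."""


class InvalidConfigError(ThermoPMIError):
    """Inconsistent simulation, matching, or case configuration."""


class DegenerateDesignError(ThermoPMIError):
    """Too few or coincident evaluation points for surrogate interpolation."""


class ExhaustedCandidatesError(ThermoPMIError):
    """Every candidate point fell inside the exclusion radius of history."""


class InsufficientDataError(ThermoPMIError):
    """Not enough evaluation records for the requested diagnostic."""
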