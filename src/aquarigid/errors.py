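"""Exception hierarchy."""


class AquarigidError(Exception):
    """Base class for package errors."""


class InvalidGeometryError(AquarigidError):
    """Monomer geometry is non-finite or outside physical bounds."""


class IncompleteModelError(AquarigidError):
    """A model is missing parameters required by the requested operation."""


class InvalidParameterError(AquarigidError):
    """A parameter value is outside its admissible range."""


class ModeError(AquarigidError):
    """Operation incompatible with the model's flexibility mode."""


class TopologyError(AquarigidError):
    """System composition inconsistent with the declared topology."""


class LatticeError(AquarigidError):
    """Requested system size incompatible with the crystal lattice."""


class ConstraintFailureError(AquarigidError):
    """Holonomic constraint solver failed to converge."""


class SingularityError(AquarigidError):
    """Overlapping sites make the potential singular."""


class BlowUpError(AquarigidError):
    """Total energy diverged during integration."""


class UnwrapRequiredError(AquarigidError):
    """Molecules are wrapped across periodic boundaries."""


class MeltFailureError(AquarigidError):
    """Slab end regions remained crystalline after the melt stage."""


class InsufficientDataError(AquarigidError):
    """Trajectory too short for the requested analysis window."""


class IllConditionedError(AquarigidError):
    """Finite-difference denominator below the noise floor."""


class FormatError(AquarigidError):
    """Unrecognized or malformed file format."""


class ConfigError(AquarigidError):
    """Invalid run configuration."""
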