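"""Exception hierarchy for the rhodolith pipeline."""


class RhodolithError(Exception):
    """Base class for all pipeline errors."""


class ProfileError(RhodolithError):
    """Invalid microsensor profile input."""


class TooFewPointsError(ProfileError):
    """Not enough profile points for the requested operation."""


class DegenerateGradientError(ProfileError):
    """Surface gradient statistically indistinguishable from zero; no DBL definable."""


class DBLOutOfRangeError(ProfileError):
    """Extrapolated DBL thickness falls outside the measured depth range."""


class AnalyteMismatchError(ProfileError):
    """Operation applied to a profile of the wrong analyte (oxygen vs pH)."""


class ProfileMismatchError(ProfileError):
    """Light/dark profile pair refers to different species or locations."""


class TitrationError(RhodolithError):
    """Invalid titration curve or Gran fit failure."""


class NoEquivalencePointError(TitrationError):
    """Titration does not proceed past the carbonic-acid equivalence point."""


class CarbonateSolverError(RhodolithError):
    """CO2-system speciation has no physical solution for the given inputs."""


class ConstantRangeError(CarbonateSolverError):
    """Temperature or salinity outside the fitted range of the constant set."""


class IncubationError(RhodolithError):
    """Invalid chamber incubation record."""


class MissingControlError(IncubationError):
    """Control incubation correction required but absent."""


class EmptyMaskError(RhodolithError):
    """Segmentation produced an empty mask."""


class ResolutionError(RhodolithError):
    """Voxel grid too coarse to resolve the requested geometry."""


class InsufficientReplicationError(RhodolithError):
    """Too few groups or replicates for the statistical procedure."""
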