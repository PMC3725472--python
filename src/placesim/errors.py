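"""Exception hierarchy shared across the toolkit."""


class PlacesimError(Exception):
    """Base class for all errors raised by placesim."""


class ParameterError(PlacesimError, ValueError):
    """An operation was called with invalid parameter values."""


class ConfigurationError(PlacesimError, ValueError):
    """A configuration (file, architecture, tiling) is inconsistent."""


class FloorPlanError(PlacesimError, ValueError):
    """A floor plan file could not be parsed or is geometrically invalid."""


class RaycastError(PlacesimError, RuntimeError):
    """A ray escaped the enclosure (open floor plan or outside origin)."""


class SimulationError(PlacesimError, RuntimeError):
    """The movement simulation could not make progress."""


class NumericalRankError(PlacesimError, RuntimeError):
    """A moment matrix is rank deficient; fitting cannot proceed."""


class StateError(PlacesimError, RuntimeError):
    """An operation was called in an invalid network/training state."""


class IntegrityError(PlacesimError, RuntimeError):
    """A data file on disk is inconsistent with its declared layout."""


class GapWarning(UserWarning):
    """A floor plan's wall segments do not form closed loops."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped before reaching its tolerance."""
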