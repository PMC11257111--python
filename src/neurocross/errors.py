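"""Exception hierarchy shared across the package."""


class NeurocrossError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NeurocrossError, ValueError):
    """An invalid parameter value or combination of settings."""


class AtlasPlacementError(NeurocrossError, RuntimeError):
    """The atlas generator could not place masks under the overlap cap."""


class PairingError(NeurocrossError, ValueError):
    """Two time-series objects cannot be combined into a pseudo-subject."""


class EstimationError(NeurocrossError, RuntimeError):
    """A network-matrix estimate could not be computed (e.g. singular covariance)."""


class SelectionError(NeurocrossError, RuntimeError):
    """Atlas matching failed to select a component for a network."""


class DimensionalityError(NeurocrossError, ValueError):
    """Decomposition rank exceeds what the data support."""


class ResamplingError(NeurocrossError, ValueError):
    """Group sizes too small for drop-one-out resampling."""


class ComparisonError(NeurocrossError, ValueError):
    """Two results are not comparable (different nodes or settings)."""


class LoaderError(NeurocrossError, ValueError):
    """A cohort directory is missing files or internally inconsistent."""
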