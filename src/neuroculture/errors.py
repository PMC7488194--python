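"""Exception types shared across the package."""


class NeurocultureError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NeurocultureError):
    """Invalid pattern/run configuration (bad kind, diameter, scale ...)."""


class GeometryError(NeurocultureError):
    """Invalid geometric query, e.g. a ray cast from inside an obstacle."""


class PackingError(NeurocultureError):
    """Rejection sampling could not place the requested number of neurons."""


class GrowthError(NeurocultureError):
    """Axon tracing failed (pathological corner with unbounded reflections)."""


class EstimationError(NeurocultureError):
    """Not enough data for a statistical estimate (e.g. too-short sequences)."""


class NumericalError(NeurocultureError):
    """Non-finite state encountered during integration."""
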