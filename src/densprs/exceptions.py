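"""Package-wide exception types."""


class DensPrsError(Exception):
    """Base class for all package errors."""


class SimulationError(DensPrsError):
    """The synthetic generator could not satisfy the requested design."""


class ValidationError(DensPrsError):
    """An input table violates its schema."""


class ConvergenceError(DensPrsError):
    """A model fit failed to converge or showed complete separation."""
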