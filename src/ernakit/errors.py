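"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter or protocol setting is invalid or inconsistent."""


class StateError(ValueError):
    """A dynamical state variable is invalid (NaN, out of bounds)."""


class DegenerateSynapseError(ValueError):
    """A synapse produced zero first-pulse release; fidelity is undefined."""


class CalibrationError(RuntimeError):
    """Synapse calibration could not bracket the requested fidelity."""

    def __init__(self, message: str, bracket: tuple | None = None):
        super().__init__(message)
        self.bracket = bracket


class InsufficientBaselineError(ValueError):
    """Pre-stimulation window too short (or degenerate) for normalization."""


class ProtocolError(ValueError):
    """Pulse-time bookkeeping is malformed (non-increasing, overlapping)."""


class NumericalInstabilityError(FloatingPointError):
    """Membrane integration diverged; usually the time step is too coarse."""


class UndefinedDynamicsError(ValueError):
    """Peak-dynamics ratio undefined (missing or zero first-pulse peak)."""


class DependencyError(RuntimeError):
    """An experiment stage is missing its upstream outputs."""
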