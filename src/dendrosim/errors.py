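"""Exception hierarchy shared across the package."""


class DendrosimError(Exception):
    """Base class for all package errors."""


class StructuralError(DendrosimError, ValueError):
    """Morphology violates a structural invariant (cycle, orphan, bad geometry)."""


class DomainError(DendrosimError, ValueError):
    """A request is outside the valid domain (e.g. distance beyond the tree)."""


class ConfigError(DendrosimError, ValueError):
    """Invalid configuration value or key."""


class UnsupportedModulationError(DendrosimError, ValueError):
    """Neuromodulation applied to a mechanism that does not support it."""


class IntegrationError(DendrosimError, RuntimeError):
    """The integrator produced a non-finite state."""

    def __init__(self, time_ms: float, compartment: int):
        self.time_ms = time_ms
        self.compartment = compartment
        super().__init__(
            f"non-finite state at t={time_ms:.4f} ms in compartment {compartment}"
        )
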