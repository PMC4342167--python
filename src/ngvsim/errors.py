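"""Exception hierarchy.

``ModelDomainError`` marks states outside the model's physical domain
(negative concentrations, exhausted cofactor pools, hemoglobin
over-saturation); ``ConfigError`` marks invalid configuration or parameter
input; ``SolverError`` marks integration or root-finding failures.
"""

__all__ = ["NgvError", "ModelDomainError", "ConfigError", "SolverError"]


class NgvError(Exception):
    """Base class for all package errors."""


class ModelDomainError(NgvError, ValueError):
    """A state or argument lies outside the model's physical domain."""


class ConfigError(NgvError, ValueError):
    """Invalid configuration, parameter name or file content."""


class SolverError(NgvError, RuntimeError):
    """Numerical failure while integrating or solving for a steady state."""

    def __init__(self, message: str, *, t: float | None = None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state
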