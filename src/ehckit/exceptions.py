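"""Exception hierarchy for ehckit."""


class EhcKitError(Exception):
    """Base class for all ehckit errors."""


class ValidationError(EhcKitError, ValueError):
    """A parameter set violates a model invariant."""


class IntegrationError(EhcKitError, RuntimeError):
    """The ODE solver failed to meet its tolerances."""


class ExtrapolationError(EhcKitError, RuntimeError):
    """A terminal-phase extrapolation is undefined (non-decaying tail)."""


class DivergenceError(EhcKitError, ArithmeticError):
    """A closed-form AUC does not converge (non-decaying peak envelope)."""
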