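"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An input parameter is outside its valid range."""


class BlowupError(RuntimeError):
    """Blow-up / no unique equilibrium.

    Raised when the mean-field denominator 1 - (n-1)mCP is non-positive,
    when the interaction matrix is (numerically) singular, or when a
    trajectory exceeds the divergence cap during integration.
    """


class InfeasiblePulseError(ValueError):
    """A pulse perturbation would push a species density to zero or below."""


class ExperimentError(RuntimeError):
    """An experiment could not be completed (e.g. feasibility rejection cap hit)."""
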