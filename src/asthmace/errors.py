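"""Package exception hierarchy."""


class AsthmaceError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(AsthmaceError):
    """A model configuration is malformed or fails validation.

    ``errors`` carries one message per violated invariant, each prefixed
    with the configuration path of the offending entry.
    """

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class MatrixValidationError(AsthmaceError):
    """A transition matrix violates row-stochasticity or state structure."""


class InfeasibleParametersError(AsthmaceError):
    """A parameter set forces a transition row outside the probability simplex."""


class ThresholdNotFoundError(AsthmaceError):
    """No price in the searched interval attains the target ICER."""
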