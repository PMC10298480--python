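"""Exception hierarchy for the gbsconcord pipeline."""


class GbsConcordError(Exception):
    """Base class for all package errors."""


class ConfigError(GbsConcordError, ValueError):
    """A configuration field is missing, out of range, or unknown."""


class InputError(GbsConcordError, ValueError):
    """Malformed input data (sequences, tables, mismatched samples)."""


class ParameterError(GbsConcordError, ValueError):
    """An operation parameter is outside its valid range."""


class ConvergenceError(GbsConcordError, RuntimeError):
    """MCMC chains failed a convergence screen.

    Carries the list of offending parameter names in ``parameters``.
    """

    def __init__(self, message: str, parameters=None):
        super().__init__(message)
        self.parameters = list(parameters or [])
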