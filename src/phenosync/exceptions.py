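"""Exception hierarchy shared across phenosync modules."""


class PhenosyncError(Exception):
    """Base class for all phenosync errors."""


class InvalidParameterError(PhenosyncError, ValueError):
    """A parameter is outside its documented domain."""


class MissingDataError(PhenosyncError):
    """A computation window is not fully covered by the input series."""


class ResolutionError(PhenosyncError):
    """A sub-daily series has an unusable time step."""


class DegenerateInputError(PhenosyncError):
    """Input has no variance (or too few points) for the requested statistic."""


class ConvergenceWarning(UserWarning):
    """An MCMC run failed its convergence diagnostic."""
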