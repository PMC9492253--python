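"""Exception hierarchy for the pmfpath pipeline.

Every stage raises a subclass of :class:`PmfPathError` so callers can
distinguish pipeline failures from programming errors.
"""


class PmfPathError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PmfPathError, ValueError):
    """Invalid user-supplied configuration (degenerate domain, bad spacing...)."""


class GenerationError(PmfPathError, RuntimeError):
    """Synthetic-surface construction failed (no stationary point found...)."""


class FormatError(PmfPathError, ValueError):
    """Malformed input file; message names the file and line."""


class EmptyHistogramError(PmfPathError, ValueError):
    """All samples fell outside the requested bin range."""


class ConvergenceError(PmfPathError, RuntimeError):
    """Iterative solver hit its iteration budget.

    Carries the last iterate in :attr:`last_result` for inspection.
    """

    def __init__(self, message, last_result=None):
        super().__init__(message)
        self.last_result = last_result


class MaskedRegionError(PmfPathError, ValueError):
    """A query touched unsampled (masked) bins of a PMF grid."""


class ConnectivityError(PmfPathError, RuntimeError):
    """The snippet graph does not connect the requested start and end minima."""


class ProfileError(PmfPathError, ValueError):
    """A 1D profile violates the alternating valley/peak structure."""


class FitError(PmfPathError, RuntimeError):
    """Curvature fit failed (stationary point escaped the fit window)."""


class ClassificationError(PmfPathError, RuntimeError):
    """Curvature fit found the wrong concavity for the declared extremum kind."""


class ChainOverflowError(PmfPathError, FloatingPointError):
    """Rate dynamic range exceeds what the ODE integrator can represent.

    Use :func:`pmfpath.rates.rate_limiting_bound` instead; the resulting
    relative rate is then an upper bound and is flagged as such.
    """


class HorizonError(PmfPathError, RuntimeError):
    """Occupancy did not absorb into the final state within the horizon."""
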