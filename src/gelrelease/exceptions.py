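"""Exception hierarchy for gelrelease."""


class GelReleaseError(Exception):
    """Base class for all gelrelease errors."""


class InvalidParameterError(GelReleaseError, ValueError):
    """A physical parameter, geometry or discretization value is invalid."""


class MassBalanceError(GelReleaseError, RuntimeError):
    """The solver produced a physically impossible mass balance
    (e.g. negative released mass beyond numerical tolerance)."""


class InsufficientDataError(GelReleaseError, ValueError):
    """Too few usable data points for the requested fit."""


class UndefinedStatisticError(GelReleaseError, ValueError):
    """A statistic is undefined for the given input (e.g. R^2 on a
    constant observed series)."""


class EstimationFailureError(GelReleaseError, RuntimeError):
    """The parameter search could not produce a single valid candidate."""


class ParseError(GelReleaseError, ValueError):
    """A data or configuration file failed validation; the message lists
    the offending lines or keys."""


class AccuracyWarning(UserWarning):
    """A numerical-accuracy bound was exceeded (not fatal)."""


class DataQualityWarning(UserWarning):
    """Measured data violate a soft expectation (e.g. cumulative release
    above 100%)."""


class IdentifiabilityWarning(UserWarning):
    """A parameter direction of the objective is nearly flat; the estimate
    along it is weakly constrained by the data."""
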