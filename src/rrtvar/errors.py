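"""Exception types shared across the package."""


class RRTVarError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(RRTVarError, ValueError):
    """A population specification is malformed (e.g. covariance not PD)."""


class InvalidParameterError(RRTVarError, ValueError):
    """A scrambling-model or estimator parameter is out of its domain."""


class InsufficientDataError(RRTVarError, ValueError):
    """Too few units to compute the requested statistic."""


class DegeneratePopulationError(RRTVarError, ValueError):
    """A moment ratio is undefined (zero variance or zero mean margin)."""


class DegenerateModelError(RRTVarError, ValueError):
    """Model constants collapse (non-positive unscrambling scale)."""


class IncompleteMomentsError(RRTVarError, KeyError):
    """A required standardized moment is missing from the moment table."""


class SingularSystemError(RRTVarError, ValueError):
    """The normal equations for the optimal constants are singular."""


class OracleFailureError(RRTVarError, RuntimeError):
    """The numerical delta-method oracle produced non-finite derivatives."""
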