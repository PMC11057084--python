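"""Exception hierarchy shared across the package."""


class SummrError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SummrError):
    """A required column is missing or a file does not match the expected layout."""


class ValidationError(SummrError):
    """Input values violate a documented invariant (se <= 0, EAF outside (0,1), ...)."""


class InsufficientInstrumentsError(SummrError):
    """Too few instruments for the requested estimator."""


class UndefinedRatioError(SummrError):
    """Wald ratio requested with a zero SNP-exposure effect."""


class UnderdeterminedModelError(SummrError):
    """Multivariable fit with no more instruments than exposures."""


class CollinearityError(SummrError):
    """Rank-deficient multivariable design; exposures need lasso pre-selection."""


class DegenerateRegionError(SummrError):
    """Colocalization region with fewer than two shared variants."""


class DegenerateWeightsError(SummrError):
    """TWAS weight vector with (numerically) zero LD-weighted norm."""
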