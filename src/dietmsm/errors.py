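"""Exception types shared across the pipeline stages."""


class DietMSMError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(DietMSMError):
    """A simulation or pipeline configuration violates its invariants."""


class ScoringError(DietMSMError):
    """An intake profile is missing a field required by a diet index."""


class DegenerateMedianError(DietMSMError):
    """Median-split scoring requested on a cohort too small to define medians."""


class RankingError(DietMSMError):
    """Quantile ranking requested with fewer subjects than quantile groups."""


class DegenerateDistributionError(DietMSMError):
    """Quantile binning requested on a constant (zero-spread) vector."""


class DataIntegrityError(DietMSMError):
    """Input tables violate structural assumptions (duplicate keys, impossible dates)."""


class PositivityError(DietMSMError):
    """A denominator treatment/censoring probability is numerically zero."""


class FittingError(DietMSMError):
    """A weight or outcome model could not be fit (separation, no events, ...)."""


class PipelineError(DietMSMError):
    """A CLI stage is missing an upstream output or got a malformed schema."""
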