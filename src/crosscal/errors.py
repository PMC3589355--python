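"""Exception hierarchy shared across the package."""


class CrossCalError(Exception):
    """Base class for all crosscal errors."""


class ConfigurationError(CrossCalError):
    """Invalid user-supplied configuration (thresholds, proportions, schemes)."""


class InsufficientDataError(CrossCalError):
    """Too few retained pairs/subjects for the requested estimator."""


class DegenerateFitError(CrossCalError):
    """The data admit no unique line (zero covariance, constant column, ...)."""


class DomainError(CrossCalError):
    """Values outside the mathematical domain of the operation (non-positive
    values under a log or CV-weighted step, missing cells, zero variance)."""
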