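"""Exception hierarchy shared across the package."""


class MethylageError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MethylageError, ValueError):
    """Invalid scenario, population, or model configuration."""


class FormatError(MethylageError, ValueError):
    """A file does not conform to the declared schema (e.g. missing column)."""


class CohortValidationError(MethylageError, ValueError):
    """Cohort content violates a contract (e.g. methylation outside [0, 100])."""


class SingularDesignError(MethylageError, ValueError):
    """A regression design matrix is rank-deficient (e.g. constant covariate)."""


class MatchingFailureError(MethylageError, RuntimeError):
    """No balanced subsample found within the attempt budget.

    Carries the best attempt's balance p-values for diagnostics.
    """

    def __init__(self, message, best_p_age=None, best_p_sex=None, run_index=None):
        super().__init__(message)
        self.best_p_age = best_p_age
        self.best_p_sex = best_p_sex
        self.run_index = run_index
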