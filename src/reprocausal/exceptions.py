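"""Exception hierarchy for the MR pipeline."""


class ReprocausalError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(ReprocausalError):
    """A configuration problem: missing column mapping, unknown preset, bad threshold."""


class ValidationError(ReprocausalError):
    """Input data violates a structural invariant (duplicate ids, r2 out of range, ...)."""


class DomainError(ReprocausalError):
    """An argument is outside the mathematical domain of an operation (e.g. n <= 2)."""


class InsufficientInstrumentsError(ReprocausalError):
    """Too few SNPs for the requested estimator or diagnostic."""


class UndefinedRatioError(ReprocausalError):
    """Wald ratio requested for a SNP with zero exposure effect."""


class DegenerateDesignError(ReprocausalError):
    """Regression design matrix is singular (no variance in instrument strengths)."""


class EmptyDataError(ReprocausalError):
    """A pipeline stage produced zero usable records for an exposure/outcome pair."""
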