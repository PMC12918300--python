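"""Exception taxonomy shared across the package.

All exceptions derive from :class:`GPTurnoverError` so callers can catch the
package's failures with a single except clause while still distinguishing
configuration mistakes from data problems.
"""


class GPTurnoverError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(GPTurnoverError, ValueError):
    """An invalid simulation or panel configuration; names the offending field."""


class ParameterError(GPTurnoverError, ValueError):
    """An invalid argument to an analysis operation (e.g. min_days < 1)."""


class InputError(GPTurnoverError, ValueError):
    """Malformed input data (bad dates, missing columns, empty tables)."""


class ConsistencyError(GPTurnoverError, RuntimeError):
    """An internal invariant was violated (e.g. a workforce member without a spell)."""


class EstimationError(GPTurnoverError, RuntimeError):
    """A model could not be estimated (e.g. rank-deficient design matrix)."""


class ImputationError(GPTurnoverError, ValueError):
    """Imputation impossible: a practice has no observed value to impute from."""


class DomainError(GPTurnoverError, ValueError):
    """A quantity lies outside the mathematically feasible domain."""


class UndefinedValueError(GPTurnoverError, ValueError):
    """The requested statistic is undefined for the given (e.g. empty) input."""
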