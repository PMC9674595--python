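"""Exception hierarchy.

Everything derives from :class:`HncsimError` so callers can catch the
package's failures with a single ``except``; each subclass also derives
from the closest builtin (``ValueError``) so sloppy call sites still fail
loudly rather than silently.
"""


class HncsimError(Exception):
    """Base class for all errors raised by hncsim."""


class ParameterError(HncsimError, ValueError):
    """Invalid or degenerate model parameters."""


class DomainError(HncsimError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class StateError(HncsimError, ValueError):
    """Clone-state vector violating its invariants (e.g. does not sum to N)."""


class DistributionError(HncsimError, ValueError):
    """Probability vector violating normalization or positivity."""


class DataError(HncsimError, ValueError):
    """Malformed empirical input (tables, series)."""


class EstimationError(HncsimError, ValueError):
    """An estimator cannot produce a result from the given data."""


class ExtrapolationError(EstimationError):
    """Observed statistic lies outside the calibrated inversion range."""
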