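"""Exception hierarchy for the neocohort pipeline.

Every stage raises a subclass of :class:`NeocohortError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class NeocohortError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(NeocohortError, ValueError):
    """An argument is outside its documented domain."""


class ConsistencyError(NeocohortError):
    """Input records contradict each other (e.g. reference residue mismatch)."""


class FormatError(NeocohortError):
    """A file does not conform to its declared format."""


class CoverageError(NeocohortError):
    """An HLA allele cannot be resolved to any scoring matrix."""


class UnsupportedClassificationError(NeocohortError):
    """A variant class for which peptide construction is not defined."""


class IncompleteInputError(NeocohortError):
    """A consensus candidate is missing one of its required predictions."""


class ReconciliationError(NeocohortError):
    """Sample universes of two inputs do not reconcile."""


class StratificationError(NeocohortError):
    """A subgroup comparison has fewer than two usable levels."""


class UndefinedCorrelationError(NeocohortError):
    """Correlation requested on a rank vector with zero variance."""
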