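"""Exception hierarchy shared across the package.

Everything derives from :class:`SFAError` so callers can catch pipeline
failures wholesale; the leaf classes mirror the distinct error contracts of
the individual operations (schema vs. validation vs. fitting, ...).
"""


class SFAError(Exception):
    """Base class for all errors raised by sfascreen."""


class SchemaError(SFAError, ValueError):
    """A column-mapping config is missing a mandatory entry."""


class InputError(SFAError, ValueError):
    """An input file is empty or structurally unusable."""


class ValidationError(SFAError, ValueError):
    """A record violates a domain invariant (bounds, labels, signs)."""


class ParseError(SFAError, ValueError):
    """A FreeSurfer stats file does not follow the expected dialect."""


class DomainError(SFAError, ValueError):
    """A numeric argument is outside its mathematical domain (e.g. TIV <= 0)."""


class FitError(SFAError, RuntimeError):
    """A model cannot be fitted (too few records, singular design)."""


class EvaluationError(SFAError, RuntimeError):
    """Cross-validated evaluation is impossible for the requested split."""


class PredictionError(SFAError, ValueError):
    """A prediction request lacks a required feature."""


class RankingError(SFAError, RuntimeError):
    """Feature ranking is undefined (e.g. constant outcome)."""


class VoteError(SFAError, RuntimeError):
    """No finite residual is available to vote on."""


class ClassificationError(SFAError, RuntimeError):
    """A subject has no usable test for classification."""


class LeakageError(SFAError, RuntimeError):
    """Training and evaluation subjects overlap."""


class UnsupportedOperationError(SFAError, RuntimeError):
    """The operation only applies to synthetic datasets."""
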