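"""Exception hierarchy for sigsel.

All package errors derive from :class:`SigselError` so callers can catch
one base class; the subclasses mirror the distinct failure modes of the
pipeline (bad structures, bad usage, numerical domain violations, ...).
"""


class SigselError(Exception):
    """Base class for all sigsel errors."""


class StructureError(SigselError):
    """A SMILES string could not be parsed or standardized."""


class UsageError(SigselError):
    """An operation was called with arguments violating its contract."""


class DomainError(SigselError):
    """A numeric input lies outside the mathematical domain of an operation."""


class UndefinedError(SigselError):
    """A quantity is undefined for the given input (e.g. selectivity of a
    single-point compound, R^2 with zero-variance truth)."""


class MembershipError(SigselError):
    """A compound profile is not eligible for the requested dataset."""


class SelectionError(SigselError):
    """Feature selection removed every feature."""


class CompatibilityError(SigselError):
    """A persisted model or representation does not match what the caller
    expects (version stamp or representation kind mismatch)."""


class UnsupportedModelError(SigselError):
    """The fitted model does not expose the requested capability
    (e.g. impurity importances on SVM/kNN)."""


class GenerationError(SigselError):
    """The synthetic library generator could not satisfy the requested
    configuration."""
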