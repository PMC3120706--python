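"""Typed exception hierarchy.

Every error the library raises deliberately derives from :class:`FamgramError`
so callers (and the CLI) can map failures to exit codes without string
matching.
"""


class FamgramError(Exception):
    """Base class for all famgram errors."""


class ParameterError(FamgramError, ValueError):
    """An argument violates a documented precondition."""


class FastaFormatError(FamgramError):
    """Malformed FASTA input (empty sequence, duplicate id, ...)."""


class LabelTableError(FamgramError):
    """Malformed or self-contradictory id-to-family table."""


class EmptyInputError(FamgramError):
    """An operation received, or would produce, an empty dataset."""


class TrainingError(FamgramError):
    """The training set cannot support model fitting (e.g. one class)."""


class CompatibilityError(FamgramError):
    """A model and an input disagree on the feature-space layout."""


class UndefinedMetricError(FamgramError):
    """A requested metric has a zero denominator and is undefined."""
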