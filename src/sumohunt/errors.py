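"""Exception hierarchy.

Each error family carries a distinct ``exit_code`` so the command-line layer
can map failures to stable, scriptable process exit statuses.
"""


class SumohuntError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParseError(SumohuntError):
    """Malformed input text (AAIndex entry, sites file, ARFF/CSV)."""

    exit_code = 3


class ValidationError(SumohuntError):
    """Structurally parsed input that violates a domain invariant."""

    exit_code = 4


class EncodingError(SumohuntError):
    """A residue or window that cannot be mapped to feature values."""

    exit_code = 5


class WindowError(SumohuntError):
    """Window extraction at a position that is not a lysine."""

    exit_code = 6


class AnnotationError(SumohuntError):
    """A site annotation inconsistent with its protein sequence."""

    exit_code = 7


class BalanceError(SumohuntError):
    """Class balancing with too few negatives."""

    exit_code = 8


class TrainingError(SumohuntError):
    """Untrainable dataset (single class, too small) or bad parameters."""

    exit_code = 9


class PredictionError(SumohuntError):
    """Feature-vector/model dimensionality mismatch."""

    exit_code = 10


class SplitError(SumohuntError):
    """Degenerate train/test split or fold count."""

    exit_code = 11


class MetricsError(SumohuntError):
    """Confusion counts from which a requested metric is undefined."""

    exit_code = 12


class DataError(SumohuntError):
    """Packaged data file missing, corrupt, or failing its checksum."""

    exit_code = 13


class ConstructionError(SumohuntError):
    """A frequency matrix from which no valid window layout exists."""

    exit_code = 14
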