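"""Exception hierarchy.

Every error raised by mutscan derives from :class:`MutscanError` so callers
can catch the package's failures with a single except clause while still
distinguishing parse, validation, training and configuration problems.
"""


class MutscanError(Exception):
    """Base class for all mutscan errors."""


class FastaParseError(MutscanError):
    """Malformed FASTA input (empty record, record without header, ...)."""


class SequenceValidationError(MutscanError):
    """A sequence violates the {A,C,G,T,N} alphabet or is empty."""


class MutationTableError(MutscanError):
    """Mutation table is missing columns or contains unusable rows."""


class ConsistencyError(MutscanError):
    """A mutation record's reference allele disagrees with the sequence."""


class ConflictError(MutscanError):
    """Two mutation records assign different alternate alleles to one site."""


class DatasetError(MutscanError):
    """A labeled dataset invariant is broken (empty class, duplicate id)."""


class ParameterError(MutscanError):
    """An argument is outside its documented domain."""


class TrainingError(MutscanError):
    """Training cannot proceed (single-class labels, too few samples)."""


class DivergenceError(TrainingError):
    """Loss became non-finite during training; carries the epoch index."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")


class InferenceError(MutscanError):
    """Inputs at prediction time are inconsistent with the fitted model."""


class StratificationError(MutscanError):
    """A split or fold lost one of the two classes."""


class ConfigError(MutscanError):
    """Run configuration is invalid (both or neither input source, ...)."""
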