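"""Exception hierarchy for taxoclass.

All package errors derive from :class:`TaxoclassError` so callers can catch
the whole family with one clause; each stage raises the most specific class.
"""


class TaxoclassError(Exception):
    """Base class for all taxoclass errors."""


# -- taxonomy -----------------------------------------------------------------

class CycleError(TaxoclassError):
    """A parent chain revisits a taxid."""


class OrphanParentError(TaxoclassError):
    """A node names a parent taxid that is not in the record set."""


class RankOrderError(TaxoclassError):
    """A parent/child pair violates the canonical rank order."""


class IncompleteLineageError(TaxoclassError):
    """A species lineage skips one of the six canonical ranks."""


class UnknownTaxonError(TaxoclassError):
    """A taxid is not present in the taxonomy."""


# -- curation -----------------------------------------------------------------

class MixedSpeciesError(TaxoclassError):
    """Assembly records passed to a per-species stage span several species."""


class DegenerateSequenceError(TaxoclassError):
    """Every fragment of a sequence set is shorter than the k-mer size."""


class ShapeError(TaxoclassError):
    """A matrix or shape tuple is malformed."""


class SingleClusterError(TaxoclassError):
    """Silhouette requested for a labelling with fewer than two clusters."""


class AlignmentError(TaxoclassError):
    """Cluster labels and records are not aligned one-to-one."""


class EmptyInputError(TaxoclassError):
    """An operation received an empty sequence collection."""


# -- classify -----------------------------------------------------------------

class AlphabetError(TaxoclassError):
    """A read contains characters outside the ACGTN alphabet."""


class SingleLabelError(TaxoclassError):
    """Profile training needs at least two labels."""


class EmptyAllowedError(TaxoclassError):
    """The allowed-label restriction excludes every model label."""


class FormatError(TaxoclassError):
    """A prediction file does not follow its declared dialect."""


# -- hierarchy ----------------------------------------------------------------

class MissingModelError(TaxoclassError):
    """A hierarchical strategy lacks a required component model."""


# -- evaluate -----------------------------------------------------------------

class MissingTruthError(TaxoclassError):
    """A prediction has no ground-truth entry."""


class EmptyMatrixError(TaxoclassError):
    """A confusion matrix holds no counts."""


class NoUnseenReadsError(TaxoclassError):
    """No read's true taxon falls outside the reference set at the rank."""


# -- simulate -----------------------------------------------------------------

class ConfigError(TaxoclassError):
    """A simulation configuration violates its invariants."""


class ShortSequenceError(TaxoclassError):
    """No source sequence is long enough to draw a read from."""


class EmptySpeciesError(TaxoclassError):
    """A species has no reads to sample from."""
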