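"""Exception hierarchy for the protein-word toolkit.

Every error raised by the library derives from :class:`PwwError` so callers
can catch the whole family with one clause; the concrete subclasses mirror
the failure modes of each pipeline stage.
"""


class PwwError(Exception):
    """Base class for all protein-wordwise errors."""


# --- sequence / backend layer -------------------------------------------------

class NoncanonicalResidue(PwwError):
    """Sequence contains a character outside the 20 canonical amino acids."""


class LengthOutOfRange(PwwError):
    """Sequence length falls outside the configured [min_len, max_len] window."""


class BackendUnavailable(PwwError):
    """A real language-model backend was requested but is not installed."""


class MalformedFasta(PwwError):
    """FASTA input could not be parsed."""


# --- synthetic generator ------------------------------------------------------

class SpecOutOfRange(PwwError):
    """A planted-word specification violates position/gap constraints."""


# --- binarization / segmentation ----------------------------------------------

class EmptyMatrix(PwwError):
    """Attention matrix is empty or smaller than 2 x 2."""


# --- alphabet / dictionary ----------------------------------------------------

class UnknownResidue(PwwError):
    """A character has no image under the degenerate alphabet."""


class EmptyCorpus(PwwError):
    """Dictionary construction requires at least one sequence."""


class AlphabetMismatch(PwwError):
    """Dictionaries built over different degenerate alphabets were combined."""


class LengthInfeasible(PwwError):
    """A requested k-mer length exceeds every sequence in the corpus."""


# --- metrics ------------------------------------------------------------------

class NoFunctionalResidues(PwwError):
    """Coverage is undefined: the sequence has no annotated functional residue."""


class NoWords(PwwError):
    """A per-word statistic was requested for an empty word list."""


class DuplicateAnnotation(PwwError):
    """The same (sequence, position) pair was annotated twice."""


class PositionOutOfRange(PwwError):
    """A 1-based residue position falls outside the sequence or embedding."""


# --- supervised model ---------------------------------------------------------

class LabelDimensionMismatch(PwwError):
    """Label vectors do not match the classifier's number of classes."""
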