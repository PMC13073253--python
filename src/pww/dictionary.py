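"""Word dictionaries: frequency-thresholded construction, lookup, controls.

A dictionary maps degenerate word literals to document frequencies over a
corpus.  Construction (multi-sequence mode) retains a literal iff the
fraction of distinct sequences containing it meets a per-length threshold;
lookup (single-sequence mode) keeps a raw word iff its degenerate form is an
exact key of any supplied dictionary.  A random-k-mer dictionary with a
matched length distribution serves as the negative control.

Per-length retention thresholds (fraction of corpus sequences):
5 residues: 5%; 6 residues: 2.5%; 7-11 residues: 0.15%; 12-20: 0.3%.
Comparison is inclusive (ties at the threshold are retained) and frequency
is document frequency -- the number of distinct sequences containing the
word at least once, not its token count.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .alphabet import DegenerateAlphabet, degenerate, load_alphabet
from .errors import AlphabetMismatch, EmptyCorpus, LengthInfeasible
from .types import GAP_CHAR, ProteinSequence, ProteinWord


def residue_count(literal: str) -> int:
    """Number of residues in a (possibly degenerate, possibly gapped) literal."""
    return len(literal) - literal.count(GAP_CHAR)


@dataclass(frozen=True)
class FrequencyThresholds:
    """Per-length document-frequency retention fractions."""

    len5: float = 0.05
    len6: float = 0.025
    len7_11: float = 0.0015
    len12_20: float = 0.003

    def for_length(self, n_residues: int) -> float:
        if n_residues <= 5:
            return self.len5
        if n_residues == 6:
            return self.len6
        if n_residues <= 11:
            return self.len7_11
        return self.len12_20


DEFAULT_THRESHOLDS = FrequencyThresholds()

_DICT_COLUMNS = ["literal", "n_residues", "doc_freq", "corpus_size", "source"]


@dataclass
class WordDictionary:
    """Degenerate-literal -> document-frequency map with provenance."""

    entries: dict  # literal -> doc_freq (int)
    corpus_size: int
    source: str = "common"  # or "family", "random_kmer"
    alphabet_name: str = "a12"
    thresholds: FrequencyThresholds = field(default_factory=FrequencyThresholds)

    def __contains__(self, literal: str) -> bool:
        return literal in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (lit, residue_count(lit), df, self.corpus_size, self.source)
            for lit, df in self.entries.items()
        ]
        frame = pd.DataFrame(rows, columns=_DICT_COLUMNS)
        return frame.sort_values("literal", kind="mergesort").reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path, alphabet_name: str = "a12",
        thresholds: FrequencyThresholds | None = None,
    ) -> "WordDictionary":
        frame = pd.read_csv(path, sep="\t")
        corpus_size = int(frame["corpus_size"].iloc[0]) if len(frame) else 0
        source = str(frame["source"].iloc[0]) if len(frame) else "common"
        return cls(
            entries=dict(zip(frame["literal"], frame["doc_freq"].astype(int))),
            corpus_size=corpus_size,
            source=source,
            alphabet_name=alphabet_name,
            thresholds=thresholds or DEFAULT_THRESHOLDS,
        )


def build_dictionary(
    word_lists: list[list[ProteinWord]],
    alphabet: DegenerateAlphabet | None = None,
    thresholds: FrequencyThresholds | None = None,
    source: str = "common",
) -> WordDictionary:
    """Multi-sequence mode: degenerate, count document frequency, threshold.

    ``word_lists`` holds one word list per corpus sequence.  A literal's
    document frequency is the number of lists in which it occurs at least
    once; it is retained iff ``doc_freq / corpus_size >= threshold(length)``.
    """
    if not word_lists:
        raise EmptyCorpus("dictionary construction needs at least one sequence")
    alphabet = alphabet or load_alphabet("a12")
    thresholds = thresholds or DEFAULT_THRESHOLDS
    corpus_size = len(word_lists)
    doc_freq: dict[str, int] = {}
    for words in word_lists:
        for lit in {degenerate(w, alphabet) for w in words}:
            doc_freq[lit] = doc_freq.get(lit, 0) + 1
    entries = {
        lit: df
        for lit, df in doc_freq.items()
        if df / corpus_size >= thresholds.for_length(residue_count(lit))
    }
    return WordDictionary(
        entries=entries,
        corpus_size=corpus_size,
        source=source,
        alphabet_name=alphabet.name,
        thresholds=thresholds,
    )


def lookup(
    raw_words: list[ProteinWord],
    dictionaries: list[WordDictionary],
    alphabet: DegenerateAlphabet | None = None,
    with_sources: bool = False,
):
    """Single-sequence mode: keep raw words found in any dictionary.

    With an empty dictionary list the call degrades to "raw mode" and passes
    every word through (the no-dictionary ablation).  All dictionaries must
    share the alphabet used for degeneration.
    """
    alphabet = alphabet or load_alphabet("a12")
    for d in dictionaries:
        if d.alphabet_name != alphabet.name:
            raise AlphabetMismatch(
                f"dictionary built over {d.alphabet_name!r}, lookup uses {alphabet.name!r}"
            )
    if not dictionaries:
        return [(w, ()) for w in raw_words] if with_sources else list(raw_words)
    kept = []
    for w in raw_words:
        lit = degenerate(w, alphabet)
        sources = tuple(d.source for d in dictionaries if lit in d)
        if sources:
            kept.append((w, sources) if with_sources else w)
    return kept


def random_kmer_dictionary(
    corpus: list[ProteinSequence],
    length_distribution: dict[int, int],
    alphabet: DegenerateAlphabet | None = None,
    seed: int = 0,
    return_draws: bool = False,
):
    """Control dictionary: contiguous subsequences sampled at matched lengths.

    For each requested length, subsequences are drawn with the host sequence
    chosen uniformly among those long enough and the offset uniform; draws
    are degenerated and deduplicated into a ``random_kmer`` dictionary.
    """
    if not corpus:
        raise EmptyCorpus("random k-mer sampling needs a non-empty corpus")
    alphabet = alphabet or load_alphabet("a12")
    rng = np.random.default_rng(seed)
    max_len = max(len(s) for s in corpus)
    entries: dict[str, int] = {}
    draws: list[str] = []
    for k in sorted(length_distribution):
        count = length_distribution[k]
        hosts = [s for s in corpus if len(s) >= k]
        if not hosts:
            raise LengthInfeasible(
                f"requested length {k} exceeds every corpus sequence (max {max_len})"
            )
        for _ in range(count):
            s = hosts[int(rng.integers(len(hosts)))]
            off = int(rng.integers(0, len(s) - k + 1))
            kmer = s.residues[off : off + k]
            draws.append(kmer)
            lit = alphabet.encode(kmer)
            entries[lit] = entries.get(lit, 0) + 1
    d = WordDictionary(
        entries=entries,
        corpus_size=len(corpus),
        source="random_kmer",
        alphabet_name=alphabet.name,
    )
    return (d, draws) if return_draws else d


def peptide_match(
    peptides: list[str],
    dictionary: WordDictionary,
    alphabet: DegenerateAlphabet | None = None,
    unique_forms: bool = False,
) -> list[str]:
    """Keep peptides whose degenerate form is an exact dictionary key.

    Only contiguous words can match a peptide.  With ``unique_forms`` the
    peptides are first deduplicated by degenerate form (duplicates counted
    once).
    """
    alphabet = alphabet or load_alphabet("a12")
    if unique_forms:
        seen: dict[str, str] = {}
        for p in peptides:
            seen.setdefault(alphabet.encode(p), p)
        return [p for form, p in seen.items() if form in dictionary]
    return [p for p in peptides if alphabet.encode(p) in dictionary]


class DictionaryBuilder(BaseEstimator):
    """Estimator wrapper over :func:`build_dictionary`.

    ``fit(X)`` consumes per-sequence word lists and exposes the result as
    the ``dictionary_`` attribute; ``transform``-style filtering lives in
    :func:`lookup`.
    """

    def __init__(
        self,
        alphabet_name: str = "a12",
        thresholds: FrequencyThresholds | None = None,
        source: str = "common",
    ) -> None:
        self.alphabet_name = alphabet_name
        self.thresholds = thresholds
        self.source = source

    def fit(self, X: list[list[ProteinWord]], y=None) -> "DictionaryBuilder":
        alphabet = load_alphabet(self.alphabet_name)
        self.dictionary_ = build_dictionary(
            X,
            alphabet=alphabet,
            thresholds=self.thresholds or DEFAULT_THRESHOLDS,
            source=self.source,
        )
        return self
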