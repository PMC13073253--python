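"""Core domain types: sequences, attention stacks, embeddings and protein words.

A *protein word* is a set of 5-20 residues of one protein, contiguous or
split into at most three runs (two gaps).  A gap may span any number of
unincluded residues and is rendered as ``_`` in the word's literal string.
All residue positions are 1-based and inclusive, in files and in memory.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyMatrix,
    LengthOutOfRange,
    NoncanonicalResidue,
)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHAR = "_"

#: Hard sequence-length window of the reference language-model backend.
MAX_SEQ_LEN = 1024
DEFAULT_MIN_SEQ_LEN = 50


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid sequence over the 20-letter canonical alphabet."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    def __post_init__(self) -> None:
        if not isinstance(self.residues, str):
            raise TypeError("residues must be a string")


def validate_sequence(
    seq: ProteinSequence,
    min_len: int = DEFAULT_MIN_SEQ_LEN,
    max_len: int = MAX_SEQ_LEN,
) -> ProteinSequence:
    """Return ``seq`` unchanged iff it is canonical and within the length window.

    Raises
    ------
    NoncanonicalResidue
        If any character is outside the 20-letter alphabet (e.g. ``X``, ``B``).
    LengthOutOfRange
        If the residue count falls outside ``[min_len, max_len]``.
    """
    bad = set(seq.residues) - set(CANONICAL_AA)
    if bad:
        raise NoncanonicalResidue(
            f"sequence {seq.id!r} contains noncanonical residues: {sorted(bad)}"
        )
    if not (min_len <= len(seq) <= max_len):
        raise LengthOutOfRange(
            f"sequence {seq.id!r} has length {len(seq)}, outside [{min_len}, {max_len}]"
        )
    return seq


@dataclass
class AttentionStack:
    """Per-sequence stack of square attention matrices, one per head.

    Matrices are L x L with nonnegative entries, special tokens already
    removed, where L is the residue count of the owning sequence.
    ``head_labels[i]`` is the (layer, head) pair of ``heads[i]``.
    """

    sequence_id: str
    heads: list[np.ndarray]
    head_labels: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.heads:
            raise EmptyMatrix(f"attention stack for {self.sequence_id!r} has no heads")
        L = self.heads[0].shape[0]
        for h in self.heads:
            if h.ndim != 2 or h.shape != (L, L):
                raise EmptyMatrix(
                    f"attention stack for {self.sequence_id!r} has inconsistent shapes"
                )
        if not self.head_labels:
            self.head_labels = [(0, i) for i in range(len(self.heads))]

    @property
    def n_heads(self) -> int:
        return len(self.heads)

    @property
    def length(self) -> int:
        return self.heads[0].shape[0]


@dataclass
class EmbeddingMatrix:
    """L x D matrix of per-residue embeddings (row i-1 is residue i)."""

    sequence_id: str
    rows: np.ndarray

    @property
    def length(self) -> int:
        return self.rows.shape[0]

    @property
    def dim(self) -> int:
        return self.rows.shape[1]


def positions_to_runs(positions: Sequence[int]) -> list[tuple[int, int]]:
    """Collapse sorted 1-based positions into maximal contiguous (start, end) runs."""
    runs: list[tuple[int, int]] = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
        else:
            runs.append((start, prev))
            start = prev = p
    runs.append((start, prev))
    return runs


@dataclass(frozen=True)
class ProteinWord:
    """A 5-20 residue word of one protein with at most two internal gaps."""

    sequence_id: str
    positions: tuple[int, ...]
    literal: str
    source_heads: frozenset[tuple[int, int]] = frozenset()

    @property
    def n_residues(self) -> int:
        return len(self.positions)

    @property
    def runs(self) -> list[tuple[int, int]]:
        return positions_to_runs(self.positions)

    @property
    def gap_count(self) -> int:
        return len(self.runs) - 1

    @staticmethod
    def from_positions(
        sequence_id: str,
        positions: Iterable[int],
        residues: str,
        source_heads: Iterable[tuple[int, int]] = (),
    ) -> "ProteinWord":
        """Build a word from 1-based positions and the full parent sequence."""
        pos = tuple(sorted(set(int(p) for p in positions)))
        if not pos:
            raise ValueError("a word needs at least one position")
        if pos[0] < 1 or pos[-1] > len(residues):
            raise ValueError(
                f"positions {pos[0]}..{pos[-1]} outside sequence of length {len(residues)}"
            )
        runs = positions_to_runs(pos)
        literal = GAP_CHAR.join(residues[s - 1 : e] for s, e in runs)
        return ProteinWord(
            sequence_id=sequence_id,
            positions=pos,
            literal=literal,
            source_heads=frozenset(source_heads),
        )


def word_sort_key(word: ProteinWord) -> tuple:
    """Deterministic ordering: first position, then residue count, then literal."""
    return (word.positions[0], word.n_residues, word.literal)
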