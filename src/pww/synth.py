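"""Synthetic fixtures: attention stacks with planted word-blocks and labeled corpora.

The generator plays the role of the language model in tests: it produces
attention stacks in which a chosen set of residue positions forms a dense
high-attention block against a low uniform noise floor, and labeled corpora
in which per-sequence function labels are deterministic functions of planted
"signal words".  Everything is seeded; identical inputs and seed give
bit-identical output.

Signal entries are drawn from Uniform(0.8*s, s) and noise from
Uniform(0, noise_level), keeping the binarizer's lower cutoff (10% of the
matrix range) cleanly between the two populations.  Planted blocks are
written symmetrically so directed and symmetrized graph variants agree on
fixtures.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpecOutOfRange
from .plm import SyntheticBackend, _stable_seed
from .types import (
    AttentionStack,
    CANONICAL_AA,
    ProteinSequence,
    ProteinWord,
    positions_to_runs,
)


@dataclass(frozen=True)
class PlantedWordSpec:
    """A residue set to be expressed as a dense attention block.

    positions are 1-based, 5-20 of them, with at most two gaps; the block is
    written on the heads listed in ``head_indices`` (0-based).
    """

    positions: tuple[int, ...]
    signal_strength: float = 1.0
    head_indices: tuple[int, ...] = (0,)

    def validate(self, L: int) -> None:
        pos = self.positions
        if len(pos) < 5 or len(pos) > 20:
            raise SpecOutOfRange(f"planted word has {len(pos)} residues, need 5-20")
        if sorted(set(pos)) != list(pos):
            raise SpecOutOfRange("positions must be strictly increasing")
        if pos[0] < 1 or pos[-1] > L:
            raise SpecOutOfRange(f"positions outside [1, {L}]")
        if len(positions_to_runs(pos)) - 1 > 2:
            raise SpecOutOfRange("planted word has more than two gaps")
        if self.signal_strength <= 0:
            raise SpecOutOfRange("signal_strength must be positive")


def make_planted_attention(
    L: int,
    specs: list[PlantedWordSpec],
    noise_level: float = 0.05,
    n_heads: int = 1,
    seed: int = 0,
) -> AttentionStack:
    """Generate an attention stack with dense blocks planted on noise.

    Off-block entries are Uniform(0, noise_level); within-block entries (both
    orientations) are Uniform(0.8*s, s) on the designated heads.
    """
    for spec in specs:
        spec.validate(L)
        if not (0 <= noise_level < spec.signal_strength):
            raise SpecOutOfRange(
                f"noise_level {noise_level} must lie in [0, signal_strength)"
            )
        if any(h < 0 or h >= n_heads for h in spec.head_indices):
            raise SpecOutOfRange("head index outside stack")
    rng = np.random.default_rng(seed)
    heads = []
    for h in range(n_heads):
        mat = (
            rng.uniform(0.0, noise_level, size=(L, L))
            if noise_level > 0
            else np.zeros((L, L))
        )
        for spec in specs:
            if h not in spec.head_indices:
                continue
            idx = np.array(spec.positions) - 1
            s = spec.signal_strength
            block = rng.uniform(0.8 * s, s, size=(len(idx), len(idx)))
            block = np.maximum(block, block.T)  # symmetric planting
            mat[np.ix_(idx, idx)] = block
        heads.append(mat)
    return AttentionStack(
        sequence_id=f"planted_L{L}",
        heads=heads,
        head_labels=[(0, i) for i in range(n_heads)],
    )


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Conditions for a labeled synthetic corpus.

    Each class has one contiguous signal word (a literal amino-acid string);
    a sequence is positive for class c iff that string occurs in it.  Decoy
    words are random spans of the background registered alongside the signal
    words so that downstream models must discriminate, not just detect.
    ``noise_level`` is the probability of flipping each emitted label after
    assignment (0 keeps labels exactly recomputable from the sequences).
    """

    n_sequences: int = 200
    n_classes: int = 4
    length_range: tuple[int, int] = (60, 120)
    signal_word_length: tuple[int, int] = (6, 10)
    p_positive: float = 0.4
    n_decoys_per_seq: int = 3
    decoy_length: tuple[int, int] = (5, 12)
    noise_level: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class PlantedWord:
    """Registry record of a planted (signal or decoy) word occurrence."""

    seq_id: str
    positions: tuple[int, ...]
    literal: str
    term: str | None  # class term for signal words, None for decoys

    @property
    def is_signal(self) -> bool:
        return self.term is not None


@dataclass
class SyntheticCorpus:
    """A labeled corpus with its ground-truth planted-word registry."""

    spec: SyntheticCorpusSpec
    sequences: list[ProteinSequence]
    terms: list[str]
    signal_words: dict[str, str]  # term -> literal signal string
    labels: dict[str, set[str]]  # seq_id -> positive terms
    registry: dict[str, list[PlantedWord]]

    def words(self, seq_id: str) -> list[ProteinWord]:
        """Ground-truth words (signal + decoys) of one sequence as ProteinWords."""
        seq = next(s for s in self.sequences if s.id == seq_id)
        return [
            ProteinWord.from_positions(seq_id, w.positions, seq.residues)
            for w in self.registry[seq_id]
        ]

    def attention_stack(
        self, seq_id: str, n_heads: int = 2, noise_level: float = 0.05
    ) -> AttentionStack:
        """Planted attention stack expressing every registry word of ``seq_id``."""
        seq = next(s for s in self.sequences if s.id == seq_id)
        specs = [
            PlantedWordSpec(positions=w.positions, head_indices=tuple(range(n_heads)))
            for w in self.registry[seq_id]
        ]
        stack = make_planted_attention(
            L=len(seq),
            specs=specs,
            noise_level=noise_level,
            n_heads=n_heads,
            seed=_stable_seed("corpus-attn", self.spec.seed, seq_id),
        )
        stack.sequence_id = seq_id
        return stack

    def backend(self, embed_dim: int = 32) -> SyntheticBackend:
        """A synthetic embedding backend keyed to this corpus's seed."""
        return SyntheticBackend(
            n_heads=2, embed_dim=embed_dim, seed=self.spec.seed, noise_level=0.05
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


def make_labeled_corpus(spec: SyntheticCorpusSpec) -> SyntheticCorpus:
    """Generate sequences, labels and the planted-word registry.

    Positive sequences literally contain their class's signal word at a
    random offset; signal insertions never overlap each other.  Labels follow
    the occurrence rule exactly, then each label is flipped independently
    with probability ``noise_level``.
    """
    if spec.n_classes < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(spec.seed)
    terms = [f"GO:SYN{c:04d}" for c in range(spec.n_classes)]
    signal_words = {
        t: _random_seq(rng, int(rng.integers(spec.signal_word_length[0],
                                             spec.signal_word_length[1] + 1)))
        for t in terms
    }
    sequences: list[ProteinSequence] = []
    labels: dict[str, set[str]] = {}
    registry: dict[str, list[PlantedWord]] = {}

    for i in range(spec.n_sequences):
        seq_id = f"syn{i:05d}"
        L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        residues = list(_random_seq(rng, L))
        chosen = [t for t in terms if rng.random() < spec.p_positive]
        occupied: list[tuple[int, int]] = []
        planted: list[PlantedWord] = []
        for t in chosen:
            w = signal_words[t]
            for _ in range(200):  # rejection-sample a non-overlapping offset
                off = int(rng.integers(0, L - len(w) + 1))
                span = (off, off + len(w))
                if all(span[1] <= a or span[0] >= b for a, b in occupied):
                    occupied.append(span)
                    residues[off : off + len(w)] = list(w)
                    planted.append(
                        PlantedWord(
                            seq_id=seq_id,
                            positions=tuple(range(off + 1, off + len(w) + 1)),
                            literal=w,
                            term=t,
                        )
                    )
                    break
        for _ in range(spec.n_decoys_per_seq):
            dlen = int(rng.integers(spec.decoy_length[0], spec.decoy_length[1] + 1))
            for _ in range(200):
                off = int(rng.integers(0, L - dlen + 1))
                span = (off, off + dlen)
                if all(span[1] <= a or span[0] >= b for a, b in occupied):
                    occupied.append(span)
                    planted.append(
                        PlantedWord(
                            seq_id=seq_id,
                            positions=tuple(range(off + 1, off + dlen + 1)),
                            literal="".join(residues[off : off + dlen]),
                            term=None,
                        )
                    )
                    break
        seq = ProteinSequence(id=seq_id, residues="".join(residues))
        # labels follow the occurrence rule on the final sequence
        pos_terms = {t for t in terms if signal_words[t] in seq.residues}
        if spec.noise_level > 0:
            flipped = set()
            for t in terms:
                if rng.random() < spec.noise_level:
                    flipped.add(t)
            pos_terms = pos_terms.symmetric_difference(flipped)
        sequences.append(seq)
        labels[seq_id] = pos_terms
        registry[seq_id] = planted
    return SyntheticCorpus(
        spec=spec,
        sequences=sequences,
        terms=terms,
        signal_words=signal_words,
        labels=labels,
        registry=registry,
    )
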