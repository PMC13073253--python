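"""Degenerate (reduced) amino-acid alphabets.

A degenerate alphabet is a total, surjective map from the 20 canonical
amino-acid letters onto K class symbols (reference K = 12, alternate K = 4).
Recoding words into the reduced alphabet lets physicochemically conservative
substitutions match the same dictionary entry; the gap character ``_`` maps
to itself and participates in exact matching (``b_b`` is distinct from
``bb``), while gap *lengths* are ignored because a gap may span any number
of residues.

The class partitions live in ``data/alphabets.json`` so an alternative
grouping can be dropped in without a code change.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .errors import UnknownResidue
from .types import CANONICAL_AA, GAP_CHAR, ProteinWord


@dataclass(frozen=True)
class DegenerateAlphabet:
    """A named total mapping from the 20 canonical letters to K symbols."""

    name: str
    mapping: dict  # letter -> class symbol

    def __post_init__(self) -> None:
        missing = set(CANONICAL_AA) - set(self.mapping)
        if missing:
            raise ValueError(f"alphabet {self.name!r} misses letters {sorted(missing)}")

    @property
    def n_classes(self) -> int:
        return len(set(self.mapping.values()))

    def encode(self, literal: str) -> str:
        """Recode a (possibly gapped) literal; ``_`` is preserved in place.

        Class symbols are fixed points, so encoding is idempotent on
        already-degenerate strings.
        """
        symbols = set(self.mapping.values())
        out = []
        for ch in literal:
            if ch == GAP_CHAR:
                out.append(GAP_CHAR)
            elif ch in self.mapping:
                out.append(self.mapping[ch])
            elif ch in symbols:
                out.append(ch)
            else:
                raise UnknownResidue(
                    f"character {ch!r} has no image in alphabet {self.name!r}"
                )
        return "".join(out)


def load_alphabet(name: str = "a12") -> DegenerateAlphabet:
    """Load a named alphabet from the packaged JSON config."""
    with resources.files("pww.data").joinpath("alphabets.json").open() as f:
        table = json.load(f)
    if name not in table:
        raise KeyError(f"no alphabet named {name!r}; available: {sorted(table)}")
    return DegenerateAlphabet(name=name, mapping=table[name]["mapping"])


def degenerate(word: ProteinWord, alphabet: DegenerateAlphabet) -> str:
    """Degenerate literal of a word; residue count is invariant under recoding."""
    return alphabet.encode(word.literal)
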