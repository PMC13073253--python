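"""Evaluation statistics for predicted protein words.

Per-protein word statistics against residue-level functional annotation:

* coverage       -- fraction of annotated functional residues that lie in
                    the union of predicted word positions (a recall);
* word accuracy  -- fraction of predicted words containing at least one
                    functional residue;
* efficiency     -- distinct covered functional residues divided by the
                    summed residue lengths of all predicted words (word
                    lengths count residues only, not gaps, and are summed
                    with multiplicity; the numerator counts each covered
                    residue once);
* precision      -- functional fraction of the residue union of the words.

Sequence-level GO prediction is scored with the Matthews correlation
coefficient per term ("functional MCC"); a zero denominator yields 0 so the
unweighted mean over terms stays well defined.

All statistics are carried at full precision; round only when reporting.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import NoFunctionalResidues, NoWords
from .types import ProteinWord


@dataclass
class AnnotationSet:
    """Residue-level binary labels and sequence-level GO term labels."""

    residue_labels: dict = field(default_factory=dict)  # (seq_id, pos) -> 0/1
    go_labels: dict = field(default_factory=dict)  # seq_id -> set of terms

    def functional_positions(self, seq_id: str) -> set[int]:
        return {
            pos
            for (sid, pos), lab in self.residue_labels.items()
            if sid == seq_id and lab == 1
        }


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass
class CoverageReport:
    """Bundle of the four word statistics for one protein."""

    n_functional: int
    n_covered: int
    coverage: float
    word_accuracy: float
    precision: float
    efficiency: float
    sum_word_lengths: int


def _functional(ann: AnnotationSet, seq_id: str) -> set[int]:
    func = ann.functional_positions(seq_id)
    if not func:
        raise NoFunctionalResidues(
            f"coverage undefined: {seq_id!r} has no annotated functional residue"
        )
    return func


def _union(words: list[ProteinWord]) -> set[int]:
    out: set[int] = set()
    for w in words:
        out.update(w.positions)
    return out


def coverage(words: list[ProteinWord], ann: AnnotationSet, seq_id: str) -> float:
    """Fraction of functional residues inside the union of word positions."""
    func = _functional(ann, seq_id)
    return len(func & _union(words)) / len(func)


def word_accuracy(words: list[ProteinWord], ann: AnnotationSet, seq_id: str) -> float:
    """Fraction of words containing at least one functional residue."""
    if not words:
        raise NoWords(f"word accuracy undefined for {seq_id!r}: no words")
    func = ann.functional_positions(seq_id)
    hits = sum(1 for w in words if func.intersection(w.positions))
    return hits / len(words)


def efficiency(words: list[ProteinWord], ann: AnnotationSet, seq_id: str) -> float:
    """Distinct covered functional residues over summed word lengths."""
    if not words:
        raise NoWords(f"efficiency undefined for {seq_id!r}: no words")
    func = ann.functional_positions(seq_id)
    covered = func & _union(words)
    total_len = sum(w.n_residues for w in words)
    return len(covered) / total_len


def residue_precision(words: list[ProteinWord], ann: AnnotationSet, seq_id: str) -> float:
    """Functional fraction of the residue union of the predicted words."""
    if not words:
        raise NoWords(f"precision undefined for {seq_id!r}: no words")
    union = _union(words)
    func = ann.functional_positions(seq_id)
    return len(func & union) / len(union)


def coverage_report(
    words: list[ProteinWord], ann: AnnotationSet, seq_id: str
) -> CoverageReport:
    func = _functional(ann, seq_id)
    union = _union(words)
    covered = func & union
    total_len = sum(w.n_residues for w in words)
    return CoverageReport(
        n_functional=len(func),
        n_covered=len(covered),
        coverage=len(covered) / len(func),
        word_accuracy=word_accuracy(words, ann, seq_id),
        precision=len(covered) / len(union) if union else 0.0,
        efficiency=len(covered) / total_len if total_len else 0.0,
        sum_word_lengths=total_len,
    )


def functional_mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient from confusion counts.

    MCC = (TP*TN - FN*FP) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero
    factor in the denominator yields 0.
    """
    num = c.TP * c.TN - c.FN * c.FP
    f1, f2, f3, f4 = c.TP + c.FP, c.TP + c.FN, c.TN + c.FP, c.TN + c.FN
    if 0 in (f1, f2, f3, f4):
        return 0.0
    return num / math.sqrt(f1 * f2) / math.sqrt(f3 * f4)


def mean_functional_mcc(per_term: dict[str, ConfusionCounts]) -> float:
    """Unweighted arithmetic mean of per-term MCCs."""
    if not per_term:
        raise ValueError("need at least one term")
    return sum(functional_mcc(c) for c in per_term.values()) / len(per_term)


def confusion_from_sets(
    predicted: dict[str, set[str]],
    truth: dict[str, set[str]],
    terms: list[str],
) -> dict[str, ConfusionCounts]:
    """Per-term confusion counts from per-sequence predicted/true term sets."""
    out = {}
    for t in terms:
        tp = fp = tn = fn = 0
        for sid, true_terms in truth.items():
            pred = t in predicted.get(sid, set())
            true = t in true_terms
            if pred and true:
                tp += 1
            elif pred:
                fp += 1
            elif true:
                fn += 1
            else:
                tn += 1
        out[t] = ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)
    return out
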