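"""File formats, run configuration, and the end-to-end pipeline driver.

Tabular artifacts are TSV with 1-based inclusive coordinates; dense tensors
go to HDF5; configs round-trip through JSON.  Every TSV written by the
pipeline starts with a comment header recording the package version and a
hash of the run configuration, so fixed-seed reruns are byte-identical and
auditable.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .dictionary import FrequencyThresholds, WordDictionary, lookup
from .errors import (
    DuplicateAnnotation,
    MalformedFasta,
    PositionOutOfRange,
    PwwError,
)
from .metrics import AnnotationSet, coverage_report
from .plm import get_attention
from .segment import BinarizationConfig, LouvainConfig, WordFilterConfig, parse_sequence
from .types import ProteinSequence, ProteinWord, validate_sequence

logger = logging.getLogger("pww")


# ------------------------------------------------------------------ sequences

def read_fasta(path) -> list[ProteinSequence]:
    """Parse a single/multi-record FASTA; validation is deferred."""
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Bio raises assorted ValueErrors
        raise MalformedFasta(f"could not parse {path}: {exc}") from exc
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return [ProteinSequence(id=r.id, residues=str(r.seq).upper()) for r in records]


def write_fasta(sequences: list[ProteinSequence], path) -> None:
    with open(path, "w") as f:
        for s in sequences:
            f.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 60):
                f.write(s.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------- annotations

def read_annotations(path, sequences: list[ProteinSequence] | None = None) -> AnnotationSet:
    """Read residue-level labels (TSV: seq_id, position, label).

    Positions are 1-based; duplicate (seq, position) rows and nonpositive
    positions are rejected, and positions are bounds-checked when the
    sequences are provided.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    lengths = {s.id: len(s) for s in sequences} if sequences else None
    labels: dict = {}
    for row in frame.itertuples(index=False):
        sid, pos, lab = str(row.seq_id), int(row.position), int(row.label)
        if pos < 1:
            raise PositionOutOfRange(f"position {pos} for {sid!r} (1-based)")
        if lengths is not None and sid in lengths and pos > lengths[sid]:
            raise PositionOutOfRange(
                f"position {pos} beyond sequence {sid!r} of length {lengths[sid]}"
            )
        if (sid, pos) in labels:
            raise DuplicateAnnotation(f"duplicate annotation for ({sid!r}, {pos})")
        labels[(sid, pos)] = lab
    return AnnotationSet(residue_labels=labels)


def write_annotations(ann: AnnotationSet, path) -> None:
    rows = sorted((sid, pos, lab) for (sid, pos), lab in ann.residue_labels.items())
    pd.DataFrame(rows, columns=["seq_id", "position", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_go_labels(path) -> dict[str, set[str]]:
    """GO label TSV: seq_id followed by a variable number of term columns."""
    out: dict[str, set[str]] = {}
    with open(path) as f:
        for line in f:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            out[parts[0]] = {t for t in parts[1:] if t}
    return out


def write_go_labels(labels: dict[str, set[str]], path) -> None:
    with open(path, "w") as f:
        for sid in sorted(labels):
            f.write("\t".join([sid, *sorted(labels[sid])]) + "\n")


# ---------------------------------------------------------------------- words

_WORD_COLUMNS = ["seq_id", "positions", "literal", "gap_count", "n_heads"]


def words_to_frame(words: list[ProteinWord]) -> pd.DataFrame:
    rows = [
        (
            w.sequence_id,
            ",".join(str(p) for p in w.positions),
            w.literal,
            w.gap_count,
            len(w.source_heads),
        )
        for w in words
    ]
    return pd.DataFrame(rows, columns=_WORD_COLUMNS)


def write_words(words: list[ProteinWord], path, config: "RunConfig | None" = None) -> None:
    header = f"# pww {__version__} config={config.hash() if config else 'none'}\n"
    with open(path, "w") as f:
        f.write(header)
        words_to_frame(words).to_csv(f, sep="\t", index=False)


def read_words(path, sequences: list[ProteinSequence] | None = None) -> list[ProteinWord]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    residues = {s.id: s.residues for s in sequences} if sequences else {}
    out = []
    for row in frame.itertuples(index=False):
        pos = tuple(int(p) for p in str(row.positions).split(","))
        out.append(
            ProteinWord(
                sequence_id=str(row.seq_id), positions=pos, literal=str(row.literal)
            )
        )
    return out


# --------------------------------------------------------------------- config

@dataclass
class RunConfig:
    """Serializable bundle of every pipeline parameter plus the global seed.

    Defaults equal the reference values of each stage: dual cutoffs
    0.10/0.40/0.60, Louvain gamma 1.0 and dQ 1e-7, 5-20 residues with at
    most 2 gaps, the 12-class alphabet with thresholds 5%/2.5%/0.15%/0.3%,
    and the reference classifier profile.
    """

    binarization: BinarizationConfig = field(default_factory=BinarizationConfig)
    louvain: LouvainConfig = field(default_factory=LouvainConfig)
    word_filter: WordFilterConfig = field(default_factory=WordFilterConfig)
    alphabet_name: str = "a12"
    thresholds: FrequencyThresholds = field(default_factory=FrequencyThresholds)
    min_seq_len: int = 50
    max_seq_len: int = 1024
    seed: int = 0
    verbose: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        return cls(
            binarization=BinarizationConfig(**raw["binarization"]),
            louvain=LouvainConfig(**raw["louvain"]),
            word_filter=WordFilterConfig(**raw["word_filter"]),
            alphabet_name=raw["alphabet_name"],
            thresholds=FrequencyThresholds(**raw["thresholds"]),
            min_seq_len=raw["min_seq_len"],
            max_seq_len=raw["max_seq_len"],
            seed=raw["seed"],
            verbose=raw.get("verbose", False),
        )

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


# ------------------------------------------------------------------- pipeline

def run_pipeline(
    sequences: list[ProteinSequence],
    config: RunConfig,
    backend,
    out_dir,
    dictionaries: list[WordDictionary] | None = None,
    annotations: AnnotationSet | None = None,
    attention_by_id: dict | None = None,
) -> dict:
    """Parse -> (lookup) -> (eval), writing all intermediates to ``out_dir``.

    Attention stacks come from ``attention_by_id`` when given (e.g. an HDF5
    cache pulled into memory), otherwise from the backend.  Sequences that
    fail validation are skipped with a logged warning.  Returns a summary
    dict with per-stage counts.
    """
    from .alphabet import load_alphabet

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alphabet = load_alphabet(config.alphabet_name)
    louvain = dataclasses.replace(config.louvain, seed=config.seed)

    kept_sequences, all_words = [], []
    n_raw = 0
    for seq in sequences:
        try:
            validate_sequence(seq, config.min_seq_len, config.max_seq_len)
        except PwwError as exc:
            logger.warning("skipping %s: %s", seq.id, exc)
            continue
        kept_sequences.append(seq)
        stack = (
            attention_by_id[seq.id]
            if attention_by_id and seq.id in attention_by_id
            else get_attention(seq, backend)
        )
        raw = parse_sequence(seq, stack, config.binarization, louvain, config.word_filter)
        n_raw += len(raw)
        if dictionaries:
            final = lookup(raw, dictionaries, alphabet)
        else:
            if dictionaries is not None:
                logger.warning("no dictionaries supplied; raw mode for %s", seq.id)
            final = raw
        all_words.extend(final)
    logger.info(
        "pipeline: %d/%d sequences kept, %d raw words, %d final words (config %s)",
        len(kept_sequences), len(sequences), n_raw, len(all_words), config.hash(),
    )
    write_words(all_words, out_dir / "words.tsv", config)

    summary = {
        "n_sequences_in": len(sequences),
        "n_sequences_kept": len(kept_sequences),
        "n_raw_words": n_raw,
        "n_final_words": len(all_words),
        "config_hash": config.hash(),
    }
    if annotations is not None:
        by_seq: dict[str, list[ProteinWord]] = {}
        for w in all_words:
            by_seq.setdefault(w.sequence_id, []).append(w)
        rows = []
        for seq in kept_sequences:
            words = by_seq.get(seq.id, [])
            if not words or not annotations.functional_positions(seq.id):
                continue
            rep = coverage_report(words, annotations, seq.id)
            rows.append(
                (seq.id, rep.n_functional, rep.n_covered,
                 round(rep.coverage, 3), round(rep.word_accuracy, 3),
                 round(rep.precision, 3), round(rep.efficiency, 3))
            )
        frame = pd.DataFrame(
            rows,
            columns=["seq_id", "n_functional", "n_covered", "coverage",
                     "word_accuracy", "precision", "efficiency"],
        )
        header = f"# pww {__version__} config={config.hash()}\n"
        with open(out_dir / "report.tsv", "w") as f:
            f.write(header)
            frame.to_csv(f, sep="\t", index=False)
        if len(frame):
            summary["median_coverage"] = float(frame["coverage"].median())
            summary["mean_coverage"] = float(frame["coverage"].mean())
    return summary
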