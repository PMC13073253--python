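# protein-wordwise

Protein words from language-model attention, and word-level function
prediction.

Most tools describe protein function at the domain or motif level.
`protein-wordwise` works at an intermediate unit: the **protein word** — a
set of 5–20 residues of one protein, contiguous or split by at most two
gaps of arbitrary length (rendered `KRPR_K`).  Words are found without any
functional annotation, by reading the pairwise residue attention of a
protein language model: every attention head gives an L × L matrix of
residue–residue weights, and residues that a head binds tightly together
form a word.  The package is aimed at researchers who want residue-level
functional hypotheses (binding sites, catalytic residues) from sequence
alone, and at anyone mapping what a protein language model has learned.

## Method

For each attention head the L × L matrix **A** is binarized with a dual
cutoff: entries below `b = min A + 0.10 · (max A − min A)` are zeroed, and
if more than 40 % of all L² entries survive, entries below the 0.60
nearest-rank quantile of the original values are zeroed as well.  The
binary matrix defines a directed graph on residues (edge *i → j* iff the
binarized value is 1), which is partitioned by Louvain community detection
(resolution γ = 1.0, modularity-gain threshold ΔQ = 10⁻⁷, seeded
multi-restart with a deterministic refinement pass).  Communities of 5–20
residues with ≤ 2 gaps are the sequence's **raw words**; results from all
heads are pooled (the reference ESM2-650M backend exposes 33 × 20 = 660
heads).

Raw words are recoded into a 12-class degenerate alphabet (e.g. the
positively charged R and K share the symbol `b`) and filtered against
**dictionaries**: degenerate words whose document frequency across a
corpus meets per-length thresholds (5 % at length 5, 2.5 % at 6, 0.15 % at
7–11, 0.3 % at 12–20).  Predicted words are scored against residue-level
annotation by coverage (recall over functional residues), word accuracy,
residue precision, and efficiency

    Efficiency = N_covered_residues / Σ_{word ∈ W} L_word .

**Word2Function** maps words to GO terms: each word is embedded as the mean
of its residues' language-model embeddings, a transformer encoder with CLS
readout predicts per-term probabilities (binary cross-entropy, Adam,
cosine learning-rate decay, early stopping), and Integrated Gradients
attributes each predicted-positive term back to the words.  The
smallest top-scoring prefix holding ≥ 0.5 of the positive attribution mass
becomes the term's *functional annotation words*, accumulated into a
reusable word table; new sequences are annotated by exact degenerate match
against that table.  Sequence-level performance is scored with the per-term
Matthews correlation coefficient (functional MCC).

A synthetic backend generates attention stacks with planted word-blocks
and labeled corpora whose GO labels are deterministic functions of planted
signal words, so the full pipeline runs and is tested without model
weights or downloads.  The ESM2 backend activates when the optional
`torch` + `fair-esm` extras are installed.

## Worked example

```python
import numpy as np
from pww import (ProteinSequence, make_planted_attention, PlantedWordSpec,
                 parse_sequence, AnnotationSet, coverage)

rng = np.random.default_rng(0)
seq = ProteinSequence("demo", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100)))
stack = make_planted_attention(
    100, [PlantedWordSpec(positions=tuple(range(10, 18)), head_indices=(0, 1))],
    noise_level=0.05, n_heads=2, seed=1)
stack.sequence_id = "demo"

words = parse_sequence(seq, stack)
print([(w.positions, w.literal) for w in words])
# [((10, 11, 12, 13, 14, 15, 16, 17), 'TPWMPYRP')]

ann = AnnotationSet(residue_labels={("demo", p): 1 for p in range(10, 18)})
print(round(coverage(words, ann, "demo"), 3))
# 1.0
```

The single emitted word is exactly the planted 8-residue block (positions
10–17, literal `TPWMPYRP`, no gaps), and it covers all 8 annotated
functional residues, so functional residue coverage is 1.0.

The same pipeline is available from the shell:

```sh
pww synth corpus --n-sequences 100 --n-classes 4 --attention --out-dir work/
pww parse --fasta work/corpus.fa --attention work/attention.h5 --out work/words.tsv
pww build-dict --words work/words.tsv --out work/dict.tsv
pww lookup --words work/words.tsv --dict work/dict.tsv --out work/final.tsv
```

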