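# Methods

This note records the models, parameters, numerical choices and known
limitations of `protein-wordwise`, in the spirit of a methods supplement.

## The word model

A *protein word* is a set of 5–20 residues of one protein with at most two
internal gaps; a gap may span any number of unincluded residues and is
written `_`.  The lower bound of 5 keeps words longer than the fragments
n-gram tokenizers already produce; the upper bound of 20 is the smallest
size from which a protein-like folding unit can form.  Words are extracted
per attention head and pooled across heads, so words from different heads
may overlap even though each head's own communities are disjoint.
Identical position sets from different heads are merged, with the union of
source heads retained; output order is deterministic (first position, then
residue count, then literal).  Coordinates are 1-based and inclusive in
every file and API.

## Binarization

Each head's L × L attention matrix is reduced to a binary interaction
matrix with two cutoffs:

* **lower bound** `b = min + lower_frac · (max − min)` with
  `lower_frac = 0.10`: entries below `b` become 0, the rest 1.  The bound
  is relative to the matrix's own range because raw attention scale varies
  strongly between heads; an absolute-threshold mode
  (`lower_mode="absolute"`) is available.
* **upper bound**: if the density of ones exceeds `density_trigger = 0.40`
  of all L² pairs, entries below the `upper_keep_quantile = 0.60`
  nearest-rank quantile of the *original* values are also zeroed.  The
  nearest-rank rule (value at 1-based rank ⌈qN⌉ of the sorted multiset,
  ties keeping all equal values) was chosen because it is a reproducible
  integer rule; linear interpolation is available.  A preset `p20`
  unconditionally drops the lowest 20 % instead, covering the alternative
  reading of the dual-cutoff scheme.

Degenerate inputs: a constant nonzero matrix binarizes to all ones (no
entry is below a zero-width range), but an all-zero matrix is treated as
edgeless — zero attention encodes no interaction — so it produces no words.

## Community detection

The binary matrix is read as a directed graph (edge *i → j* iff entry 1;
self-loops dropped; a `symmetrize` mode collapses to the undirected
closure).  Partitioning uses Louvain with resolution γ = 1.0 and
modularity-gain threshold ΔQ = 10⁻⁷ under directed Newman modularity.

Greedy Louvain is order-sensitive and can strand nodes in local optima, so
`detect_communities` (a) runs `n_restarts = 4` seeded restarts and keeps
the highest-modularity result, and (b) post-processes each run with a
deterministic refinement: best single-node moves at the finest level,
pairwise community merges, exhaustive bipartition of communities of ≤ 10
nodes, pairwise node swaps on graphs of ≤ 64 nodes, and, on graphs of
≤ 16 nodes, a depth-2 Kernighan–Lin step that forces one possibly
worsening move, re-converges, and keeps the excursion only if net
modularity improves.  All phases use the same ΔQ threshold and
deterministic visit orders, so fixed-seed reruns are bit-identical.  On
random connected digraphs of ≤ 8 nodes the refined partitions match or
closely approach the exhaustive-enumeration optimum; the refinement remains
a bounded-move heuristic, not an exact solver.  Communities outside 5–20
residues or with > 2 gaps are discarded, not repaired or split.

## Degenerate alphabet and dictionaries

The 20 amino acids are recoded into 12 physicochemical classes
(`data/alphabets.json`; A,G→a; R,K→b; D,E→c; N,Q→d; C→e; H→f; I,L,V→g;
F,Y→h; M→i; P→j; S,T→k; W→m), with a more aggressive 4-class alternative
(hydrophobic / polar / positive / negative).  The table ships as a config
file so a different partition can be substituted without code changes.
Gap symbols map to themselves and participate in exact matching (`b_b` ≠
`bb`); gap lengths are ignored.

Dictionary construction counts **document frequency** — the number of
distinct sequences containing a degenerate literal at least once — and
retains a literal iff `doc_freq / corpus_size` meets the per-length
threshold: 5 % (5 residues), 2.5 % (6), 0.15 % (7–11), 0.3 % (12–20),
inclusive at the boundary.  Lookup keeps a raw word iff its degenerate form
is an exact key of any supplied dictionary (common + family); with no
dictionaries the call degrades to raw-mode pass-through, mirroring the
no-dictionary ablation.  The random-k-mer control samples contiguous
subsequences with a matched length distribution (host sequence uniform
among those long enough, offset uniform) and is the negative control for
dictionary enrichment analyses.

## Evaluation metrics

Per-protein, against binary residue-level annotation:

* coverage = |functional ∩ ⋃ words| / |functional| (undefined — an error,
  not 0 — when the protein has no annotated functional residue);
* word accuracy = fraction of words containing ≥ 1 functional residue;
* residue precision = |functional ∩ ⋃ words| / |⋃ words| (the union
  convention: the named metric has no printed formula, and the union form
  matches the coverage convention);
* efficiency = distinct covered functional residues / Σ word lengths
  (residues only, summed with multiplicity).  Efficiency equals precision
  when words are disjoint and is ≤ 1 always.

Sequence-level GO prediction uses the Matthews correlation coefficient per
term, with the zero-denominator convention MCC = 0 so the unweighted mean
over terms stays defined.  Metrics are carried at full precision and
rounded to 3 decimals only at serialization.

## Word2Function

Word embeddings are means of the constituent residues' language-model
embeddings (reference dimension 1280); the whole-sequence mean is appended
as one extra pseudo-word for context and is excluded from functional-word
selection.  The classifier is a transformer encoder — learned CLS vector,
multi-head self-attention with key masking, GELU feed-forward, residual
connections, CLS readout through a fully connected layer to independent
sigmoids.  Reference profile: embedding and hidden dimension 1280, 20
heads, 1 encoder layer (configurable), batch 256, up to 600 epochs,
Adam with learning rate 10⁻³ under cosine decay, weight decay 10⁻⁵, early
stopping on a 90/10 validation split with patience 60.  The prediction
threshold for "the model predicts a term" is probability ≥ 0.5.

Two architectural choices deserve note.  The feed-forward activation is
GELU and the encoder omits LayerNorm (`layer_norm=False`; the network is
one shallow layer and optimizes well without it).  Both keep the model a
smooth function of its inputs along the Integrated-Gradients path: LayerNorm
has a zero-variance singularity at the all-zero baseline that concentrates
the entire path integral into α < 0.01, and ReLU kinks add O(1/n)
quadrature error; either breaks the completeness axiom at practical step
counts.  With the smooth network, IG uses the trapezoid rule (default 64
steps, zero baseline, one GO term per pass); completeness
Σ attributions ≈ F(x) − F(0) holds to well under 0.1 % relative at 256
steps.  A left-Riemann option is retained.

Per-word attribution is the sum over the word's embedding coordinates.
For every predicted-positive term, words with positive scores are ranked
(ties by input order) and the shortest prefix holding
`alpha_factor = 0.5` of the total positive mass is kept; 0.5 captures
roughly the top handful of words per term — a larger factor admits noise
words, a smaller one drops genuine ones.  Selected words enter the word
table in degenerate form; duplicate (term, literal) rows keep the highest
score.  Table-based prediction assigns every term whose literals intersect
the query's degenerate word forms.

## Synthetic data

The generator emulates exactly what the downstream algorithms consume:

* **planted attention**: within-block entries Uniform(0.8·s, s) on the
  designated heads, written symmetrically; everything else
  Uniform(0, noise) with noise = 0.05 against signal s = 1.0, so the
  relative lower cutoff falls cleanly between noise and signal.  Blocks
  satisfy the 5–20/≤ 2-gap geometry by construction.
* **labeled corpora**: 400 sequences of 60–120 residues over the uniform
  20-letter alphabet (defaults), 4 classes, each with one contiguous
  signal word of 6–10 residues inserted at a random non-overlapping offset
  in 40 % of sequences, plus 3 random decoy spans per sequence; a sequence
  is positive for a class iff its signal word occurs.  Labels are
  recomputable from the sequences at the default zero label noise.
  The synthetic embedding backend assigns each amino-acid letter a fixed
  random code vector plus small positional jitter, so identical
  subsequences embed nearly identically — the property the supervised
  model needs.

What the generator does **not** emulate: the banded/striped statistics of
real transformer attention, residue composition bias, homology structure,
multi-occurrence and gapped signal words, and label noise at realistic
rates.  Passing tests therefore demonstrate that the algorithms are
implemented correctly and recover planted structure under honest noise;
they do not certify accuracy on real proteomes, which depends on the
language model's attention quality.

## Problem sizes and determinism

The test suite and the acceptance script use 400-sequence corpora,
32-dimensional embeddings with 4 attention heads, 2-head attention stacks,
and 100-stack recovery batches — sizes chosen so the complete pipeline
(segmentation through training and attribution) runs in minutes on one
CPU while leaving every algorithmic path identical to the reference
profile.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); per-sequence and per-head streams are
derived by stable CRC mixing, so results are independent of processing
order, and fixed-seed reruns are byte-identical (files) and
weight-identical (training).

## Known limitations

* The ESM2 backend requires the optional `torch`/`fair-esm` extras; the
  packaged alphabet is a physicochemical default, and family-specific
  dictionary thresholds are assumed equal to the common ones.
* The word-table route only matches words exactly in degenerate space; no
  fuzzy or position-weight matching.
* Louvain refinement guarantees apply to small graphs; very long sequences
  rely on the restart heuristic alone for partition quality.
* Per-sequence word deduplication discards head multiplicity, which a
  token-frequency dictionary variant would need.
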