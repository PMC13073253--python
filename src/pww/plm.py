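"""Backends that supply per-sequence attention stacks and residue embeddings.

Two backends share one contract: :class:`SyntheticBackend` (always available,
deterministic under a seed, used for fixtures and tests) and
:class:`ESM2Backend`, a thin adapter over the 650M-parameter ESM2 model
(33 layers x 20 heads = 660 attention matrices, 1280-dim embeddings) that is
only usable when ``torch`` and ``fair-esm`` are installed.

The transformer backends prepend a begin token and append an end token to
every sequence; :func:`strip_special_tokens` removes the corresponding first
and last row/column so that every matrix handed downstream is exactly L x L
over residues only.
"""
from __future__ import annotations

import zlib

import numpy as np

from .errors import BackendUnavailable
from .types import AttentionStack, EmbeddingMatrix, ProteinSequence, CANONICAL_AA

#: Reference backend geometry (ESM2-650M).
ESM2_N_LAYERS = 33
ESM2_HEADS_PER_LAYER = 20
ESM2_N_HEADS = ESM2_N_LAYERS * ESM2_HEADS_PER_LAYER
ESM2_EMBED_DIM = 1280


def strip_special_tokens(matrix: np.ndarray) -> np.ndarray:
    """Drop the first and last row and column (begin/end token positions)."""
    if matrix.shape[0] < 3 or matrix.shape[1] < 3:
        raise ValueError("matrix too small to contain special tokens")
    return matrix[1:-1, 1:-1]


def _stable_seed(*parts) -> int:
    """Deterministic 31-bit seed derived from arbitrary string/int parts."""
    text = "\x1f".join(str(p) for p in parts)
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


class SyntheticBackend:
    """Deterministic pseudo-language-model backend for testing and fixtures.

    Residue embeddings are drawn from a fixed 20-row codebook (one row per
    amino-acid letter) plus small positional jitter, so that identical
    subsequences in different proteins receive nearly identical mean-pooled
    word embeddings -- the property the supervised model relies on.
    Attention is unstructured low-level noise; planted structure comes from
    :mod:`pww.synth`.

    Parameters
    ----------
    n_heads : number of attention matrices per sequence.
    embed_dim : residue-embedding dimension D.
    seed : global seed; per-sequence streams are derived from it and the
        sequence id, so results do not depend on call order.
    noise_level : scale of the attention noise and of the embedding jitter.
    """

    def __init__(
        self,
        n_heads: int = 4,
        embed_dim: int = 16,
        seed: int = 0,
        noise_level: float = 0.05,
    ) -> None:
        self.n_heads = n_heads
        self.embed_dim = embed_dim
        self.seed = seed
        self.noise_level = noise_level
        rng = np.random.default_rng(_stable_seed("codebook", seed, embed_dim))
        self._codebook = rng.normal(0.0, 1.0, size=(len(CANONICAL_AA), embed_dim))
        self._aa_index = {aa: i for i, aa in enumerate(CANONICAL_AA)}

    def attention(self, seq: ProteinSequence) -> AttentionStack:
        L = len(seq)
        rng = np.random.default_rng(_stable_seed("attn", self.seed, seq.id, L))
        heads = [
            rng.uniform(0.0, self.noise_level, size=(L, L)) for _ in range(self.n_heads)
        ]
        labels = [(0, i) for i in range(self.n_heads)]
        return AttentionStack(sequence_id=seq.id, heads=heads, head_labels=labels)

    def embeddings(self, seq: ProteinSequence) -> EmbeddingMatrix:
        rng = np.random.default_rng(_stable_seed("emb", self.seed, seq.id, len(seq)))
        idx = np.array([self._aa_index[a] for a in seq.residues])
        rows = self._codebook[idx] + rng.normal(
            0.0, self.noise_level, size=(len(seq), self.embed_dim)
        )
        return EmbeddingMatrix(sequence_id=seq.id, rows=rows)


class ESM2Backend:
    """Adapter over the ESM2-650M protein language model.

    Requires the optional ``torch`` and ``fair-esm`` dependencies; if either
    is missing, construction raises :class:`BackendUnavailable` (the synthetic
    backend never does).  Attention matrices and embeddings have their
    begin/end special-token rows and columns stripped before return, so each
    of the 660 matrices is exactly L x L.
    """

    n_heads = ESM2_N_HEADS
    embed_dim = ESM2_EMBED_DIM

    def __init__(self, model_name: str = "esm2_t33_650M_UR50D") -> None:
        try:
            import esm  # type: ignore
            import torch  # noqa: F401
        except ImportError as exc:  # pragma: no cover - requires optional deps
            raise BackendUnavailable(
                "ESM2 backend requires the optional 'torch' and 'fair-esm' "
                "packages (pip install protein-wordwise[esm])"
            ) from exc
        self._model, alphabet = getattr(esm.pretrained, model_name)()
        self._model.eval()
        self._batch_converter = alphabet.get_batch_converter()

    def attention(self, seq: ProteinSequence) -> AttentionStack:  # pragma: no cover
        import torch

        _, _, tokens = self._batch_converter([(seq.id, seq.residues)])
        with torch.no_grad():
            out = self._model(tokens, need_head_weights=True)
        # attentions: (1, layers, heads, T, T) including special tokens
        att = out["attentions"][0].numpy()
        heads, labels = [], []
        for layer in range(att.shape[0]):
            for head in range(att.shape[1]):
                heads.append(strip_special_tokens(att[layer, head]))
                labels.append((layer + 1, head + 1))
        return AttentionStack(sequence_id=seq.id, heads=heads, head_labels=labels)

    def embeddings(self, seq: ProteinSequence) -> EmbeddingMatrix:  # pragma: no cover
        import torch

        _, _, tokens = self._batch_converter([(seq.id, seq.residues)])
        with torch.no_grad():
            out = self._model(tokens, repr_layers=[ESM2_N_LAYERS])
        reps = out["representations"][ESM2_N_LAYERS][0].numpy()
        return EmbeddingMatrix(sequence_id=seq.id, rows=reps[1:-1])


def get_attention(seq: ProteinSequence, backend) -> AttentionStack:
    """Fetch the attention stack for ``seq``, enforcing the shape contract."""
    stack = backend.attention(seq)
    if stack.length != len(seq):
        raise ValueError(
            f"backend returned {stack.length}x{stack.length} matrices for a "
            f"{len(seq)}-residue sequence"
        )
    return stack


def get_embeddings(seq: ProteinSequence, backend) -> EmbeddingMatrix:
    """Fetch residue embeddings for ``seq``, enforcing one row per residue."""
    emb = backend.embeddings(seq)
    if emb.length != len(seq):
        raise ValueError(
            f"backend returned {emb.length} embedding rows for a "
            f"{len(seq)}-residue sequence"
        )
    return emb


class AttentionCache:
    """Optional on-disk HDF5 cache of attention stacks.

    Datasets are named ``<seq_id>/<layer>_<head>`` and stored float32.
    """

    def __init__(self, path) -> None:
        self.path = str(path)

    def save(self, stack: AttentionStack) -> None:
        import h5py

        with h5py.File(self.path, "a") as f:
            grp = f.require_group(stack.sequence_id)
            for (layer, head), mat in zip(stack.head_labels, stack.heads):
                name = f"{layer}_{head}"
                if name in grp:
                    del grp[name]
                grp.create_dataset(name, data=mat.astype(np.float32))

    def load(self, sequence_id: str) -> AttentionStack:
        import h5py

        with h5py.File(self.path, "r") as f:
            grp = f[sequence_id]
            labels = sorted(
                (tuple(int(x) for x in name.split("_")) for name in grp),
                key=lambda t: (t[0], t[1]),
            )
            heads = [grp[f"{layer}_{head}"][()].astype(float) for layer, head in labels]
        return AttentionStack(
            sequence_id=sequence_id, heads=heads, head_labels=list(labels)
        )

    def __contains__(self, sequence_id: str) -> bool:
        import h5py
        import os

        if not os.path.exists(self.path):
            return False
        with h5py.File(self.path, "r") as f:
            return sequence_id in f
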