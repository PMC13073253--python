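"""Supervised mapping from protein words to GO terms.

Each word of a parsed protein is embedded as the mean of its residues'
language-model embeddings; the whole sequence is appended as one extra
pseudo-word for context.  A transformer encoder classifier (CLS-token
readout, independent sigmoid per GO term) is trained with binary
cross-entropy.  After training, Integrated Gradients attributes each
prediction back to the input words: attributions are integrated along the
straight-line path from an all-zero baseline to the input, the per-word
score being the sum over that word's embedding coordinates.  For every
predicted-positive term, the positive-score words are ranked and the
shortest top prefix whose score mass reaches ``alpha_factor`` (default 0.5)
times the total positive mass is retained as the term's *functional
annotation words*.  Those words, in degenerate form, accumulate into a
reusable word table that assigns GO terms to new sequences by exact match.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import AdamOptimizer, TransformerClassifierNet, bce_loss_and_grad
from .alphabet import DegenerateAlphabet, degenerate, load_alphabet
from .errors import LabelDimensionMismatch, PositionOutOfRange
from .types import EmbeddingMatrix, ProteinWord


@dataclass
class WordEmbeddingSequence:
    """Per-word mean embeddings of one sequence, whole-sequence vector last.

    ``embeddings`` has ``len(words) + 1`` rows; the final row is the mean
    over all residues of the protein (the whole-sequence pseudo-word, which
    participates in attention but is never selected as a functional word).
    """

    sequence_id: str
    embeddings: np.ndarray
    words: list[ProteinWord]

    @property
    def n_words(self) -> int:
        return len(self.words)


def embed_words(words: list[ProteinWord], emb: EmbeddingMatrix) -> WordEmbeddingSequence:
    """Mean-pool residue embeddings per word and append the sequence mean."""
    rows = []
    for w in words:
        idx = np.array(w.positions) - 1
        if idx.min() < 0 or idx.max() >= emb.length:
            raise PositionOutOfRange(
                f"word positions {w.positions[0]}..{w.positions[-1]} outside "
                f"embedding with {emb.length} rows"
            )
        rows.append(emb.rows[idx].mean(axis=0))
    rows.append(emb.rows.mean(axis=0))
    return WordEmbeddingSequence(
        sequence_id=emb.sequence_id, embeddings=np.vstack(rows), words=list(words)
    )


def _pad_batch(items: list[WordEmbeddingSequence], embed_dim: int):
    T = max(it.embeddings.shape[0] for it in items)
    B = len(items)
    X = np.zeros((B, T, embed_dim))
    mask = np.zeros((B, T), dtype=bool)
    for i, it in enumerate(items):
        n = it.embeddings.shape[0]
        X[i, :n] = it.embeddings
        mask[i, :n] = True
    return X, mask


class Word2FunctionClassifier(ClassifierMixin, BaseEstimator):
    """Multi-label GO-term classifier over word-embedding sequences.

    Scikit-learn style estimator: ``fit(X, Y)`` with ``X`` a list of
    :class:`WordEmbeddingSequence` and ``Y`` a binary (n_samples, n_terms)
    array; ``predict_proba`` returns independent per-term probabilities.
    Training uses Adam with cosine learning-rate decay and early stopping on
    a held-out validation split.  Identical data and seed reproduce
    identical weights.

    Defaults follow the reference profile (1280-dim embeddings, hidden 1280,
    20 heads, batch 256, up to 600 epochs, patience 60, lr 1e-3, weight
    decay 1e-5); synthetic fixtures shrink ``embed_dim``/``n_heads``.
    """

    def __init__(
        self,
        embed_dim: int = 1280,
        hidden_dim: int = 1280,
        n_heads: int = 20,
        n_layers: int = 1,
        lr: float = 1e-3,
        batch_size: int = 256,
        max_epochs: int = 600,
        patience: int = 60,
        weight_decay: float = 1e-5,
        val_fraction: float = 0.1,
        threshold: float = 0.5,
        seed: int = 0,
    ) -> None:
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.weight_decay = weight_decay
        self.val_fraction = val_fraction
        self.threshold = threshold
        self.seed = seed

    # ------------------------------------------------------------------ fit
    def fit(self, X: list[WordEmbeddingSequence], Y, terms: list[str] | None = None):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[0] != len(X):
            raise LabelDimensionMismatch(
                f"Y has shape {Y.shape}, expected ({len(X)}, n_terms)"
            )
        n_classes = Y.shape[1]
        if n_classes < 2:
            raise LabelDimensionMismatch("need at least two label columns")
        self.terms_ = list(terms) if terms is not None else [
            f"class_{i}" for i in range(n_classes)
        ]
        if len(self.terms_) != n_classes:
            raise LabelDimensionMismatch("terms length does not match Y columns")

        rng = np.random.default_rng(self.seed)
        net = TransformerClassifierNet(
            embed_dim=self.embed_dim,
            hidden_dim=self.hidden_dim,
            n_heads=self.n_heads,
            n_layers=self.n_layers,
            n_classes=n_classes,
            seed=self.seed,
        )
        opt = AdamOptimizer(net.params, lr=self.lr, weight_decay=self.weight_decay)

        n = len(X)
        order = rng.permutation(n)
        n_val = int(round(self.val_fraction * n))
        val_idx, train_idx = order[:n_val], order[n_val:]
        Xtr = [X[i] for i in train_idx]
        Ytr = Y[train_idx]
        Xval = [X[i] for i in val_idx]
        Yval = Y[val_idx]
        Xv, mv = (None, None)
        if len(Xval):
            Xv, mv = _pad_batch(Xval, self.embed_dim)

        best_loss = np.inf
        best_state = net.get_state()
        best_epoch = 0
        history = []
        for epoch in range(self.max_epochs):
            lr_t = self.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / self.max_epochs))
            perm = rng.permutation(len(Xtr))
            ep_loss = 0.0
            n_batches = 0
            for start in range(0, len(Xtr), self.batch_size):
                idx = perm[start : start + self.batch_size]
                Xb, mb = _pad_batch([Xtr[i] for i in idx], self.embed_dim)
                logits, cache = net.forward(Xb, mb)
                loss, dlogits = bce_loss_and_grad(logits, Ytr[idx])
                grads, _ = net.backward(cache, dlogits)
                opt.step(net.params, grads, lr=lr_t)
                ep_loss += loss
                n_batches += 1
            if Xv is not None:
                logits, _ = net.forward(Xv, mv)
                monitor, _ = bce_loss_and_grad(logits, Yval)
            else:
                monitor = ep_loss / max(n_batches, 1)
            history.append(monitor)
            if monitor < best_loss - 1e-12:
                best_loss = monitor
                best_state = net.get_state()
                best_epoch = epoch
            elif epoch - best_epoch >= self.patience:
                break
        net.set_state(best_state)
        self.net_ = net
        self.n_classes_ = n_classes
        self.best_val_loss_ = float(best_loss)
        self.history_ = history
        self.n_epochs_ = len(history)
        return self

    # -------------------------------------------------------------- predict
    def predict_proba(self, X: list[WordEmbeddingSequence]) -> np.ndarray:
        Xb, mb = _pad_batch(X, self.embed_dim)
        return self.net_.predict_proba(Xb, mb)

    def predict(self, X: list[WordEmbeddingSequence]) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)

    def predict_terms(self, X: list[WordEmbeddingSequence]) -> list[set[str]]:
        pred = self.predict(X)
        return [
            {self.terms_[j] for j in np.flatnonzero(row)} for row in pred
        ]

    # -------------------------------------------------------- serialization
    def save(self, path) -> None:
        meta = dict(
            embed_dim=self.embed_dim, hidden_dim=self.hidden_dim,
            n_heads=self.n_heads, n_layers=self.n_layers,
            n_classes=self.n_classes_, seed=self.seed, threshold=self.threshold,
        )
        np.savez(
            path,
            _terms=np.array(self.terms_, dtype=object),
            _meta=np.array([meta], dtype=object),
            **self.net_.params,
        )

    @classmethod
    def load(cls, path) -> "Word2FunctionClassifier":
        data = np.load(path, allow_pickle=True)
        meta = data["_meta"][0]
        clf = cls(
            embed_dim=int(meta["embed_dim"]), hidden_dim=int(meta["hidden_dim"]),
            n_heads=int(meta["n_heads"]), n_layers=int(meta["n_layers"]),
            threshold=float(meta["threshold"]), seed=int(meta["seed"]),
        )
        net = TransformerClassifierNet(
            embed_dim=clf.embed_dim, hidden_dim=clf.hidden_dim,
            n_heads=clf.n_heads, n_layers=clf.n_layers,
            n_classes=int(meta["n_classes"]), seed=clf.seed,
        )
        net.set_state({k: data[k] for k in net.params})
        clf.net_ = net
        clf.terms_ = [str(t) for t in data["_terms"]]
        clf.n_classes_ = int(meta["n_classes"])
        return clf


# --------------------------------------------------------------- attribution

@dataclass(frozen=True)
class AttributionConfig:
    """Integrated-Gradients settings: zero baseline, straight-line path."""

    n_steps: int = 64
    alpha_factor: float = 0.5
    method: str = "trapezoid"  # "left" (left-Riemann) also available

    def __post_init__(self) -> None:
        if not (0 < self.alpha_factor < 1):
            raise ValueError("alpha_factor must be in (0, 1)")
        if self.method not in ("left", "trapezoid"):
            raise ValueError("unknown quadrature method")


def integrated_gradients(
    net: TransformerClassifierNet,
    x: np.ndarray,
    mask: np.ndarray,
    target: int,
    n_steps: int = 64,
    method: str = "trapezoid",
    target_output: str = "probability",
) -> np.ndarray:
    """Per-coordinate IG attributions of the target-class output.

    ``x``: (T, D) token embeddings of one sample; baseline is all-zero;
    ``target_output`` selects the attributed quantity F (the sigmoid
    probability by default, or the raw logit).  Returns an attribution
    matrix of the same shape whose total approximates F(x) - F(0)
    (completeness).
    """
    if method == "left":
        alphas = np.arange(n_steps) / n_steps
        weights = np.full(n_steps, 1.0 / n_steps)
    else:  # trapezoid
        alphas = np.linspace(0.0, 1.0, n_steps + 1)
        weights = np.full(n_steps + 1, 1.0 / n_steps)
        weights[0] = weights[-1] = 0.5 / n_steps
    Xb = alphas[:, None, None] * x[None, :, :]
    mb = np.broadcast_to(mask, (len(alphas), mask.size))
    logits, cache = net.forward(Xb, mb)
    dlogits = np.zeros_like(logits)
    if target_output == "probability":
        probs = 1.0 / (1.0 + np.exp(-logits))
        dlogits[:, target] = probs[:, target] * (1.0 - probs[:, target])
    else:  # raw logit
        dlogits[:, target] = 1.0
    _, dX = net.backward(cache, dlogits)
    avg_grad = np.tensordot(weights, dX, axes=(0, 0))
    return x * avg_grad


def attribute_words(
    model: Word2FunctionClassifier,
    x: WordEmbeddingSequence,
    term: str | int,
    cfg: AttributionConfig | None = None,
) -> np.ndarray:
    """Per-word attribution scores for one GO term.

    Scores are returned for the real words only (the whole-sequence
    pseudo-word is attributed but excluded from ranking and selection).
    """
    cfg = cfg or AttributionConfig()
    t = model.terms_.index(term) if isinstance(term, str) else int(term)
    mask = np.ones(x.embeddings.shape[0], dtype=bool)
    attr = integrated_gradients(
        model.net_, x.embeddings, mask, t, n_steps=cfg.n_steps, method=cfg.method
    )
    return attr.sum(axis=1)[: x.n_words]


def select_functional_words(
    scores: np.ndarray, alpha_factor: float = 0.5
) -> list[int]:
    """Indices of the minimal top prefix of positive scores reaching alpha.

    Non-positive scores are dropped; the rest are sorted descending (ties
    keep input order), and the shortest prefix whose cumulative score
    reaches ``alpha_factor`` times the total positive mass is returned.
    """
    scores = np.asarray(scores, dtype=float)
    pos = [(s, i) for i, s in enumerate(scores) if s > 0]
    if not pos:
        return []
    order = sorted(pos, key=lambda t: (-t[0], t[1]))
    alpha = alpha_factor * sum(s for s, _ in order)
    selected, acc = [], 0.0
    for s, i in order:
        selected.append(i)
        acc += s
        if acc >= alpha:
            break
    return selected


# ----------------------------------------------------------------- WordTable

_TABLE_COLUMNS = ["term", "literal", "score", "seq_id"]


@dataclass
class WordTable:
    """Accumulated GO term -> functional-annotation-word mapping."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_TABLE_COLUMNS)
    )

    def add(self, term: str, literal: str, score: float, seq_id: str) -> None:
        """Insert a row; a duplicate (term, literal) keeps the higher score."""
        existing = self.rows[
            (self.rows["term"] == term) & (self.rows["literal"] == literal)
        ]
        if len(existing):
            i = existing.index[0]
            if score > self.rows.at[i, "score"]:
                self.rows.at[i, "score"] = score
                self.rows.at[i, "seq_id"] = seq_id
            return
        self.rows.loc[len(self.rows)] = [term, literal, float(score), seq_id]

    @property
    def index(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for term, lit in zip(self.rows["term"], self.rows["literal"]):
            out.setdefault(term, set()).add(lit)
        return out

    def __len__(self) -> int:
        return len(self.rows)

    def to_tsv(self, path) -> None:
        frame = self.rows.sort_values(
            ["term", "score"], ascending=[True, False], kind="mergesort"
        )
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "WordTable":
        return cls(rows=pd.read_csv(path, sep="\t"))


def build_word_table(
    model: Word2FunctionClassifier,
    items: list[WordEmbeddingSequence],
    cfg: AttributionConfig | None = None,
    alphabet: DegenerateAlphabet | None = None,
) -> WordTable:
    """Attribute every predicted-positive term of every sequence and collect
    the selected words (degenerate form) into a word table."""
    cfg = cfg or AttributionConfig()
    alphabet = alphabet or load_alphabet("a12")
    table = WordTable()
    probs = model.predict_proba(items)
    for item, p in zip(items, probs):
        for t in np.flatnonzero(p >= model.threshold):
            scores = attribute_words(model, item, int(t), cfg)
            for i in select_functional_words(scores, cfg.alpha_factor):
                table.add(
                    term=model.terms_[t],
                    literal=degenerate(item.words[i], alphabet),
                    score=float(scores[i]),
                    seq_id=item.sequence_id,
                )
    return table


def predict_with_table(
    words: list[ProteinWord],
    table: WordTable,
    alphabet: DegenerateAlphabet | None = None,
) -> set[str]:
    """Assign every GO term whose table literals intersect the sequence's
    degenerate word forms (exact match)."""
    alphabet = alphabet or load_alphabet("a12")
    forms = {degenerate(w, alphabet) for w in words}
    return {term for term, lits in table.index.items() if forms & lits}
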