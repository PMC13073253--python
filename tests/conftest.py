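"""Shared fixtures: labeled synthetic corpus, embeddings, trained classifier.

The expensive end-to-end artifacts (corpus parse + classifier training) are
session-scoped so the supervised-model tests and the acceptance suite share
one training run.
"""
from __future__ import annotations

import numpy as np
import pytest

from pww.alphabet import load_alphabet
from pww.plm import get_embeddings
from pww.segment import parse_sequence
from pww.synth import SyntheticCorpusSpec, make_labeled_corpus
from pww.word2function import Word2FunctionClassifier, embed_words

CORPUS_SEED = 1
N_SEQUENCES = 400
N_CLASSES = 4
EMBED_DIM = 32
N_TRAIN = 320


@pytest.fixture(scope="session")
def alphabet12():
    return load_alphabet("a12")


@pytest.fixture(scope="session")
def alphabet4():
    return load_alphabet("a4")


def build_corpus_items(seed: int):
    """Corpus -> segmentation -> word embeddings, the full unsupervised front."""
    corpus = make_labeled_corpus(
        SyntheticCorpusSpec(n_sequences=N_SEQUENCES, n_classes=N_CLASSES, seed=seed)
    )
    backend = corpus.backend(embed_dim=EMBED_DIM)
    items = []
    for s in corpus.sequences:
        words = parse_sequence(s, corpus.attention_stack(s.id)) or corpus.words(s.id)
        items.append(embed_words(words, get_embeddings(s, backend)))
    Y = np.array(
        [
            [int(t in corpus.labels[it.sequence_id]) for t in corpus.terms]
            for it in items
        ]
    )
    return corpus, items, Y


@pytest.fixture(scope="session")
def labeled_corpus_items():
    return build_corpus_items(CORPUS_SEED)


@pytest.fixture(scope="session")
def trained_classifier(labeled_corpus_items):
    corpus, items, Y = labeled_corpus_items
    clf = Word2FunctionClassifier(
        embed_dim=EMBED_DIM, hidden_dim=EMBED_DIM, n_heads=4,
        max_epochs=600, seed=CORPUS_SEED,
    )
    clf.fit(items[:N_TRAIN], Y[:N_TRAIN], terms=corpus.terms)
    return clf
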