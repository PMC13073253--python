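"""Transformer classifier internals, Integrated Gradients, word selection."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pww._nn import AdamOptimizer, TransformerClassifierNet, bce_loss_and_grad
from pww.errors import LabelDimensionMismatch, PositionOutOfRange
from pww.types import EmbeddingMatrix, ProteinWord
from pww.word2function import (
    AttributionConfig,
    Word2FunctionClassifier,
    WordTable,
    attribute_words,
    embed_words,
    integrated_gradients,
    select_functional_words,
)

RNG = np.random.default_rng(17)


class TestNetwork:
    def test_gradients_match_finite_differences(self):
        net = TransformerClassifierNet(8, 12, 2, 2, 3, seed=0)
        net.params["Wout"] = RNG.normal(0, 0.3, net.params["Wout"].shape)
        X = RNG.normal(0, 1, (3, 4, 8))
        mask = np.ones((3, 4), bool)
        mask[1, 3] = False
        Y = RNG.integers(0, 2, (3, 3))

        def loss():
            logits, _ = net.forward(X, mask)
            return bce_loss_and_grad(logits, Y)[0]

        logits, cache = net.forward(X, mask)
        _, dlogits = bce_loss_and_grad(logits, Y)
        grads, dX = net.backward(cache, dlogits)
        eps = 1e-7
        for k in net.params:
            if k.startswith("ln"):
                continue  # layer norm disabled in the default profile
            flat = net.params[k].reshape(-1)
            for idx in RNG.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                assert abs((lp - lm) / (2 * eps) - grads[k].reshape(-1)[idx]) < 1e-6
        for _ in range(10):
            i, t, d = (int(RNG.integers(n)) for n in (3, 4, 8))
            orig = X[i, t, d]
            X[i, t, d] = orig + eps
            lp = loss()
            X[i, t, d] = orig - eps
            lm = loss()
            X[i, t, d] = orig
            assert abs((lp - lm) / (2 * eps) - dX[i, t, d]) < 1e-6

    def test_zero_initialized_head_predicts_half(self):
        net = TransformerClassifierNet(8, 8, 2, 1, 4, seed=1)
        X = RNG.normal(0, 1, (2, 3, 8))
        probs = net.predict_proba(X, np.ones((2, 3), bool))
        np.testing.assert_allclose(probs, 0.5)

    def test_padded_tokens_do_not_influence_output(self):
        net = TransformerClassifierNet(8, 8, 2, 1, 2, seed=2)
        net.params["Wout"] = RNG.normal(0, 0.5, net.params["Wout"].shape)
        X = RNG.normal(0, 1, (1, 4, 8))
        mask = np.array([[True, True, False, False]])
        base = net.predict_proba(X, mask)
        X2 = X.copy()
        X2[0, 2:] = RNG.normal(0, 5, (2, 8))
        np.testing.assert_allclose(net.predict_proba(X2, mask), base)

    def test_adam_descends_on_quadratic(self):
        params = {"w": np.array([5.0, -3.0])}
        opt = AdamOptimizer(params, lr=0.1)
        for _ in range(500):
            opt.step(params, {"w": 2 * params["w"]})
        assert np.abs(params["w"]).max() < 1e-3


class TestEmbedWords:
    def embedding(self, rows):
        return EmbeddingMatrix("s", np.asarray(rows, dtype=float))

    def test_single_residue_word_is_that_row(self):
        emb = self.embedding(RNG.normal(0, 1, (6, 4)))
        w = ProteinWord.from_positions("s", [3], "ACDEFG")
        out = embed_words([w], emb)
        np.testing.assert_array_equal(out.embeddings[0], emb.rows[2])

    def test_opposite_embeddings_cancel(self):
        e = RNG.normal(0, 1, 4)
        rows = np.vstack([e, -e, e, -e, e, -e])
        w = ProteinWord.from_positions("s", [1, 2], "ACDEFG")
        out = embed_words([w], self.embedding(rows))
        np.testing.assert_allclose(out.embeddings[0], 0.0, atol=1e-15)

    def test_mean_matches_brute_force(self):
        emb = self.embedding(RNG.normal(0, 1, (30, 8)))
        for _ in range(50):
            size = int(RNG.integers(5, 12))
            start = int(RNG.integers(1, 30 - size + 1))
            w = ProteinWord.from_positions("s", range(start, start + size), "A" * 30)
            out = embed_words([w], emb)
            brute = sum(emb.rows[p - 1] for p in w.positions) / len(w.positions)
            np.testing.assert_allclose(out.embeddings[0], brute, atol=1e-9)

    def test_whole_sequence_vector_appended_last(self):
        emb = self.embedding(RNG.normal(0, 1, (10, 4)))
        w = ProteinWord.from_positions("s", range(1, 6), "A" * 10)
        out = embed_words([w], emb)
        assert out.embeddings.shape == (2, 4)
        np.testing.assert_allclose(out.embeddings[-1], emb.rows.mean(0))

    def test_out_of_range_positions_rejected(self):
        emb = self.embedding(RNG.normal(0, 1, (5, 4)))
        w = ProteinWord.from_positions("s", range(3, 9), "A" * 10)
        with pytest.raises(PositionOutOfRange):
            embed_words([w], emb)


class _LinearStub:
    """Minimal linear model implementing the forward/backward protocol."""

    def __init__(self, W):
        self.W = W  # (T, D, C)

    def forward(self, X, mask):
        logits = np.einsum("btd,tdc->bc", X, self.W)
        return logits, {"X": X}

    def backward(self, cache, dlogits):
        dX = np.einsum("bc,tdc->btd", dlogits, self.W)
        return {}, dX


class TestIntegratedGradients:
    def test_linear_model_closed_form(self):
        T, D, C = 3, 4, 2
        W = RNG.normal(0, 1, (T, D, C))
        x = RNG.normal(0, 1, (T, D))
        attr = integrated_gradients(
            _LinearStub(W), x, np.ones(T, bool), target=1,
            n_steps=1, target_output="logit",
        )
        np.testing.assert_allclose(attr, x * W[:, :, 1], atol=1e-10)

    def test_completeness_on_random_models(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            D = int(rng.choice([8, 16]))
            T = int(rng.integers(2, 7))
            net = TransformerClassifierNet(D, 2 * D, 2, 1, 3, seed=trial)
            net.params["Wout"] = rng.normal(0, 0.5, net.params["Wout"].shape)
            net.params["bout"] = rng.normal(0, 0.2, net.params["bout"].shape)
            x = rng.normal(0, 1, (T, D))
            mask = np.ones(T, bool)
            t = int(rng.integers(3))
            attr = integrated_gradients(net, x, mask, t, n_steps=256)
            probs = lambda z: net.predict_proba(z[None], mask[None])[0, t]
            delta = probs(x) - probs(np.zeros_like(x))
            assert abs(attr.sum() - delta) <= 1e-3 * abs(delta) + 1e-6


class TestSelectFunctionalWords:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([0.6, 0.3, 0.2], [0]),  # alpha = 0.55, first word suffices
            ([0.4, 0.4, 0.2], [0, 1]),  # alpha = 0.5, need two
            ([-0.1, -0.2], []),  # nothing positive
        ],
    )
    def test_forced_selections(self, scores, expected):
        assert select_functional_words(np.array(scores), 0.5) == expected

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=12),
        st.floats(0.05, 0.95),
    )
    def test_minimality_against_prefix_search(self, scores, alpha_factor):
        scores = np.asarray(scores)
        sel = select_functional_words(scores, alpha_factor)
        pos = sorted(
            ((s, i) for i, s in enumerate(scores) if s > 0),
            key=lambda t: (-t[0], t[1]),
        )
        alpha = alpha_factor * sum(s for s, _ in pos)
        if not pos:
            assert sel == []
            return
        # brute-force shortest qualifying prefix
        acc, brute = 0.0, []
        for s, i in pos:
            brute.append(i)
            acc += s
            if acc >= alpha:
                break
        assert sel == brute
        assert sum(scores[i] for i in sel) >= alpha - 1e-12
        if len(sel) > 1:
            assert sum(scores[i] for i in sel[:-1]) < alpha


class TestClassifierContract:
    def small_items(self, n=40, T=3, D=8, seed=0):
        rng = np.random.default_rng(seed)
        from pww.word2function import WordEmbeddingSequence

        items, Y = [], []
        for i in range(n):
            words = [
                ProteinWord.from_positions(f"q{i}", range(1, 6), "A" * 20)
                for _ in range(T - 1)
            ]
            emb = rng.normal(0, 1, (T, D))
            items.append(WordEmbeddingSequence(f"q{i}", emb, words))
            Y.append([int(emb.sum() > 0), int(emb[0, 0] > 0)])
        return items, np.array(Y)

    def test_label_dimension_checked(self):
        items, Y = self.small_items()
        clf = Word2FunctionClassifier(embed_dim=8, hidden_dim=8, n_heads=2)
        with pytest.raises(LabelDimensionMismatch):
            clf.fit(items, Y[:, :1])
        with pytest.raises(LabelDimensionMismatch):
            clf.fit(items, Y, terms=["only-one"])

    def test_fit_is_deterministic(self):
        items, Y = self.small_items()
        kw = dict(embed_dim=8, hidden_dim=8, n_heads=2, max_epochs=30, seed=3)
        a = Word2FunctionClassifier(**kw).fit(items, Y)
        b = Word2FunctionClassifier(**kw).fit(items, Y)
        for k in a.net_.params:
            np.testing.assert_array_equal(a.net_.params[k], b.net_.params[k])

    def test_probabilities_are_independent_sigmoids(self):
        items, Y = self.small_items()
        clf = Word2FunctionClassifier(
            embed_dim=8, hidden_dim=8, n_heads=2, max_epochs=20, seed=0
        ).fit(items, Y)
        probs = clf.predict_proba(items)
        assert np.all((probs > 0) & (probs < 1))
        assert not np.allclose(probs.sum(axis=1), 1.0)

    def test_save_load_roundtrip(self, tmp_path):
        items, Y = self.small_items()
        clf = Word2FunctionClassifier(
            embed_dim=8, hidden_dim=8, n_heads=2, max_epochs=10, seed=0
        ).fit(items, Y, terms=["GO:1", "GO:2"])
        path = tmp_path / "model.npz"
        clf.save(path)
        loaded = Word2FunctionClassifier.load(path)
        np.testing.assert_array_equal(
            clf.predict_proba(items), loaded.predict_proba(items)
        )
        assert loaded.terms_ == ["GO:1", "GO:2"]

    def test_sklearn_get_set_params(self):
        clf = Word2FunctionClassifier(embed_dim=16)
        assert clf.get_params()["embed_dim"] == 16
        clf.set_params(lr=5e-4)
        assert clf.lr == 5e-4


class TestWordTable:
    def test_duplicate_rows_keep_max_score(self):
        t = WordTable()
        t.add("GO:1", "bba", 0.5, "s1")
        t.add("GO:1", "bba", 0.9, "s2")
        t.add("GO:1", "bba", 0.2, "s3")
        assert len(t) == 1
        assert float(t.rows["score"].iloc[0]) == 0.9
        assert t.rows["seq_id"].iloc[0] == "s2"

    def test_tsv_roundtrip_sorted_by_score(self, tmp_path):
        t = WordTable()
        t.add("GO:2", "aaa", 0.1, "s")
        t.add("GO:1", "bbb", 0.7, "s")
        t.add("GO:1", "ccc", 0.9, "s")
        path = tmp_path / "table.tsv"
        t.to_tsv(path)
        loaded = WordTable.from_tsv(path)
        assert list(loaded.rows["literal"]) == ["ccc", "bbb", "aaa"]
        assert loaded.index == {"GO:1": {"bbb", "ccc"}, "GO:2": {"aaa"}}
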