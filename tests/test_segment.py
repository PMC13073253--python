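"""Binarization, residue graphs, Louvain communities, and word assembly."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from pww.errors import EmptyMatrix
from pww.segment import (
    BinarizationConfig,
    LouvainConfig,
    WordFilterConfig,
    WordSegmenter,
    assemble_words,
    binarize,
    build_graph,
    detect_communities,
    nearest_rank_quantile,
    parse_sequence,
)
from pww.synth import PlantedWordSpec, make_planted_attention
from pww.types import ProteinSequence, positions_to_runs

from _oracles import binarize_oracle, nearest_rank_quantile_oracle

RNG = np.random.default_rng(11)
AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_seq(L, ident="s"):
    return ProteinSequence(ident, "".join(RNG.choice(AA, size=L)))


class TestBinarize:
    def test_constant_matrix_all_ones(self):
        m = np.full((6, 6), 0.7)
        assert binarize(m).sum() == 36

    def test_all_zero_matrix_is_edgeless(self):
        assert binarize(np.zeros((5, 5))).sum() == 0

    def test_upper_bound_not_triggered_below_density(self):
        # exactly 30% of entries above the lower bound: trigger stays off
        m = np.zeros((10, 10))
        m.ravel()[:30] = 0.9
        out = binarize(m)
        assert out.sum() == 30
        assert np.array_equal(np.flatnonzero(out.ravel()), np.arange(30))

    def test_derived_nearest_rank_example(self):
        # 60 entries at 0.9, 40 at 0.0: density 0.60 > 0.40 triggers the
        # upper bound; nearest-rank 60th percentile of the 100 sorted values
        m = np.zeros((10, 10))
        m.ravel()[:60] = 0.9
        u = nearest_rank_quantile_oracle(m, 0.60)
        out = binarize(m)
        expected = (m >= max(u, 0.09)).astype(int)
        np.testing.assert_array_equal(out, expected)
        assert out.sum() == 60

    def test_matches_oracle_on_random_matrices(self):
        for _ in range(500):
            L = int(RNG.integers(3, 16))
            m = RNG.uniform(0, 1, (L, L))
            np.testing.assert_array_equal(binarize(m), binarize_oracle(m))

    def test_quantile_matches_multiset_oracle(self):
        for _ in range(200):
            vals = RNG.uniform(0, 1, int(RNG.integers(1, 50)))
            q = float(RNG.uniform(0.05, 0.95))
            assert nearest_rank_quantile(vals, q) == nearest_rank_quantile_oracle(
                vals, q
            )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(4, 12), st.integers(0, 2**31 - 1))
    def test_density_bound_after_upper_cutoff(self, L, seed):
        # tie-free matrices: final density <= 1 - q + 1/L^2 when triggered
        rng = np.random.default_rng(seed)
        m = rng.permutation(L * L).reshape(L, L) / (L * L)  # distinct values
        cfg = BinarizationConfig(density_trigger=0.01)
        out = binarize(m, cfg)
        q = cfg.upper_keep_quantile
        assert out.mean() <= 1 - q + 1 / (L * L) + 1e-12

    def test_p20_preset_always_drops_lowest_fifth(self):
        m = RNG.uniform(0, 1, (10, 10))
        out = binarize(m, BinarizationConfig.preset("p20"))
        u = nearest_rank_quantile_oracle(m, 0.20)
        lo = m.min() + 0.10 * (m.max() - m.min())
        np.testing.assert_array_equal(out, ((m >= lo) & (m >= u)).astype(int))

    def test_tiny_matrix_rejected(self):
        with pytest.raises(EmptyMatrix):
            binarize(np.array([[1.0]]))


class TestBuildGraph:
    def test_identity_matrix_yields_no_edges(self):
        g = build_graph(np.eye(4, dtype=int))
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 0

    def test_single_directed_edge(self):
        b = np.zeros((6, 6), dtype=int)
        b[1, 4] = 1  # residues 2 -> 5
        g = build_graph(b)
        assert list(g.edges) == [(2, 5)]

    def test_symmetrize_mode_undirects(self):
        b = np.zeros((6, 6), dtype=int)
        b[1, 4] = 1
        g = build_graph(b, "symmetrize")
        assert not g.is_directed()
        assert set(map(frozenset, g.edges)) == {frozenset({2, 5})}


class TestDetectCommunities:
    def test_two_disjoint_cliques_recovered(self):
        b = np.zeros((12, 12), dtype=int)
        b[np.ix_(range(6), range(6))] = 1
        b[np.ix_(range(6, 12), range(6, 12))] = 1
        part = detect_communities(build_graph(b))
        assert sorted(map(sorted, part)) == [list(range(1, 7)), list(range(7, 13))]

    def test_edgeless_graph_gives_singletons(self):
        part = detect_communities(build_graph(np.zeros((5, 5), dtype=int)))
        assert part == [{1}, {2}, {3}, {4}, {5}]

    def test_complete_graph_single_community(self):
        part = detect_communities(build_graph(np.ones((8, 8), dtype=int)))
        assert part == [set(range(1, 9))]

    def test_deterministic_under_seed(self):
        b = (RNG.uniform(0, 1, (20, 20)) < 0.3).astype(int)
        cfg = LouvainConfig(seed=4)
        assert detect_communities(build_graph(b), cfg) == detect_communities(
            build_graph(b), cfg
        )


class TestAssembleWords:
    def test_contiguous_community_becomes_word(self):
        seq = random_seq(10)
        words = assemble_words([{3, 4, 5, 6, 7}], seq)
        assert len(words) == 1
        assert words[0].gap_count == 0
        assert words[0].literal == seq.residues[2:7]

    def test_one_gap_allowed(self):
        seq = random_seq(10)
        (w,) = assemble_words([{1, 2, 3, 7, 8}], seq)
        assert w.gap_count == 1
        assert "_" in w.literal

    @pytest.mark.parametrize(
        "community",
        [{1, 3, 5, 7, 9}, {1, 2, 3, 4}, set(range(1, 25))],
    )
    def test_fragmented_small_or_oversized_discarded(self, community):
        seq = random_seq(30)
        assert assemble_words([community], seq) == []


class TestParseSequence:
    def test_recovers_planted_block(self):
        L = 80
        seq = random_seq(L)
        planted = tuple(range(21, 30))
        stack = make_planted_attention(
            L,
            [PlantedWordSpec(positions=planted, head_indices=(0, 1))],
            noise_level=0.02,
            n_heads=2,
            seed=2,
        )
        stack.sequence_id = seq.id
        words = parse_sequence(seq, stack)
        assert any(w.positions == planted for w in words)

    def test_all_zero_stack_has_no_words(self):
        seq = random_seq(60)
        stack = make_planted_attention(
            60, [], noise_level=0.0, n_heads=2, seed=0
        )
        stack.sequence_id = seq.id
        assert parse_sequence(seq, stack) == []

    def test_duplicate_words_merge_source_heads(self):
        L = 60
        seq = random_seq(L)
        planted = tuple(range(5, 12))
        stack = make_planted_attention(
            L,
            [PlantedWordSpec(positions=planted, head_indices=(0, 1, 2))],
            noise_level=0.0,
            n_heads=3,
            seed=0,
        )
        stack.sequence_id = seq.id
        words = [w for w in parse_sequence(seq, stack) if w.positions == planted]
        assert len(words) == 1
        assert len(words[0].source_heads) == 3

    def test_words_can_overlap_across_heads(self):
        L = 60
        seq = random_seq(L)
        stack = make_planted_attention(
            L,
            [
                PlantedWordSpec(positions=tuple(range(10, 18)), head_indices=(0,)),
                PlantedWordSpec(positions=tuple(range(14, 22)), head_indices=(1,)),
            ],
            noise_level=0.0,
            n_heads=2,
            seed=0,
        )
        stack.sequence_id = seq.id
        words = parse_sequence(seq, stack)
        sets = [set(w.positions) for w in words]
        assert any(a & b for i, a in enumerate(sets) for b in sets[i + 1 :])

    def test_every_emitted_word_satisfies_geometry(self):
        # random planted stacks; all outputs must be 5-20 residues, <= 2 gaps
        for trial in range(100):
            rng = np.random.default_rng(trial)
            L = int(rng.integers(50, 120))
            seq = random_seq(L, f"t{trial}")
            n_specs = int(rng.integers(1, 4))
            specs, used = [], set()
            for _ in range(n_specs):
                size = int(rng.integers(5, 15))
                start = int(rng.integers(1, L - size + 1))
                pos = set(range(start, start + size))
                if pos & used:
                    continue
                used |= pos
                specs.append(PlantedWordSpec(positions=tuple(sorted(pos))))
            stack = make_planted_attention(L, specs, 0.05, 1, seed=trial)
            stack.sequence_id = seq.id
            for w in parse_sequence(seq, stack):
                assert 5 <= w.n_residues <= 20
                assert w.gap_count <= 2
                assert list(w.positions) == sorted(set(w.positions))

    def test_rerun_is_identical(self):
        seq = random_seq(70)
        stack = make_planted_attention(
            70, [PlantedWordSpec(positions=tuple(range(30, 40)))], 0.05, 2, seed=5
        )
        stack.sequence_id = seq.id
        a = parse_sequence(seq, stack)
        b = parse_sequence(seq, stack)
        assert [(w.positions, w.literal) for w in a] == [
            (w.positions, w.literal) for w in b
        ]


class TestWordSegmenter:
    def test_sklearn_protocol(self):
        seg = WordSegmenter(lower_frac=0.2, seed=3)
        params = seg.get_params()
        assert params["lower_frac"] == 0.2
        cloned = clone(seg)
        assert cloned.get_params() == params
        seg.set_params(resolution=1.5)
        assert seg.resolution == 1.5

    def test_transform_matches_parse_sequence(self):
        seq = random_seq(60)
        stack = make_planted_attention(
            60, [PlantedWordSpec(positions=tuple(range(10, 17)))], 0.05, 1, seed=1
        )
        stack.sequence_id = seq.id
        seg = WordSegmenter().fit()
        (words,) = seg.transform([(seq, stack)])
        assert [w.positions for w in words] == [
            w.positions for w in parse_sequence(seq, stack)
        ]
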