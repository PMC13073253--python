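"""The unsupervised word-segmentation engine.

Each attention head of a protein language model yields an L x L matrix of
pairwise residue weights.  The engine (i) binarizes the matrix with a
dual-cutoff rule, (ii) interprets the binary matrix as a directed residue
graph, (iii) partitions the graph with Louvain community detection, and
(iv) keeps every community of 5-20 residues with at most two gaps as a
"raw protein word".  Words from all heads are pooled and deduplicated.

Binarization rule
-----------------
Let ``b = min + lower_frac * (max - min)`` (default ``lower_frac = 0.10``):
entries below ``b`` become 0, the rest 1.  If the resulting density of ones
over all L^2 entries exceeds ``density_trigger`` (default 0.40), an upper
bound ``u`` -- the ``upper_keep_quantile`` (default 0.60) nearest-rank
quantile of *all original entries* -- is additionally applied: every entry
whose original value is below ``u`` is zeroed.  An all-zero matrix is
treated as edgeless (no words), overriding the constant-matrix corner for
the zero constant: zero attention encodes no interaction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import EmptyMatrix
from .plm import _stable_seed
from .types import (
    AttentionStack,
    ProteinSequence,
    ProteinWord,
    positions_to_runs,
    word_sort_key,
)


@dataclass(frozen=True)
class BinarizationConfig:
    """Dual-cutoff binarization parameters.

    ``lower_mode='relative'`` interprets ``lower_frac`` as a fraction of the
    matrix's own value range; ``'absolute'`` uses it as a fixed threshold.
    ``always_upper=True`` applies the quantile cutoff unconditionally (the
    "discard the lowest 20%" preset) instead of only past the density trigger.
    """

    lower_frac: float = 0.10
    density_trigger: float = 0.40
    upper_keep_quantile: float = 0.60
    percentile_method: str = "nearest_rank"  # or "linear_interpolation"
    lower_mode: str = "relative"  # or "absolute"
    always_upper: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.lower_frac < 1):
            raise ValueError("lower_frac must be in (0, 1)")
        if not (0 < self.density_trigger < 1):
            raise ValueError("density_trigger must be in (0, 1)")
        if not (0 < self.upper_keep_quantile < 1):
            raise ValueError("upper_keep_quantile must be in (0, 1)")
        if self.percentile_method not in ("nearest_rank", "linear_interpolation"):
            raise ValueError("unknown percentile_method")
        if self.lower_mode not in ("relative", "absolute"):
            raise ValueError("unknown lower_mode")

    @classmethod
    def preset(cls, name: str) -> "BinarizationConfig":
        """Named presets: ``p60`` (default dual-cutoff) and ``p20``
        (unconditionally drop the lowest 20% of attention values)."""
        if name == "p60":
            return cls()
        if name == "p20":
            return cls(upper_keep_quantile=0.20, always_upper=True)
        raise ValueError(f"unknown binarization preset {name!r}")


@dataclass(frozen=True)
class LouvainConfig:
    """Louvain parameters: resolution gamma, modularity-gain stop threshold
    dQ, seed for the node-visit shuffle, and directed-vs-symmetrized mode."""

    resolution: float = 1.0
    modularity_gain_threshold: float = 1e-7
    seed: int = 0
    directed_mode: str = "directed"  # or "symmetrize"
    refine: bool = True
    n_restarts: int = 4

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.modularity_gain_threshold <= 0:
            raise ValueError("modularity_gain_threshold must be positive")
        if self.directed_mode not in ("directed", "symmetrize"):
            raise ValueError("unknown directed_mode")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be at least 1")


@dataclass(frozen=True)
class WordFilterConfig:
    """Community size and gap filter defining a valid protein word."""

    min_len: int = 5
    max_len: int = 20
    max_gaps: int = 2

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile on the sorted multiset: v[ceil(q*N)] (1-based)."""
    v = np.sort(values, axis=None)
    rank = max(1, math.ceil(q * v.size))
    return float(v[rank - 1])


def binarize(matrix: np.ndarray, cfg: BinarizationConfig | None = None) -> np.ndarray:
    """Binarize one attention matrix with the dual-cutoff rule."""
    cfg = cfg or BinarizationConfig()
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[0] != matrix.shape[1]:
        raise EmptyMatrix(f"expected a square matrix with L >= 2, got {matrix.shape}")
    mx = float(matrix.max())
    if mx == 0.0:
        return np.zeros_like(matrix, dtype=np.int8)
    mn = float(matrix.min())
    if cfg.lower_mode == "relative":
        b = mn + cfg.lower_frac * (mx - mn)
    else:
        b = cfg.lower_frac
    binary = (matrix >= b).astype(np.int8)
    density = binary.mean()
    if cfg.always_upper or density > cfg.density_trigger:
        if cfg.percentile_method == "nearest_rank":
            u = nearest_rank_quantile(matrix, cfg.upper_keep_quantile)
        else:
            u = float(np.quantile(matrix, cfg.upper_keep_quantile))
        binary[matrix < u] = 0
    return binary


def build_graph(binary: np.ndarray, directed_mode: str = "directed") -> nx.Graph:
    """Residue graph of a binary matrix: nodes 1..L, edge i->j iff entry 1.

    Self-loops are dropped.  ``symmetrize`` replaces the edge set with its
    undirected closure.
    """
    L = binary.shape[0]
    rows, cols = np.nonzero(binary)
    edges = [(int(i) + 1, int(j) + 1) for i, j in zip(rows, cols) if i != j]
    g: nx.Graph = nx.Graph() if directed_mode == "symmetrize" else nx.DiGraph()
    g.add_nodes_from(range(1, L + 1))
    g.add_edges_from(edges)
    return g


def _refine_partition(
    graph: nx.DiGraph,
    partition: list[set[int]],
    gamma: float,
    threshold: float,
    swap_node_limit: int = 64,
    split_size_limit: int = 10,
    kick_node_limit: int = 16,
) -> list[set[int]]:
    """Greedy refinement of a partition under directed modularity.

    Iterates four deterministic improvement phases until none yields a gain
    above ``threshold``: (1) single-node moves to neighboring communities or
    detachment into a singleton (Louvain's local rule applied at the finest
    level to the final partition), (2) pairwise community merges,
    (3) exhaustive bipartition of small communities (up to
    ``split_size_limit`` nodes), (4) pairwise node swaps between
    communities, on graphs of at most ``swap_node_limit`` nodes, and
    (5) on graphs of at most ``kick_node_limit`` nodes, a Kernighan-Lin
    style depth-2 search: force one (possibly worsening) move, re-run the
    local moves to convergence, and keep the excursion if the net
    modularity improves.  Phases (3)-(5) repair the known Louvain failure
    modes -- stranded communities, coordinated exchanges, and barriers that
    require a temporarily worsening step -- that greedy single-node moves
    cannot cross.  Nodes are visited in sorted order and ties break
    deterministically, so the result is reproducible.
    """
    m = graph.number_of_edges()
    if m == 0:
        return partition
    kin = dict(graph.in_degree())
    kout = dict(graph.out_degree())
    comm_of: dict[int, int] = {}
    comms: dict[int, set[int]] = {}
    for cid, nodes in enumerate(partition):
        comms[cid] = set(nodes)
        for v in nodes:
            comm_of[v] = cid
    sig_in = {cid: sum(kin[v] for v in c) for cid, c in comms.items()}
    sig_out = {cid: sum(kout[v] for v in c) for cid, c in comms.items()}
    state = {"next_cid": len(partition)}
    inv_m = 1.0 / m
    inv_m2 = gamma / (m * m)

    def degree_into(v, cid):
        d = sum(1 for u in graph.successors(v) if u != v and comm_of[u] == cid)
        d += sum(1 for u in graph.predecessors(v) if u != v and comm_of[u] == cid)
        return d

    def move_gain(v, b):
        """Modularity gain of moving v from its community to b (None = new)."""
        a = comm_of[v]
        d_a = degree_into(v, a)
        d_b = degree_into(v, b) if b is not None else 0
        si_b = sig_in[b] if b is not None else 0
        so_b = sig_out[b] if b is not None else 0
        return (d_b - d_a) * inv_m - inv_m2 * (
            kout[v] * (si_b - (sig_in[a] - kin[v]))
            + kin[v] * (so_b - (sig_out[a] - kout[v]))
        )

    def apply_move(v, b):
        a = comm_of[v]
        if b is None:
            b = state["next_cid"]
            state["next_cid"] += 1
            comms[b] = set()
            sig_in[b] = sig_out[b] = 0
        comms[a].discard(v)
        sig_in[a] -= kin[v]
        sig_out[a] -= kout[v]
        if not comms[a]:
            del comms[a], sig_in[a], sig_out[a]
        comms[b].add(v)
        sig_in[b] += kin[v]
        sig_out[b] += kout[v]
        comm_of[v] = b
        return b

    def local_moves():
        """Phase-1 sweep: best single-node moves until convergence."""
        any_moved = False
        moved = True
        while moved:
            moved = False
            for v in sorted(comm_of):
                a = comm_of[v]
                targets = {
                    comm_of[u]
                    for u in (*graph.successors(v), *graph.predecessors(v))
                    if u != v
                }
                targets.discard(a)
                candidates = sorted(targets, key=lambda c: min(comms[c]))
                if len(comms[a]) > 1:
                    candidates.append(None)
                best_gain, best, found = threshold, None, False
                for b in candidates:
                    gain = move_gain(v, b)
                    if gain > best_gain:
                        best_gain, best, found = gain, b, True
                if found:
                    apply_move(v, best)
                    moved = any_moved = True
        return any_moved

    def current_q():
        intra = sum(1 for u, w in graph.edges if comm_of[u] == comm_of[w])
        null = sum(sig_out[c] * sig_in[c] for c in comms)
        return intra * inv_m - null * inv_m2

    def snapshot():
        return (
            {c: set(nodes) for c, nodes in comms.items()},
            dict(comm_of),
            dict(sig_in),
            dict(sig_out),
            state["next_cid"],
        )

    def restore(saved):
        comms.clear()
        comms.update({c: set(nodes) for c, nodes in saved[0].items()})
        comm_of.clear()
        comm_of.update(saved[1])
        sig_in.clear()
        sig_in.update(saved[2])
        sig_out.clear()
        sig_out.update(saved[3])
        state["next_cid"] = saved[4]

    improved_any = True
    while improved_any:
        improved_any = False

        # phase 1: single-node moves
        if local_moves():
            improved_any = True

        # phase 2: pairwise merges of connected communities
        pair_edges: dict[tuple[int, int], int] = {}
        for u, w in graph.edges:
            cu, cw = comm_of[u], comm_of[w]
            if cu != cw:
                key = (cu, cw) if cu < cw else (cw, cu)
                pair_edges[key] = pair_edges.get(key, 0) + 1
        best_gain, best_pair = threshold, None
        for (ca, cb), e_ab in sorted(pair_edges.items()):
            gain = e_ab * inv_m - inv_m2 * (
                sig_out[ca] * sig_in[cb] + sig_out[cb] * sig_in[ca]
            )
            if gain > best_gain:
                best_gain, best_pair = gain, (ca, cb)
        if best_pair is not None:
            ca, cb = best_pair
            for v in comms[cb]:
                comm_of[v] = ca
            comms[ca] |= comms[cb]
            sig_in[ca] += sig_in[cb]
            sig_out[ca] += sig_out[cb]
            del comms[cb], sig_in[cb], sig_out[cb]
            improved_any = True
            continue

        # phase 3: exhaustive bipartition of small communities (the split
        # gain is the negative of the corresponding merge gain)
        split_done = False
        for cid in sorted(comms):
            nodes = sorted(comms[cid])
            k = len(nodes)
            if k < 2 or k > split_size_limit:
                continue
            intra = [
                (u, w)
                for u, w in graph.edges
                if u != w and comm_of[u] == cid and comm_of[w] == cid
            ]
            best_gain, best_mask = threshold, None
            for bitmask in range(1, 2 ** (k - 1)):
                in_a = [bool(bitmask >> i & 1) for i in range(k)]
                side = dict(zip(nodes, in_a))
                cross = sum(1 for u, w in intra if side[u] != side[w])
                so_a = sum(kout[v] for v in nodes if side[v])
                si_a = sum(kin[v] for v in nodes if side[v])
                gain = -cross * inv_m + inv_m2 * (
                    so_a * (sig_in[cid] - si_a) + (sig_out[cid] - so_a) * si_a
                )
                if gain > best_gain:
                    best_gain, best_mask = gain, bitmask
            if best_mask is not None:
                group_a = {nodes[i] for i in range(k) if best_mask >> i & 1}
                group_b = set(nodes) - group_a
                new_cid = state["next_cid"]
                state["next_cid"] += 1
                comms[cid] = group_a
                sig_in[cid] = sum(kin[v] for v in group_a)
                sig_out[cid] = sum(kout[v] for v in group_a)
                comms[new_cid] = group_b
                sig_in[new_cid] = sum(kin[v] for v in group_b)
                sig_out[new_cid] = sum(kout[v] for v in group_b)
                for v in group_b:
                    comm_of[v] = new_cid
                improved_any = split_done = True
                break
        if split_done:
            continue

        # phase 4: pairwise node swaps (small graphs only)
        if len(comm_of) <= swap_node_limit:
            best_gain, best_swap = threshold, None
            cids = sorted(comms, key=lambda c: min(comms[c]))
            for ia, ca in enumerate(cids):
                for cb in cids[ia + 1 :]:
                    for u in sorted(comms[ca]):
                        g1 = move_gain(u, cb)
                        # evaluate v's counter-move analytically in the
                        # post-u-move state (no mutation)
                        si_ca = sig_in[ca] - kin[u]
                        so_ca = sig_out[ca] - kout[u]
                        si_cb = sig_in[cb] + kin[u]
                        so_cb = sig_out[cb] + kout[u]
                        for v in sorted(comms[cb]):
                            adj_uv = int(graph.has_edge(u, v)) + int(
                                graph.has_edge(v, u)
                            )
                            d_ca = degree_into(v, ca) - adj_uv
                            d_cb = degree_into(v, cb) + adj_uv
                            g2 = (d_ca - d_cb) * inv_m - inv_m2 * (
                                kout[v] * (si_ca - (si_cb - kin[v]))
                                + kin[v] * (so_ca - (so_cb - kout[v]))
                            )
                            if g1 + g2 > best_gain:
                                best_gain, best_swap = g1 + g2, (u, cb, v, ca)
            if best_swap is not None:
                # exchange memberships directly so neither community
                # transiently empties
                u, cb, v, ca = best_swap
                comms[ca].discard(u)
                comms[cb].discard(v)
                comms[ca].add(v)
                comms[cb].add(u)
                sig_in[ca] += kin[v] - kin[u]
                sig_out[ca] += kout[v] - kout[u]
                sig_in[cb] += kin[u] - kin[v]
                sig_out[cb] += kout[u] - kout[v]
                comm_of[u], comm_of[v] = cb, ca
                improved_any = True
                continue

        # phase 5: depth-2 kick (tiny graphs): force one move, re-converge
        # with local moves, keep the excursion iff net modularity improves
        if not improved_any and len(comm_of) <= kick_node_limit:
            q0 = current_q()
            base = snapshot()
            best_q, best_state = q0 + threshold, None
            for v in sorted(comm_of):
                a = comm_of[v]
                targets = {
                    comm_of[u]
                    for u in (*graph.successors(v), *graph.predecessors(v))
                    if u != v
                }
                targets.discard(a)
                options = sorted(targets, key=lambda c: min(comms[c]))
                if len(comms[a]) > 1:
                    options.append(None)
                for b in options:
                    apply_move(v, b)
                    local_moves()
                    q = current_q()
                    if q > best_q:
                        best_q, best_state = q, snapshot()
                    restore(base)
            if best_state is not None:
                restore(best_state)
                improved_any = True

    return [set(c) for c in comms.values()]


def detect_communities(
    graph: nx.Graph, cfg: LouvainConfig | None = None
) -> list[set[int]]:
    """Louvain partition of the residue graph, deterministic under the seed.

    Louvain is order-sensitive, so ``n_restarts`` greedy runs are launched
    from seeds derived from ``cfg.seed`` and the partition with the highest
    modularity is kept; each run's result is post-processed by a node-level
    move/merge/split/swap refinement on the original graph (see
    :func:`_refine_partition`; disable with ``refine=False``).  An edgeless
    graph partitions into singletons.  Output communities are sorted by
    their smallest node for reproducible downstream ordering.
    """
    cfg = cfg or LouvainConfig()
    if graph.number_of_nodes() == 0:
        return []
    if graph.number_of_edges() == 0:
        return [{n} for n in sorted(graph.nodes)]
    g = graph
    if cfg.directed_mode == "symmetrize" and g.is_directed():
        g = g.to_undirected()
    directed = g if g.is_directed() else g.to_directed()
    best_q, best = -np.inf, None
    for restart in range(cfg.n_restarts):
        comms = nx.community.louvain_communities(
            g,
            resolution=cfg.resolution,
            threshold=cfg.modularity_gain_threshold,
            seed=(cfg.seed + restart) & 0x7FFFFFFF,
        )
        comms = [set(c) for c in comms]
        if cfg.refine:
            comms = _refine_partition(
                directed, comms, cfg.resolution, cfg.modularity_gain_threshold
            )
        q = nx.community.modularity(g, comms, resolution=cfg.resolution)
        if q > best_q + 1e-15:
            best_q, best = q, comms
    return sorted((set(c) for c in best), key=min)


def assemble_words(
    partition: list[set[int]],
    seq: ProteinSequence,
    filter_cfg: WordFilterConfig | None = None,
    head_label: tuple[int, int] = (0, 0),
) -> list[ProteinWord]:
    """Turn communities into protein words, discarding out-of-spec clusters.

    A community survives iff it has ``min_len``-``max_len`` members and at
    most ``max_gaps`` gaps; oversized or fragmented clusters are discarded,
    not repaired.
    """
    filter_cfg = filter_cfg or WordFilterConfig()
    words = []
    for comm in partition:
        n = len(comm)
        if n < filter_cfg.min_len or n > filter_cfg.max_len:
            continue
        pos = sorted(comm)
        if len(positions_to_runs(pos)) - 1 > filter_cfg.max_gaps:
            continue
        words.append(
            ProteinWord.from_positions(seq.id, pos, seq.residues, [head_label])
        )
    return words


def parse_sequence(
    seq: ProteinSequence,
    stack: AttentionStack,
    bin_cfg: BinarizationConfig | None = None,
    louvain_cfg: LouvainConfig | None = None,
    filter_cfg: WordFilterConfig | None = None,
) -> list[ProteinWord]:
    """Segment one sequence into raw words using every head of its stack.

    Words with identical position sets arising from different heads are
    merged (their source-head sets union); within one head communities are
    disjoint, but words may overlap across heads.  Output order is
    deterministic: first position, then residue count, then literal.
    """
    bin_cfg = bin_cfg or BinarizationConfig()
    louvain_cfg = louvain_cfg or LouvainConfig()
    filter_cfg = filter_cfg or WordFilterConfig()
    if stack.length != len(seq):
        raise ValueError(
            f"stack length {stack.length} does not match sequence length {len(seq)}"
        )
    by_positions: dict[tuple[int, ...], ProteinWord] = {}
    for idx, (label, mat) in enumerate(zip(stack.head_labels, stack.heads)):
        binary = binarize(mat, bin_cfg)
        graph = build_graph(binary, louvain_cfg.directed_mode)
        head_cfg = replace(louvain_cfg, seed=_stable_seed(louvain_cfg.seed, idx))
        partition = detect_communities(graph, head_cfg)
        for w in assemble_words(partition, seq, filter_cfg, head_label=label):
            prev = by_positions.get(w.positions)
            if prev is None:
                by_positions[w.positions] = w
            else:
                by_positions[w.positions] = ProteinWord(
                    sequence_id=w.sequence_id,
                    positions=w.positions,
                    literal=w.literal,
                    source_heads=prev.source_heads | w.source_heads,
                )
    return sorted(by_positions.values(), key=word_sort_key)


class WordSegmenter(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer: (sequence, attention stack) -> words.

    The transform is stateless (``fit`` only validates parameters), but the
    estimator interface lets the segmenter participate in sklearn pipelines
    and grid search over its cutoff/resolution parameters.

    Parameters mirror :class:`BinarizationConfig`, :class:`LouvainConfig`
    and :class:`WordFilterConfig`.
    """

    def __init__(
        self,
        lower_frac: float = 0.10,
        density_trigger: float = 0.40,
        upper_keep_quantile: float = 0.60,
        percentile_method: str = "nearest_rank",
        lower_mode: str = "relative",
        always_upper: bool = False,
        resolution: float = 1.0,
        modularity_gain_threshold: float = 1e-7,
        directed_mode: str = "directed",
        min_len: int = 5,
        max_len: int = 20,
        max_gaps: int = 2,
        seed: int = 0,
    ) -> None:
        self.lower_frac = lower_frac
        self.density_trigger = density_trigger
        self.upper_keep_quantile = upper_keep_quantile
        self.percentile_method = percentile_method
        self.lower_mode = lower_mode
        self.always_upper = always_upper
        self.resolution = resolution
        self.modularity_gain_threshold = modularity_gain_threshold
        self.directed_mode = directed_mode
        self.min_len = min_len
        self.max_len = max_len
        self.max_gaps = max_gaps
        self.seed = seed

    def _configs(self):
        return (
            BinarizationConfig(
                lower_frac=self.lower_frac,
                density_trigger=self.density_trigger,
                upper_keep_quantile=self.upper_keep_quantile,
                percentile_method=self.percentile_method,
                lower_mode=self.lower_mode,
                always_upper=self.always_upper,
            ),
            LouvainConfig(
                resolution=self.resolution,
                modularity_gain_threshold=self.modularity_gain_threshold,
                seed=self.seed,
                directed_mode=self.directed_mode,
            ),
            WordFilterConfig(
                min_len=self.min_len, max_len=self.max_len, max_gaps=self.max_gaps
            ),
        )

    def fit(self, X=None, y=None) -> "WordSegmenter":
        self._configs()  # parameter validation
        self.is_fitted_ = True
        return self

    def transform(self, X) -> list[list[ProteinWord]]:
        """X: iterable of (ProteinSequence, AttentionStack) pairs."""
        bin_cfg, louvain_cfg, filter_cfg = self._configs()
        return [
            parse_sequence(seq, stack, bin_cfg, louvain_cfg, filter_cfg)
            for seq, stack in X
        ]
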