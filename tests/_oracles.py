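"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own code paths: modularity is
computed from the definition, quantiles from the sorted multiset, and
metrics from explicit set arithmetic with exact rational numbers.
"""
from __future__ import annotations

from fractions import Fraction

import numpy as np


def set_partitions(items):
    """Yield every partition of ``items`` as a list of lists."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def directed_modularity(edges, partition, gamma=1.0):
    """Newman modularity of a directed unweighted graph from the definition.

    Q = sum_ij (A_ij/m - gamma * kout_i * kin_j / m^2) * [c_i == c_j].
    """
    m = len(edges)
    if m == 0:
        return 0.0
    label = {}
    for ci, comm in enumerate(partition):
        for node in comm:
            label[node] = ci
    kout, kin = {}, {}
    for u, v in edges:
        kout[u] = kout.get(u, 0) + 1
        kin[v] = kin.get(v, 0) + 1
    q = sum(1 for u, v in edges if label[u] == label[v]) / m
    for comm in partition:
        so = sum(kout.get(n, 0) for n in comm)
        si = sum(kin.get(n, 0) for n in comm)
        q -= gamma * so * si / (m * m)
    return q


def best_partition_modularity(nodes, edges, gamma=1.0):
    """Exhaustive maximum of directed modularity over all node partitions."""
    best = -np.inf
    for part in set_partitions(nodes):
        q = directed_modularity(edges, part, gamma)
        if q > best:
            best = q
    return best


def nearest_rank_quantile_oracle(values, q):
    """Nearest-rank quantile over the sorted multiset of all values."""
    v = sorted(np.asarray(values).ravel().tolist())
    import math

    rank = max(1, math.ceil(q * len(v)))
    return v[rank - 1]


def binarize_oracle(matrix, lower_frac=0.10, density_trigger=0.40,
                    upper_keep_quantile=0.60):
    """Straight-from-definition dual-cutoff binarization."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.max() == 0.0:
        return np.zeros_like(matrix, dtype=int)
    lo = matrix.min() + lower_frac * (matrix.max() - matrix.min())
    binary = (matrix >= lo).astype(int)
    if binary.sum() / matrix.size > density_trigger:
        u = nearest_rank_quantile_oracle(matrix, upper_keep_quantile)
        binary[matrix < u] = 0
    return binary


# --- exact-rational metric oracles -------------------------------------------

def coverage_oracle(word_position_sets, functional):
    union = set().union(*word_position_sets) if word_position_sets else set()
    return Fraction(len(functional & union), len(functional))


def word_accuracy_oracle(word_position_sets, functional):
    hits = sum(1 for w in word_position_sets if w & functional)
    return Fraction(hits, len(word_position_sets))


def efficiency_oracle(word_position_sets, functional):
    union = set().union(*word_position_sets)
    total = sum(len(w) for w in word_position_sets)
    return Fraction(len(functional & union), total)


def precision_oracle(word_position_sets, functional):
    union = set().union(*word_position_sets)
    return Fraction(len(functional & union), len(union))


def mcc_oracle(tp, fp, tn, fn):
    """MCC via 50-digit decimal arithmetic (high-precision reference)."""
    from decimal import Decimal, getcontext

    getcontext().prec = 50
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return float(Decimal(tp * tn - fn * fp) / Decimal(denom2).sqrt())
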