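"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (exhaustive enumeration, direct
definitions) that never share code with the package internals.
"""
from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def hypergeom_tail_enumeration(n: int, M: int, N: int, U: int) -> Fraction:
    """P(X >= n) by enumerating every N-subset of a U-element universe
    and counting its overlap with the fixed subset {0..M-1}."""
    fixed = set(range(M))
    hits = total = 0
    for subset in itertools.combinations(range(U), N):
        total += 1
        if len(fixed.intersection(subset)) >= n:
            hits += 1
    return Fraction(hits, total)


def overlap_histogram(M: int, N: int, U: int) -> dict[int, int]:
    """Counts of each overlap size over all N-subsets (shared helper for
    scanning every n at once)."""
    fixed = set(range(M))
    hist: dict[int, int] = {}
    for subset in itertools.combinations(range(U), N):
        k = len(fixed.intersection(subset))
        hist[k] = hist.get(k, 0) + 1
    return hist


def spearman_rank_pearson(x, y) -> float:
    """Spearman rho via the definition: mean-rank the data, then compute
    a plain Pearson correlation on the ranks."""
    def mean_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0  # average of 1-based ranks
            i = j
        return ranks
    rx, ry = mean_ranks(x), mean_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def kcore_peel(adjacency: dict, k: int) -> set:
    """k-core by iterative removal of vertices with degree < k."""
    nodes = set(adjacency)
    changed = True
    while changed:
        changed = False
        for v in list(nodes):
            if sum(1 for w in adjacency[v] if w in nodes) < k:
                nodes.discard(v)
                changed = True
    return nodes


def mcode_vertex_weight_bruteforce(adjacency: dict, v, degree_cutoff: int = 2) -> float:
    """MCODE vertex weight from first principles: peel the closed
    neighbourhood for every k until empty, keep the highest non-empty
    core, and multiply its density by k."""
    neighbors = set(adjacency[v])
    if len(neighbors) < degree_cutoff:
        return 0.0
    nodes = neighbors | {v}
    sub = {a: [b for b in adjacency[a] if b in nodes] for a in nodes}
    best_k, best_core = 0, nodes
    k = 1
    while True:
        core = kcore_peel(sub, k)
        if not core:
            break
        best_k, best_core = k, core
        k += 1
    m = sum(1 for a in best_core for b in sub[a] if b in best_core) // 2
    n = len(best_core)
    density = 0.0 if n < 2 else 2.0 * m / (n * (n - 1))
    return best_k * density
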