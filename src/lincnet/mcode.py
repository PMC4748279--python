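"""Molecular Complex Detection (MCODE) for mining dense sub-networks.

The algorithm has three stages:

1. *Vertex weighting* — each vertex is scored by the density of the
   highest k-core of its closed neighbourhood, multiplied by that core
   number k.  Vertices below the degree cutoff score 0.
2. *Complex prediction* — unassigned vertices seed complexes in
   decreasing weight order; a complex grows outward (breadth-first,
   depth-limited) over unassigned neighbours whose weight is at least
   ``seed weight * (1 - node_score_cutoff)`` and which are attached to
   the growing complex by at least two edges (once it has two members).
   The attachment requirement keeps a single bridge edge from chaining
   two dense regions into one complex and stops sparse chains (paths,
   simple cycles) from seeding complexes at all.
3. *Post-processing* — complexes lacking a k-core of the configured
   order are dropped; *fluff* optionally adds boundary vertices with a
   dense closed neighbourhood (these may be shared between complexes);
   *haircut* trims the complex to its 2-core.  Complexes with fewer than
   two members are discarded.

All ties (equal weights, equal scores) break lexicographically by node
or community id so the output is independent of node insertion order.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .errors import ConfigError, DomainError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class McodeParams:
    """Cytoscape-plugin default parameters."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ConfigError("node_score_cutoff must be in [0, 1]")
        if not 0.0 <= self.fluff_density_cutoff <= 1.0:
            raise ConfigError("fluff_density_cutoff must be in [0, 1]")
        if min(self.degree_cutoff, self.k_core, self.max_depth) < 1:
            raise ConfigError("degree_cutoff, k_core and max_depth must be >= 1")


@dataclass(frozen=True)
class Community:
    """An MCODE complex: its members, seed vertex and score
    (density of the complex subgraph times its node count)."""

    community_id: str
    members: frozenset
    seed: str
    score: float

    def __post_init__(self):
        if self.score < 0:
            raise DomainError("complex score must be >= 0")


def _closed_neighborhood_core(graph: nx.Graph, v) -> tuple[int, float]:
    """Highest k-core of v's closed neighbourhood: (k, density of that core)."""
    nbhd = graph.subgraph([v, *graph.neighbors(v)])
    core_numbers = nx.core_number(nbhd)
    k = max(core_numbers.values())
    core_nodes = [n for n, c in core_numbers.items() if c >= k]
    return k, nx.density(nbhd.subgraph(core_nodes))


def vertex_weights(graph: nx.Graph, degree_cutoff: int = 2) -> dict:
    """Core-clustering weight of every vertex; degree < cutoff scores 0."""
    weights = {}
    for v in graph.nodes:
        if graph.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        k, density = _closed_neighborhood_core(graph, v)
        weights[v] = k * density
    return weights


def complex_score(graph: nx.Graph, members) -> float:
    """Edge density of the induced subgraph times the member count."""
    members = set(members)
    if len(members) < 2:
        raise DomainError("complex score needs >= 2 members")
    sub = graph.subgraph(members)
    return nx.density(sub) * len(members)


def _expand_complex(graph: nx.Graph, weights: dict, seed, assigned: set,
                    params: McodeParams) -> set:
    """Breadth-first, depth-limited greedy expansion from the seed."""
    threshold = weights[seed] * (1.0 - params.node_score_cutoff)
    members = {seed}
    frontier = [seed]
    depth = 0
    while frontier and depth < params.max_depth:
        next_frontier = []
        for v in frontier:
            for w in sorted(graph.neighbors(v), key=str):
                if w in members or w in assigned:
                    continue
                if weights[w] < threshold:
                    continue
                attachment = sum(1 for u in graph.neighbors(w) if u in members)
                if len(members) >= 2 and attachment < 2:
                    continue  # a single edge is not dense attachment
                members.add(w)
                next_frontier.append(w)
        frontier = next_frontier
        depth += 1
    return members


def _fluff(graph: nx.Graph, members: set, cutoff: float) -> set:
    """Add boundary neighbours whose closed neighbourhood is dense enough.
    Fluffed vertices may belong to several complexes."""
    extra = set()
    for v in members:
        for w in graph.neighbors(v):
            if w in members or w in extra:
                continue
            nbhd = graph.subgraph([w, *graph.neighbors(w)])
            if nx.density(nbhd) > cutoff:
                extra.add(w)
    return members | extra


def find_complexes(graph: nx.Graph, params: McodeParams | None = None) -> list[Community]:
    """Run the full MCODE procedure and return complexes sorted by score
    (descending), breaking ties by size (larger first) then seed id."""
    params = params or McodeParams()
    weights = vertex_weights(graph, params.degree_cutoff)
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    raw: list[tuple[str, set]] = []
    for seed in order:
        if seed in assigned:
            continue
        members = _expand_complex(graph, weights, seed, assigned, params)
        assigned |= members
        raw.append((seed, members))

    complexes: list[tuple[str, frozenset, float]] = []
    for seed, members in raw:
        if len(members) < 2:
            continue
        # complex must contain a k-core of the configured order
        sub = graph.subgraph(members)
        if max(nx.core_number(sub).values()) < params.k_core:
            continue
        if params.fluff:
            members = _fluff(graph, members, params.fluff_density_cutoff)
        if params.haircut:
            members = set(nx.k_core(graph.subgraph(members), 2).nodes)
        if len(members) < 2:
            continue
        if seed not in members:
            seed = min(members, key=str)
        complexes.append((seed, frozenset(members),
                          complex_score(graph, members)))

    complexes.sort(key=lambda c: (-c[2], -len(c[1]), str(c[0])))
    return [Community(community_id=f"C{i:03d}", members=m, seed=s, score=sc)
            for i, (s, m, sc) in enumerate(complexes, start=1)]
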