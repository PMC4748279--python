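"""GO over-representation analysis and three-tier lincRNA annotation.

Communities are annotated with their single most significant GO term
(hypergeometric upper tail, raw p < alpha).  Each lincRNA then receives
at most one GO term by guilt-by-association:

* tier ``community`` — the lincRNA sits in an annotated community and
  inherits its term;
* tier ``neighbor_enrichment`` — otherwise, enrichment over its direct
  gene neighbours in the network; the top passing term is assigned;
* tier ``neighbor_majority`` — otherwise, the term annotating the
  largest number of distinct gene neighbours (no p-value attached).

Only genes carry GO annotations; lincRNAs never count toward the query
set M or the universe U.  GO terms are flat labels here — no ontology
propagation is applied.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import DomainError
from .mcode import Community
from .network import hypergeom_upper_tail

logger = logging.getLogger(__name__)

ALPHA_ENRICH = 0.05

TIER_COMMUNITY = "community"
TIER_NEIGHBOR_ENRICHMENT = "neighbor_enrichment"
TIER_NEIGHBOR_MAJORITY = "neighbor_majority"


@dataclass(frozen=True)
class EnrichmentResult:
    go_id: str
    go_name: str
    n: int          # |query ∩ term|
    M: int          # annotated query genes
    N: int          # term genes in the universe
    U: int          # universe size
    p: float

    def __post_init__(self):
        if self.n > min(self.M, self.N) or not 0.0 <= self.p <= 1.0:
            raise DomainError(f"inconsistent enrichment result {self!r}")


@dataclass(frozen=True)
class LincAnnotation:
    lincrna_id: str
    go_id: str
    go_name: str
    tier: str
    p: float | None = None
    community_id: str | None = None

    def __post_init__(self):
        if self.tier not in (TIER_COMMUNITY, TIER_NEIGHBOR_ENRICHMENT,
                             TIER_NEIGHBOR_MAJORITY):
            raise DomainError(f"unknown tier {self.tier!r}")
        if self.tier == TIER_COMMUNITY and (self.p is None or self.community_id is None):
            raise DomainError("community-tier annotation needs p and community id")
        if self.tier == TIER_NEIGHBOR_MAJORITY and self.p is not None:
            raise DomainError("majority-tier annotation carries no p-value")


def go_universe(go_table: pd.DataFrame) -> frozenset[str]:
    """Default enrichment universe: every gene with >= 1 GO annotation."""
    return frozenset(go_table["gene_id"])


def go_enrichment(query_genes: Iterable[str],
                  go_table: pd.DataFrame,
                  universe: Iterable[str],
                  alpha: float = ALPHA_ENRICH) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each GO term hit by the query.

    Returns terms with p < alpha sorted ascending by p, ties broken by
    GO id.  The query is intersected with the universe before testing.
    """
    universe = frozenset(universe)
    if not universe:
        raise DomainError("empty enrichment universe")
    anno = go_table[go_table["gene_id"].isin(universe)]
    query = frozenset(query_genes) & universe
    M, U = len(query), len(universe)
    if M == 0:
        return []
    names = dict(zip(anno["go_id"], anno["go_name"]))
    term_genes = anno.groupby("go_id")["gene_id"].agg(frozenset)
    results = []
    for go_id, genes in term_genes.items():
        n = len(query & genes)
        if n == 0:
            continue
        p = hypergeom_upper_tail(n, M, len(genes), U)
        if p < alpha:
            results.append(EnrichmentResult(go_id=go_id, go_name=names.get(go_id, ""),
                                            n=n, M=M, N=len(genes), U=U, p=p))
    results.sort(key=lambda r: (r.p, r.go_id))
    return results


def annotate_communities(communities: Sequence[Community],
                         go_table: pd.DataFrame,
                         universe: Iterable[str],
                         rna_types: Mapping[str, str],
                         alpha: float = ALPHA_ENRICH,
                         ) -> dict[str, EnrichmentResult | None]:
    """Assign each community its minimum-p enriched term (or None)."""
    out: dict[str, EnrichmentResult | None] = {}
    for com in communities:
        genes = [m for m in com.members if rna_types.get(m) == "gene"]
        hits = go_enrichment(genes, go_table, universe, alpha) if genes else []
        out[com.community_id] = hits[0] if hits else None
    n_annotated = sum(1 for v in out.values() if v is not None)
    logger.info("annotate_communities: %d/%d communities annotated (%.1f%%)",
                n_annotated, len(out), 100.0 * n_annotated / len(out) if out else 0.0)
    return out


def annotate_lincrnas(net: nx.Graph,
                      communities: Sequence[Community],
                      community_annotations: Mapping[str, EnrichmentResult | None],
                      go_table: pd.DataFrame,
                      universe: Iterable[str],
                      alpha: float = ALPHA_ENRICH) -> list[LincAnnotation]:
    """Three-tier guilt-by-association annotation of every lincRNA node."""
    universe = frozenset(universe)
    gene_terms = go_table.groupby("gene_id")["go_id"].agg(set)
    names = dict(zip(go_table["go_id"], go_table["go_name"]))
    by_score = sorted(communities, key=lambda c: (-c.score, c.community_id))

    annotations: list[LincAnnotation] = []
    lincs = sorted(n for n, d in net.nodes(data=True) if d.get("rna_type") == "lincRNA")
    for linc in lincs:
        # tier 1: inherit from the highest-scoring annotated community
        tier1 = None
        for com in by_score:
            if linc in com.members:
                res = community_annotations.get(com.community_id)
                if res is not None:
                    tier1 = (com.community_id, res)
                    break
        if tier1 is not None:
            cid, res = tier1
            annotations.append(LincAnnotation(linc, res.go_id, res.go_name,
                                              TIER_COMMUNITY, p=res.p,
                                              community_id=cid))
            continue
        gene_neighbors = [n for n in net.neighbors(linc)
                          if net.nodes[n].get("rna_type") == "gene"]
        # tier 2: enrichment over direct gene neighbours
        hits = go_enrichment(gene_neighbors, go_table, universe, alpha) \
            if gene_neighbors else []
        if hits:
            top = hits[0]
            annotations.append(LincAnnotation(linc, top.go_id, top.go_name,
                                              TIER_NEIGHBOR_ENRICHMENT, p=top.p))
            continue
        # tier 3: majority term over distinct annotated gene neighbours
        counts: dict[str, int] = {}
        for g in gene_neighbors:
            for t in gene_terms.get(g, ()):
                counts[t] = counts.get(t, 0) + 1
        if counts:
            go_id = min(counts, key=lambda t: (-counts[t], t))
            annotations.append(LincAnnotation(linc, go_id, names.get(go_id, ""),
                                              TIER_NEIGHBOR_MAJORITY))
    logger.info("annotate_lincrnas: annotated %d/%d lincRNAs",
                len(annotations), len(lincs))
    return annotations
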