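"""End-to-end orchestration: network -> communities -> annotation ->
key lincRNAs, plus recovery metrics against a planted truth."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from . import annotate, keylinc, mcode, network
from .io import ExpressionMatrix, SampleMeta, TargetMap
from .mcode import Community, McodeParams
from .simulate import PlantedTruth, SimConfig, simulate_expression, \
    simulate_go_annotations, simulate_target_map

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    net: nx.Graph
    communities: list[Community]
    community_annotations: dict
    linc_annotations: list
    de_table: pd.DataFrame
    key_report: keylinc.KeyLincReport
    clustering: keylinc.SampleClustering | None


def run_pipeline(targets: TargetMap,
                 expr: ExpressionMatrix,
                 go_table: pd.DataFrame,
                 de_table: pd.DataFrame,
                 tissue: str = "root",
                 condition: str = "starved",
                 alpha_overlap: float = network.ALPHA_OVERLAP,
                 alpha_corr: float = network.ALPHA_CORR,
                 alpha_enrich: float = annotate.ALPHA_ENRICH,
                 hub_fraction: float = keylinc.HUB_FRACTION,
                 mcode_params: McodeParams | None = None) -> PipelineResult:
    """Run every stage on already-loaded tables.

    Correlation is computed over the stress-condition samples of the
    requested tissue, the study's convention.
    """
    def stress(s: SampleMeta) -> bool:
        return s.tissue == tissue and s.condition == condition

    candidates = network.candidate_pairs(targets, expr.rna_ids, alpha_overlap)
    net = network.build_network(candidates, expr, stress, alpha_corr)
    communities = mcode.find_complexes(net, mcode_params)
    universe = annotate.go_universe(go_table)
    rna_types = {r: str(expr.rna_types[r]) for r in expr.rna_ids}
    comm_anno = annotate.annotate_communities(communities, go_table, universe,
                                              rna_types, alpha_enrich)
    linc_anno = annotate.annotate_lincrnas(net, communities, comm_anno,
                                           go_table, universe, alpha_enrich)
    _, hubs = keylinc.hub_threshold(net, hub_fraction) if net.number_of_nodes() \
        else (0, frozenset())
    report = keylinc.select_key_lincrnas(net, hubs, de_table, linc_anno,
                                         tissue=tissue)
    clustering = None
    if report.entries:
        try:
            clustering = keylinc.cluster_samples(
                expr, [e[0] for e in report.entries], stress)
        except Exception as exc:  # degenerate feature sets stay reportable
            logger.warning("sample clustering skipped: %s", exc)
    return PipelineResult(net=net, communities=communities,
                          community_annotations=comm_anno,
                          linc_annotations=linc_anno, de_table=de_table,
                          key_report=report, clustering=clustering)


def run_synthetic(cfg: SimConfig, **kwargs) -> tuple[PipelineResult, PlantedTruth,
                                                     ExpressionMatrix]:
    """Simulate a data set under ``cfg`` and run the full pipeline on it.
    DE calls come from the built-in two-group test over the lincRNAs."""
    targets, truth = simulate_target_map(cfg)
    expr = simulate_expression(cfg, truth)
    go_table = simulate_go_annotations(cfg, truth)
    linc_ids = expr.lincrna_ids()
    de_table = keylinc.simple_de_all_timepoints(
        ExpressionMatrix(expr.values.loc[linc_ids],
                         expr.rna_types[linc_ids], expr.samples),
        conditions=cfg.conditions)
    result = run_pipeline(targets, expr, go_table, de_table,
                          tissue=cfg.tissue, condition=cfg.conditions[1],
                          **kwargs)
    return result, truth, expr


# ---------------------------------------------------------------------------
# recovery metrics against the planted truth
# ---------------------------------------------------------------------------

def edge_recall(net: nx.Graph, truth: PlantedTruth) -> float:
    """Fraction of planted within-module RNA pairs present as edges."""
    pairs = truth.within_module_pairs()
    hit = sum(1 for a, b in pairs if net.has_edge(a, b))
    return hit / len(pairs) if pairs else float("nan")


def edge_pairwise_f1(net: nx.Graph, truth: PlantedTruth) -> float:
    """Pairwise F1 of network edges against planted within-module pairs."""
    pairs = truth.within_module_pairs()
    edges = {tuple(sorted(e)) for e in net.edges}
    tp = len(pairs & edges)
    if tp == 0:
        return 0.0
    precision = tp / len(edges)
    recall = tp / len(pairs)
    return 2 * precision * recall / (precision + recall)


def lincrna_go_recovery(linc_annotations, truth: PlantedTruth) -> float:
    """Fraction of planted-module lincRNAs annotated (any tier) with
    their own module's GO term."""
    by_linc = {a.lincrna_id: a.go_id for a in linc_annotations}
    planted = [(linc, mod.go_term)
               for mod in truth.modules for linc in mod.lincrnas]
    hit = sum(1 for linc, term in planted if by_linc.get(linc) == term)
    return hit / len(planted) if planted else float("nan")


def decoy_tier1_rate(linc_annotations, truth: PlantedTruth) -> float:
    """Fraction of community-tier annotations assigning a decoy
    (non-planted) term to a planted-module lincRNA; 0 on clean recovery."""
    planted_terms = {m.go_term for m in truth.modules}
    planted_lincs = set().union(*(m.lincrnas for m in truth.modules))
    tier1 = [a for a in linc_annotations
             if a.tier == annotate.TIER_COMMUNITY and a.lincrna_id in planted_lincs]
    if not tier1:
        return 0.0
    return sum(1 for a in tier1 if a.go_id not in planted_terms) / len(tier1)


def key_lincrna_recall(report: keylinc.KeyLincReport, truth: PlantedTruth) -> float:
    """Fraction of planted responsive lincRNAs appearing as key lincRNAs."""
    if not truth.de_lincrnas:
        return float("nan")
    return len(report.lincrna_ids & truth.de_lincrnas) / len(truth.de_lincrnas)


def early_late_agreement(clustering: keylinc.SampleClustering,
                         expr: ExpressionMatrix,
                         late_start_index: int) -> float:
    """Agreement (best over label swap) between the 2-group partition and
    the early/late split of the clustered samples."""
    order = []
    for s in expr.samples:
        if s.timepoint not in order:
            order.append(s.timepoint)
    late_tps = set(order[late_start_index:])
    meta = {s.sample_id: s for s in expr.samples}
    truth_labels = [1 if meta[sid].timepoint in late_tps else 0
                    for sid in clustering.sample_ids]
    pred = [clustering.two_groups[sid] - 1 for sid in clustering.sample_ids]
    agree = sum(int(t == p) for t, p in zip(truth_labels, pred))
    return max(agree, len(pred) - agree) / len(pred)
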