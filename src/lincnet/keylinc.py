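"""Hub selection, key-lincRNA identification and sample clustering.

Hubs are the top 20% of network nodes by degree (ties at the boundary
are included, so the realised threshold is a strict lower bound on hub
degree).  Key lincRNAs are hub lincRNAs that are differentially
expressed (FDR < 0.05) at one or more time points of the stress time
course.  Samples can be hierarchically clustered on the key lincRNAs
(correlation distance, average linkage), which on late-responding
stress data splits the time course into early and late phases.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .annotate import LincAnnotation
from .errors import ConfigError, DomainError, UndefinedResultError
from .io import ExpressionMatrix, SampleMeta

logger = logging.getLogger(__name__)

DE_ALPHA = 0.05
HUB_FRACTION = 0.2


@dataclass(frozen=True)
class KeyLincReport:
    """Key lincRNAs of one tissue: (id, degree, annotation or None),
    sorted by degree descending."""

    tissue: str
    degree_threshold: int
    entries: tuple[tuple[str, int, LincAnnotation | None], ...]

    @property
    def lincrna_ids(self) -> frozenset[str]:
        return frozenset(e[0] for e in self.entries)


def hub_threshold(net: nx.Graph, fraction: float = HUB_FRACTION) -> tuple[int, frozenset]:
    """Top-``fraction`` nodes by degree, ties at the boundary included.

    Returns the realised strict threshold (the largest degree among
    non-hubs; hubs are exactly the nodes with degree > threshold) and
    the hub set.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise DomainError("hub selection undefined for an empty network")
    if not 0.0 < fraction <= 1.0:
        raise ConfigError("hub fraction must be in (0, 1]")
    degrees = dict(net.degree())
    ranked = sorted(degrees, key=lambda v: (-degrees[v], str(v)))
    k = max(1, math.floor(fraction * n))
    cutoff_degree = degrees[ranked[k - 1]]
    hubs = frozenset(v for v in ranked if degrees[v] >= cutoff_degree)
    non_hub_degrees = [degrees[v] for v in ranked if v not in hubs]
    if non_hub_degrees:
        threshold = max(non_hub_degrees)
    else:
        threshold = cutoff_degree - 1
        logger.warning("hub_threshold: all %d nodes tied into the hub set", n)
    return threshold, hubs


def de_lincrnas(de_table: pd.DataFrame, alpha: float = DE_ALPHA) -> frozenset[str]:
    """RNAs with FDR < alpha at one or more time points."""
    hit = de_table[de_table["fdr"] < alpha]
    return frozenset(hit["rna_id"])


def select_key_lincrnas(net: nx.Graph,
                        hubs: Iterable[str],
                        de_table: pd.DataFrame,
                        annotations: Sequence[LincAnnotation] = (),
                        tissue: str = "root",
                        alpha: float = DE_ALPHA) -> KeyLincReport:
    """Key lincRNAs = hub ∧ lincRNA ∧ differentially expressed somewhere."""
    hubs = set(hubs)
    de_set = de_lincrnas(de_table, alpha)
    by_linc = {a.lincrna_id: a for a in annotations}
    degrees = dict(net.degree())
    non_hub = [degrees[v] for v in net.nodes if v not in hubs]
    threshold = max(non_hub) if non_hub else (min(degrees.values()) - 1 if degrees else 0)
    entries = []
    for v in sorted(hubs, key=lambda v: (-degrees[v], str(v))):
        if net.nodes[v].get("rna_type") != "lincRNA":
            continue
        if v not in de_set:
            continue
        entries.append((v, degrees[v], by_linc.get(v)))
    return KeyLincReport(tissue=tissue, degree_threshold=threshold,
                         entries=tuple(entries))


def compare_key_sets(a: KeyLincReport | Iterable[str],
                     b: KeyLincReport | Iterable[str],
                     ) -> tuple[frozenset, frozenset, frozenset]:
    """Exact intersection/differences of two key-lincRNA id sets."""
    ids_a = a.lincrna_ids if isinstance(a, KeyLincReport) else frozenset(a)
    ids_b = b.lincrna_ids if isinstance(b, KeyLincReport) else frozenset(b)
    return ids_a & ids_b, ids_a - ids_b, ids_b - ids_a


@dataclass
class SampleClustering:
    """Full merge tree plus the flat two-group partition."""

    sample_ids: list[str]
    linkage: np.ndarray
    two_groups: dict[str, int]

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        def walk(node):
            if node.is_leaf():
                return self.sample_ids[node.id]
            return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"
        return walk(tree) + ";"


def cluster_samples(expr: ExpressionMatrix,
                    feature_ids: Iterable[str],
                    sample_filter: Callable[[SampleMeta], bool] = lambda s: True,
                    standardize: bool = True,
                    metric: str = "uncentered") -> SampleClustering:
    """Agglomerative clustering of samples on log2(RPKM+1) feature rows
    with average linkage; the flat partition is the top-level 2-cut.

    By default each feature row is z-scored across the clustered samples
    (the expression-heatmap convention) and sample profiles are compared
    with 1 minus the *uncentered* correlation — the classic
    expression-clustering similarity, which keeps a shared up-shift of
    the features visible.  ``metric="pearson"`` gives the centered
    variant instead, which is blind to feature-uniform shifts.
    Zero-variance features are dropped; an entirely constant feature
    set is a degenerate input.
    """
    if metric not in ("uncentered", "pearson"):
        raise ConfigError(f"unknown clustering metric {metric!r}")
    sub = expr.select_samples(sample_filter)
    if len(sub.samples) < 2:
        raise ConfigError("clustering needs >= 2 samples after filtering")
    feature_ids = [f for f in feature_ids if f in sub.values.index]
    X = np.log2(sub.values.loc[feature_ids].to_numpy(dtype=float) + 1.0).T
    keep = X.std(axis=0) > 0
    if not keep.any():
        raise UndefinedResultError("all clustering features have zero variance")
    X = X[:, keep]
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    dists = pdist(X, metric="cosine" if metric == "uncentered" else "correlation")
    Z = hierarchy.linkage(dists, method="average")
    flat = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    ids = [s.sample_id for s in sub.samples]
    return SampleClustering(sample_ids=ids, linkage=Z,
                            two_groups=dict(zip(ids, (int(c) for c in flat))))


def simple_de(expr: ExpressionMatrix,
              timepoint: str,
              conditions: tuple[str, str] = ("control", "starved"),
              ) -> pd.DataFrame:
    """Per-RNA Welch t-test on log2(RPKM+1) replicate values at one
    time point, Benjamini–Hochberg corrected across the tested RNAs.

    A deliberately simple two-group test for synthetic data; it is not
    equivalent to a count-based negative-binomial DE model and should
    not be applied to real read counts.
    """
    groups = []
    for cond in conditions:
        cols = [s.sample_id for s in expr.samples
                if s.timepoint == timepoint and s.condition == cond]
        if len(cols) < 2:
            raise ConfigError(
                f"need >= 2 replicates for condition {cond!r} at {timepoint!r}")
        groups.append(np.log2(expr.values[cols].to_numpy(dtype=float) + 1.0))
    a, b = groups
    pvals = np.ones(len(expr.values.index))
    for i in range(a.shape[0]):
        if np.ptp(a[i]) == 0 and np.ptp(b[i]) == 0:
            pvals[i] = 1.0 if a[i, 0] == b[i, 0] else 0.0
            continue
        _, p = stats.ttest_ind(a[i], b[i], equal_var=False)
        pvals[i] = 1.0 if math.isnan(p) else p
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"rna_id": expr.values.index, "timepoint": timepoint,
                         "fdr": fdr})


def simple_de_all_timepoints(expr: ExpressionMatrix,
                             conditions: tuple[str, str] = ("control", "starved"),
                             ) -> pd.DataFrame:
    seen = []
    for s in expr.samples:
        if s.timepoint not in seen:
            seen.append(s.timepoint)
    return pd.concat([simple_de(expr, tp, conditions) for tp in seen],
                     ignore_index=True)
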