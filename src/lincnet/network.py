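"""Construction and topology analysis of the ceRNA network.

Two RNAs form a candidate ceRNA pair when the overlap of their miRNA
regulator sets is larger than expected by chance under a hypergeometric
null (upper-tail test at alpha 0.05).  Candidates are confirmed as ceRNA
pairs when their expression profiles are significantly positively
rank-correlated over the configured sample subset.  The result is a
simple undirected graph whose nodes are typed ``gene`` or ``lincRNA``
and whose edges carry the full test results.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .errors import ConfigError, DomainError, UndefinedResultError
from .io import ExpressionMatrix, SampleMeta, TargetMap

logger = logging.getLogger(__name__)

ALPHA_OVERLAP = 0.05
ALPHA_CORR = 0.05


@dataclass(frozen=True)
class OverlapTest:
    """Hypergeometric shared-regulator test for one RNA pair.

    n shared regulators out of regulator sets of sizes M and N drawn
    from a universe of U miRNAs; p is the inclusive upper tail P(X >= n).
    """

    n: int
    M: int
    N: int
    U: int
    p: float

    def __post_init__(self):
        if not (0 <= self.n <= min(self.M, self.N) and self.M <= self.U
                and self.N <= self.U and 0.0 <= self.p <= 1.0):
            raise DomainError(f"inconsistent overlap test {self!r}")


@dataclass(frozen=True)
class DegreeFit:
    """Log-log least-squares fit of the degree-frequency distribution."""

    exponent: float
    correlation: float
    r_squared: float


def hypergeom_upper_tail(n: int, M: int, N: int, U: int) -> float:
    """P(X >= n) where X is the overlap of a random N-subset with a fixed
    M-subset of a U-element universe.

    Computed through the survival function of the hypergeometric
    distribution, which is evaluated in log space internally and is
    stable for universes well beyond 1e5.
    """
    if U < 1 or M < 0 or N < 0 or M > U or N > U:
        raise DomainError(f"invalid universe/set sizes M={M}, N={N}, U={U}")
    if not 0 <= n <= min(M, N):
        raise DomainError(f"overlap n={n} outside [0, min(M={M}, N={N})]")
    if n == 0:
        return 1.0
    p = float(stats.hypergeom.sf(n - 1, U, M, N))
    return min(max(p, 0.0), 1.0)


def candidate_pairs(targets: TargetMap,
                    rnas: Iterable[str],
                    alpha_overlap: float = ALPHA_OVERLAP,
                    ) -> list[tuple[tuple[str, str], OverlapTest]]:
    """Evaluate the shared-regulator test on all unordered pairs of
    eligible RNAs and return those with p < alpha_overlap, ordered
    lexicographically by pair.

    RNAs with no miRNA regulator in the target map are excluded up front
    (their overlap test is undefined) and counted in the log.
    """
    U = targets.universe_size
    if U < 1:
        raise DomainError("empty miRNA universe")
    regulators = targets.regulators_of_rnas()
    rnas = sorted(set(rnas))
    eligible = [r for r in rnas if regulators.get(r)]
    skipped = len(rnas) - len(eligible)
    if skipped:
        logger.info("candidate_pairs: excluded %d RNA(s) with no miRNA regulator",
                    skipped)
    mirna_index = {m: i for i, m in enumerate(sorted(targets.universe))}
    A = np.zeros((len(eligible), U), dtype=bool)
    for i, r in enumerate(eligible):
        for m in regulators[r]:
            A[i, mirna_index[m]] = True
    sizes = A.sum(axis=1)
    shared = A.astype(np.int32) @ A.T.astype(np.int32)

    # p-values vectorised over the distinct (n, M, N) triples actually seen
    out: list[tuple[tuple[str, str], OverlapTest]] = []
    cache: dict[tuple[int, int, int], float] = {}
    for i, j in itertools.combinations(range(len(eligible)), 2):
        n = int(shared[i, j])
        M, N = int(sizes[i]), int(sizes[j])
        key = (n, M, N)
        p = cache.get(key)
        if p is None:
            p = hypergeom_upper_tail(n, M, N, U)
            cache[key] = p
        if p < alpha_overlap:
            out.append(((eligible[i], eligible[j]),
                        OverlapTest(n=n, M=M, N=N, U=U, p=p)))
    return out


def spearman_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Ties receive average ranks.  Series shorter than 3 or with zero
    variance give (nan, nan): the caller skips such pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        return (math.nan, math.nan)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    rho, p = stats.spearmanr(x, y)
    if math.isnan(rho):
        return (math.nan, math.nan)
    if abs(rho) >= 1.0 - 1e-12:  # perfect monotone up to float error in ranks
        return (math.copysign(1.0, rho), 0.0)
    return (float(rho), float(p))


def build_network(candidates: Sequence[tuple[tuple[str, str], OverlapTest]],
                  expr: ExpressionMatrix,
                  sample_filter: Callable[[SampleMeta], bool],
                  alpha_corr: float = ALPHA_CORR) -> nx.Graph:
    """Confirm candidate pairs by positive Spearman correlation over the
    filtered samples and assemble the ceRNA network.

    Only nodes incident to at least one retained edge appear; node types
    are copied from the expression matrix.
    """
    sub = expr.select_samples(sample_filter)
    if len(sub.samples) < 3:
        raise ConfigError(
            f"sample filter selected {len(sub.samples)} samples; need >= 3")
    values = sub.values
    net = nx.Graph()
    n_skipped = 0
    for (a, b), overlap in candidates:
        if a not in values.index or b not in values.index:
            raise ConfigError(f"candidate RNA missing from expression matrix: "
                              f"{a if a not in values.index else b!r}")
        rho, p_rho = spearman_with_p(values.loc[a].to_numpy(),
                                     values.loc[b].to_numpy())
        if math.isnan(rho):
            n_skipped += 1
            continue
        if rho > 0 and p_rho < alpha_corr:
            net.add_edge(a, b, shared_count=overlap.n, p_overlap=overlap.p,
                         rho=rho, p_rho=p_rho)
    if n_skipped:
        logger.info("build_network: skipped %d pair(s) with undefined correlation",
                    n_skipped)
    for node in net.nodes:
        net.nodes[node]["rna_type"] = str(expr.rna_types[node])
    logger.info("build_network: %d nodes, %d edges (from %d candidates)",
                net.number_of_nodes(), net.number_of_edges(), len(candidates))
    return net


def validate_network(net: nx.Graph,
                     alpha_overlap: float = ALPHA_OVERLAP,
                     alpha_corr: float = ALPHA_CORR) -> None:
    """Check the stored-edge invariants: overlap p < alpha, rho > 0 with
    p_rho < alpha, simple graph, typed endpoints."""
    if any(a == b for a, b in net.edges):
        raise DomainError("network contains a self-loop")
    for n, d in net.nodes(data=True):
        if d.get("rna_type") not in ("gene", "lincRNA"):
            raise DomainError(f"node {n!r} lacks a valid rna_type")
    for a, b, d in net.edges(data=True):
        if not d["p_overlap"] < alpha_overlap:
            raise DomainError(f"edge ({a},{b}) fails overlap test")
        if not (d["rho"] > 0 and d["p_rho"] < alpha_corr):
            raise DomainError(f"edge ({a},{b}) fails correlation test")


def average_degree(net: nx.Graph) -> float:
    if net.number_of_nodes() == 0:
        raise DomainError("average degree undefined for an empty network")
    return 2.0 * net.number_of_edges() / net.number_of_nodes()


def average_degree_from_counts(n_nodes: int, n_edges: int) -> float:
    if n_nodes <= 0:
        raise DomainError("average degree undefined without nodes")
    return 2.0 * n_edges / n_nodes


def degree_powerlaw_fit(net: nx.Graph) -> DegreeFit:
    """Ordinary least squares on (log10 degree, log10 frequency) of the
    degree-frequency table (zero-frequency and zero degrees omitted).

    The slope's negation is reported as the power-law exponent, together
    with the Pearson correlation of the log-log points and its square.
    """
    degrees = [d for _, d in net.degree() if d > 0]
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 3:
        raise UndefinedResultError(
            f"power-law fit needs >= 3 distinct positive degrees, got {len(values)}")
    lx, ly = np.log10(values), np.log10(counts)
    fit = stats.linregress(lx, ly)
    return DegreeFit(exponent=-float(fit.slope),
                     correlation=float(fit.rvalue),
                     r_squared=float(fit.rvalue) ** 2)


def topology_report(net: nx.Graph) -> dict:
    """Node/edge counts, lincRNA count, average degree and (when defined)
    the power-law fit — the summary printed by the CLI."""
    n_linc = sum(1 for _, d in net.nodes(data=True) if d.get("rna_type") == "lincRNA")
    report = {
        "nodes": net.number_of_nodes(),
        "edges": net.number_of_edges(),
        "lincrnas": n_linc,
        "average_degree": average_degree(net) if net.number_of_nodes() else math.nan,
    }
    try:
        fit = degree_powerlaw_fit(net)
        report.update(powerlaw_exponent=fit.exponent,
                      powerlaw_correlation=fit.correlation,
                      powerlaw_r_squared=fit.r_squared)
    except UndefinedResultError:
        pass
    return report
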