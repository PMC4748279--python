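"""Shared-regulator test, correlation filter and network topology."""
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import hypergeom_tail_enumeration, spearman_rank_pearson
from lincnet import (ExpressionMatrix, SampleMeta, TargetMap, average_degree,
                     average_degree_from_counts, build_network,
                     candidate_pairs, degree_powerlaw_fit,
                     hypergeom_upper_tail, spearman_with_p)
from lincnet.errors import ConfigError, DomainError, UndefinedResultError
from lincnet.network import validate_network


class TestHypergeomUpperTail:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper_tail(0, 5, 7, 100) == 1.0

    def test_forced_total_overlap(self):
        assert hypergeom_upper_tail(3, 3, 3, 3) == pytest.approx(1.0)

    def test_small_case_equals_enumeration(self):
        # C(10,4) = 210 subsets enumerated independently
        expected = hypergeom_tail_enumeration(2, 3, 4, 10)
        assert expected == Fraction(1, 3)
        assert hypergeom_upper_tail(2, 3, 4, 10) == pytest.approx(float(expected),
                                                                  abs=1e-12)

    @pytest.mark.parametrize("n,M,N,U", [
        (1, 1, 1, 2), (2, 2, 3, 6), (3, 4, 4, 9), (4, 5, 6, 11), (1, 6, 2, 12),
    ])
    def test_matches_enumeration_oracle(self, n, M, N, U):
        expected = float(hypergeom_tail_enumeration(n, M, N, U))
        assert hypergeom_upper_tail(n, M, N, U) == pytest.approx(expected, abs=1e-12)

    def test_large_universe_is_stable(self):
        p = hypergeom_upper_tail(40, 50, 60, 100_000)
        assert 0.0 <= p < 1e-50  # extreme overlap: tiny but finite, not 0/nan
        assert math.isfinite(p)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(1, 60), st.integers(1, 60), st.integers(60, 200))
    def test_monotone_nonincreasing_in_overlap(self, M, N, U):
        tail = [hypergeom_upper_tail(n, M, N, U) for n in range(min(M, N) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(tail, tail[1:]))

    def test_rejects_invalid_arguments(self):
        with pytest.raises(DomainError):
            hypergeom_upper_tail(4, 3, 5, 10)   # n > min(M, N)
        with pytest.raises(DomainError):
            hypergeom_upper_tail(1, 11, 5, 10)  # M > U


def _target_map(pairs):
    out = {}
    for mir, rna in pairs:
        out.setdefault(mir, set()).add(rna)
    return TargetMap({m: frozenset(t) for m, t in out.items()})


class TestCandidatePairs:
    def test_full_overlap_selected_with_closed_form_p(self):
        mirs = [f"m{i}" for i in range(100)]
        pairs = [(m, r) for m in mirs[:5] for r in ("A", "B")]
        pairs += [(m, f"bg{i}") for i, m in enumerate(mirs[5:])]  # fill U to 100
        tm = _target_map(pairs)
        result = candidate_pairs(tm, ["A", "B"])
        assert len(result) == 1
        (a, b), ov = result[0]
        assert (a, b) == ("A", "B") and ov.n == 5
        assert ov.p == pytest.approx(1 / math.comb(100, 5), rel=1e-12)

    def test_disjoint_regulators_rejected(self):
        tm = _target_map([("m1", "A"), ("m2", "B"), ("m3", "C")])
        assert candidate_pairs(tm, ["A", "B", "C"]) == []

    def test_rna_without_regulators_excluded(self):
        tm = _target_map([("m1", "A"), ("m1", "B")])
        result = candidate_pairs(tm, ["A", "B", "Z"])
        assert all("Z" not in pair for pair, _ in result)

    def test_empty_universe_errors(self):
        with pytest.raises(DomainError):
            candidate_pairs(TargetMap({}), ["A", "B"])

    def test_label_equivariance(self):
        pairs = [("m1", "A"), ("m1", "B"), ("m2", "A"), ("m2", "B"),
                 ("m3", "C"), ("m1", "C")]
        tm = _target_map(pairs)
        base = candidate_pairs(tm, ["A", "B", "C"], alpha_overlap=1.1)
        perm = {"A": "C", "B": "A", "C": "B"}
        tm2 = _target_map([(m, perm[r]) for m, r in pairs])
        permuted = candidate_pairs(tm2, ["A", "B", "C"], alpha_overlap=1.1)
        base_map = {tuple(sorted(perm[x] for x in pair)): ov.p for pair, ov in base}
        perm_map = {tuple(sorted(pair)): ov.p for pair, ov in permuted}
        assert base_map == perm_map


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_with_p([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == 1.0 and p == 0.0

    def test_perfect_antitone(self):
        rho, p = spearman_with_p([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert rho == -1.0 and p == 0.0

    @pytest.mark.parametrize("x,y", [
        ([1, 2, 2, 4], [3, 5, 4, 8]),
        ([1, 1, 2, 3, 3], [2, 1, 5, 4, 4]),
        ([5, 1, 4, 4, 2, 2], [1, 2, 2, 3, 3, 3]),
    ])
    def test_ties_match_mean_rank_pearson_oracle(self, x, y):
        rho, _ = spearman_with_p(x, y)
        assert rho == pytest.approx(spearman_rank_pearson(x, y), abs=1e-12)

    def test_degenerate_series_signal_nan(self):
        assert math.isnan(spearman_with_p([1, 1, 1], [1, 2, 3])[0])
        assert math.isnan(spearman_with_p([1, 2], [3, 4])[0])


def _expr(values: dict, n_samples: int, types=None) -> ExpressionMatrix:
    samples = [SampleMeta(f"s{i}", "root", "starved", f"t{i}", i + 1.0, 1)
               for i in range(n_samples)]
    df = pd.DataFrame(values, index=[s.sample_id for s in samples]).T
    rtypes = pd.Series({r: (types or {}).get(r, "gene") for r in df.index})
    return ExpressionMatrix(df, rtypes, samples)


def _overlap_candidates(pairs):
    from lincnet.network import OverlapTest
    ov = OverlapTest(n=3, M=3, N=3, U=100, p=1e-6)
    return [(p, ov) for p in pairs]


class TestBuildNetwork:
    def test_negative_correlation_excluded(self):
        expr = _expr({"A": [1, 2, 3, 4, 5], "B": [5, 4, 3, 2, 1]}, 5)
        net = build_network(_overlap_candidates([("A", "B")]), expr, lambda s: True)
        assert net.number_of_edges() == 0

    def test_positive_correlation_retained_with_attributes(self):
        expr = _expr({"A": [1, 2, 3, 4, 5], "B": [2, 4, 5, 8, 9]}, 5,
                     types={"B": "lincRNA"})
        net = build_network(_overlap_candidates([("A", "B")]), expr, lambda s: True)
        assert net.has_edge("A", "B")
        assert net.nodes["B"]["rna_type"] == "lincRNA"
        validate_network(net)

    def test_no_candidates_gives_empty_network(self):
        expr = _expr({"A": [1, 2, 3]}, 3)
        assert build_network([], expr, lambda s: True).number_of_nodes() == 0

    def test_too_few_samples_is_config_error(self):
        expr = _expr({"A": [1, 2, 3], "B": [1, 2, 3]}, 3)
        with pytest.raises(ConfigError):
            build_network(_overlap_candidates([("A", "B")]), expr,
                          lambda s: s.sample_id == "s0")


class TestTopology:
    def test_average_degree_matches_reported_root_network(self):
        assert round(average_degree_from_counts(4847, 31794), 2) == 13.12

    def test_average_degree_matches_reported_shoot_network(self):
        assert round(average_degree_from_counts(4979, 63660), 2) == 25.57

    def test_triangle(self):
        net = nx.cycle_graph(3)
        assert average_degree(net) == 2.0

    def test_average_degree_equals_mean_of_degree_list(self):
        net = nx.gnp_random_graph(40, 0.15, seed=5)
        degrees = [d for _, d in net.degree()]
        assert average_degree(net) == pytest.approx(np.mean(degrees))

    def test_empty_network_errors(self):
        with pytest.raises(DomainError):
            average_degree(nx.Graph())

    def test_exact_power_law_recovered(self):
        net = nx.Graph()
        node = 0
        # frequency table f(k) = round(1000 k^-2), realised as star-free stubs:
        # build an explicit degree-frequency structure via a configuration-like
        # trick is overkill — fit the table directly through a crafted graph
        # of many small stars is fragile, so instead check on a graph whose
        # degree counts follow the law exactly: disjoint cliques K_{k+1}
        # give k-regular components with counts we control.
        for k in range(1, 8):
            count = max(1, round(120 * k ** -2))
            n_cliques = max(1, count // (k + 1))
            for _ in range(n_cliques):
                nodes = list(range(node, node + k + 1))
                net.add_edges_from(
                    (a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:])
                node += k + 1
        fit = degree_powerlaw_fit(net)
        assert fit.correlation < -0.9
        assert fit.r_squared > 0.8
        assert fit.exponent > 0

    def test_uniform_degrees_fit_undefined(self):
        with pytest.raises(UndefinedResultError):
            degree_powerlaw_fit(nx.cycle_graph(10))

    def test_preferential_attachment_graph_fits_well(self):
        net = nx.barabasi_albert_graph(400, 2, seed=11)
        fit = degree_powerlaw_fit(net)
        assert fit.r_squared > 0.6
        assert fit.correlation < 0
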