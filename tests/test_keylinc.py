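"""Hub selection, key-lincRNA reports, sample clustering, built-in DE."""
import numpy as np
import pandas as pd
import pytest

from lincnet import (ExpressionMatrix, SampleMeta, SimConfig, cluster_samples,
                     compare_key_sets, hub_threshold, select_key_lincrnas,
                     simple_de, simple_de_all_timepoints,
                     simulate_expression, simulate_target_map)
from lincnet.errors import ConfigError, DomainError, UndefinedResultError
from lincnet.io import load_reference_key_lincrnas
import networkx as nx


class TestHubThreshold:
    def test_distinct_degree_staircase(self):
        # degrees 1..10 have odd sum, so pad with one extra mid-degree node:
        # top-20% of 11 nodes is 2 nodes (degrees 10 and 9), threshold 8
        seq = [10, 9, 8, 7, 6, 5, 5, 4, 3, 2, 1]
        g = nx.havel_hakimi_graph(seq)
        degrees = dict(g.degree())
        assert sorted(degrees.values(), reverse=True) == seq
        threshold, hubs = hub_threshold(g, 0.2)
        assert threshold == 8
        assert {degrees[v] for v in hubs} == {9, 10}

    def test_all_tied_degrees_everyone_is_hub(self):
        g = nx.cycle_graph(8)  # all degree 2
        threshold, hubs = hub_threshold(g, 0.2)
        assert hubs == frozenset(g.nodes)
        assert threshold == 1

    def test_single_node_network(self):
        g = nx.Graph()
        g.add_node("only")
        threshold, hubs = hub_threshold(g, 0.2)
        assert hubs == frozenset({"only"})

    def test_hub_floor_and_separation(self):
        g = nx.barabasi_albert_graph(100, 2, seed=1)
        threshold, hubs = hub_threshold(g, 0.2)
        degrees = dict(g.degree())
        assert len(hubs) >= int(0.2 * 100)
        assert min(degrees[v] for v in hubs) > \
            max(degrees[v] for v in g if v not in hubs)

    def test_empty_network_errors(self):
        with pytest.raises(DomainError):
            hub_threshold(nx.Graph())


def de_table(rows):
    return pd.DataFrame(rows, columns=["rna_id", "timepoint", "fdr"])


class TestSelectKeyLincrnas:
    def _net(self):
        g = nx.Graph()
        edges = [("lincA", f"g{i}") for i in range(5)]
        edges += [("lincB", f"g{i}") for i in range(4)]
        edges += [("g0", "g1"), ("g2", "g3")]
        g.add_edges_from(edges)
        for n in g.nodes:
            g.nodes[n]["rna_type"] = "lincRNA" if n.startswith("linc") else "gene"
        return g

    def test_de_hub_lincrna_included_and_sorted(self):
        net = self._net()
        de = de_table([("lincA", "t1", 0.04), ("lincB", "t1", 0.2),
                       ("lincB", "t2", 0.01)])
        report = select_key_lincrnas(net, {"lincA", "lincB"}, de)
        assert [e[0] for e in report.entries] == ["lincA", "lincB"]
        assert report.entries[0][1] == 5

    def test_non_de_hub_excluded(self):
        net = self._net()
        de = de_table([("lincA", "t1", 0.06), ("lincB", "t1", 0.5)])
        report = select_key_lincrnas(net, {"lincA", "lincB"}, de)
        assert report.entries == ()

    def test_de_non_hub_excluded(self):
        net = self._net()
        de = de_table([("lincA", "t1", 0.001)])
        report = select_key_lincrnas(net, {"lincB"}, de)
        assert "lincA" not in report.lincrna_ids


class TestCompareKeySets:
    def test_reference_root_shoot_overlap(self):
        root = load_reference_key_lincrnas("root")
        shoot = load_reference_key_lincrnas("shoot")
        common, only_root, only_shoot = compare_key_sets(
            root["lincrna_id"], shoot["lincrna_id"])
        assert len(root) == 47 and len(shoot) == 40
        assert len(common) == 11

    def test_identical_and_disjoint(self):
        c, a, b = compare_key_sets(["x", "y"], ["x", "y"])
        assert c == {"x", "y"} and not a and not b
        c, a, b = compare_key_sets(["x"], ["y"])
        assert not c and a == {"x"} and b == {"y"}

    def test_symmetry_of_common_component(self):
        c1, _, _ = compare_key_sets(["x", "y", "z"], ["y", "q"])
        c2, _, _ = compare_key_sets(["y", "q"], ["x", "y", "z"])
        assert c1 == c2


def _expr_from_matrix(values: np.ndarray, rna_ids, samples) -> ExpressionMatrix:
    df = pd.DataFrame(values, index=rna_ids,
                      columns=[s.sample_id for s in samples])
    types = pd.Series({r: "lincRNA" for r in rna_ids})
    return ExpressionMatrix(df, types, samples)


class TestClusterSamples:
    def _samples(self, n, timepoints=None):
        return [SampleMeta(f"s{i}", "root", "starved",
                           (timepoints[i] if timepoints else f"t{i}"),
                           i + 1.0, 1) for i in range(n)]

    def test_duplicated_blocks_recover_partition(self):
        rng = np.random.default_rng(0)
        profile_a = rng.uniform(1, 50, size=6)
        profile_b = rng.uniform(1, 50, size=6)
        cols = [profile_a] * 3 + [profile_b] * 3
        samples = self._samples(6)
        expr = _expr_from_matrix(np.column_stack(cols), [f"f{i}" for i in range(6)],
                                 samples)
        out = cluster_samples(expr, [f"f{i}" for i in range(6)])
        labels = [out.two_groups[s.sample_id] for s in samples]
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert labels[0] != labels[3]

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(1, 20, size=(8, 10))
        samples = self._samples(10)
        expr = _expr_from_matrix(X, [f"f{i}" for i in range(8)], samples)
        out1 = cluster_samples(expr, [f"f{i}" for i in range(8)])
        perm = list(reversed(range(10)))
        expr2 = _expr_from_matrix(X[:, perm], [f"f{i}" for i in range(8)],
                                  [samples[j] for j in perm])
        out2 = cluster_samples(expr2, [f"f{i}" for i in range(8)])
        part1 = {sid: g for sid, g in out1.two_groups.items()}
        part2 = {sid: g for sid, g in out2.two_groups.items()}
        same = all(
            (part1[a] == part1[b]) == (part2[a] == part2[b])
            for a in part1 for b in part1)
        assert same

    def test_zero_variance_features_degenerate(self):
        samples = self._samples(4)
        expr = _expr_from_matrix(np.ones((3, 4)), ["f0", "f1", "f2"], samples)
        with pytest.raises(UndefinedResultError):
            cluster_samples(expr, ["f0", "f1", "f2"])

    def test_newick_export_contains_all_samples(self):
        rng = np.random.default_rng(2)
        samples = self._samples(5)
        expr = _expr_from_matrix(rng.uniform(1, 9, (4, 5)),
                                 [f"f{i}" for i in range(4)], samples)
        nwk = cluster_samples(expr, [f"f{i}" for i in range(4)]).newick()
        assert nwk.endswith(";")
        for s in samples:
            assert s.sample_id in nwk


class TestSimpleDe:
    def _expr(self, a_reps, b_reps, n_rna=4, delta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        samples, cols = [], []
        for cond, reps in (("control", a_reps), ("starved", b_reps)):
            for r in range(1, reps + 1):
                samples.append(SampleMeta(f"{cond}_r{r}", "root", cond, "t1",
                                          1.0, r))
                shift = delta if cond == "starved" else 0.0
                cols.append(2 ** (5 + shift + rng.normal(scale=0.2, size=n_rna)))
        return _expr_from_matrix(np.column_stack(cols),
                                 [f"r{i}" for i in range(n_rna)], samples)

    def test_identical_values_not_significant(self):
        samples = [SampleMeta(f"{c}_r{r}", "root", c, "t1", 1.0, r)
                   for c in ("control", "starved") for r in (1, 2, 3)]
        expr = _expr_from_matrix(np.full((3, 6), 7.0), ["a", "b", "c"], samples)
        out = simple_de(expr, "t1")
        assert (out["fdr"] == 1.0).all()

    def test_type_one_error_controlled_at_nominal_level(self):
        # null data over 60 seeds: the BH-flagged fraction stays near or
        # below the nominal 5% level
        flagged = total = 0
        for seed in range(60):
            expr = self._expr(3, 3, n_rna=20, delta=0.0, seed=seed)
            out = simple_de(expr, "t1")
            flagged += int((out["fdr"] < 0.05).sum())
            total += len(out)
        assert flagged / total < 0.05 + 0.02

    def test_strong_shift_recovered(self):
        expr = self._expr(3, 3, n_rna=10, delta=3.0, seed=5)
        out = simple_de(expr, "t1")
        assert (out["fdr"] < 0.05).all()

    def test_too_few_replicates_errors(self):
        expr = self._expr(1, 3)
        with pytest.raises(ConfigError):
            simple_de(expr, "t1")


class TestSyntheticDeRecovery:
    def test_null_generator_flags_near_nominal_fraction(self):
        # de_effect = 0: flagged fraction of lincRNAs across 50 seeds stays
        # at or below the nominal FDR level
        flagged = total = 0
        for seed in range(50):
            cfg = SimConfig(seed=seed, de_effect=0.0, n_genes=30, n_lincrnas=12,
                            n_modules=2, module_size=5, lincrnas_per_module=2,
                            responsive_extra_genes=0, n_mirnas=20)
            _, truth = simulate_target_map(cfg)
            expr = simulate_expression(cfg, truth)
            lincs = expr.lincrna_ids()
            sub = ExpressionMatrix(expr.values.loc[lincs],
                                   expr.rna_types[lincs], expr.samples)
            de = simple_de_all_timepoints(sub)
            flagged += int((de.groupby("rna_id")["fdr"].min() < 0.05).sum())
            total += len(lincs)
        assert flagged / total <= 0.05 + 0.03

    def test_planted_responsive_lincrnas_recovered(self):
        # de_effect = 2: >= 90% of planted responsive lincRNAs flagged at
        # some time point, pooled over 20 seeds
        hits = total = 0
        for seed in range(20):
            cfg = SimConfig(seed=seed)
            _, truth = simulate_target_map(cfg)
            expr = simulate_expression(cfg, truth)
            lincs = expr.lincrna_ids()
            sub = ExpressionMatrix(expr.values.loc[lincs],
                                   expr.rna_types[lincs], expr.samples)
            de = simple_de_all_timepoints(sub)
            de_set = set(de[de["fdr"] < 0.05]["rna_id"])
            hits += len(truth.de_lincrnas & de_set)
            total += len(truth.de_lincrnas)
        assert hits / total >= 0.9
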