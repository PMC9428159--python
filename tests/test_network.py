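"""Co-occurrence network construction, validation, topology and keystones."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from denitnet.design import StudyDesign
from denitnet.io import OtuTable
from denitnet.network import (CooccurrenceNetwork, build_graph,
                              correlation_edges, degree_centralization,
                              detect_modules, identify_keystones,
                              prevalence_filter, topology, validate_edges)


def _table(counts, gene="nirS", samples=None):
    counts = np.asarray(counts, dtype=float)
    ids = [f"o{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return OtuTable(pd.DataFrame(counts, index=ids, columns=samples),
                    pd.Series(["g"] * len(ids), index=ids), gene)


class TestPrevalenceFilter:
    def _design_table(self):
        design = StudyDesign(treatments=("A", "B"), replicates=2)
        counts = np.array([
            [5, 5, 5, 5],    # everywhere
            [5, 0, 5, 5],    # missing one replicate of A
            [0, 0, 5, 5],    # only treatment B complete
            [0, 0, 0, 0],    # absent
        ], dtype=float)
        return design, _table(counts, samples=design.sample_ids())

    def test_strict_requires_all_samples(self):
        design, t = self._design_table()
        kept = prevalence_filter(t, design, mode="strict")
        assert kept.otu_ids == ["o0"]

    def test_any_treatment_keeps_complete_treatment(self):
        # o1 misses one replicate of A but is complete in B -> retained
        design, t = self._design_table()
        kept = prevalence_filter(t, design, mode="any-treatment")
        assert kept.otu_ids == ["o0", "o1", "o2"]

    def test_all_zero_removed_in_both_modes(self):
        design, t = self._design_table()
        for mode in ("strict", "any-treatment"):
            assert "o3" not in prevalence_filter(t, design, mode=mode).otu_ids

    def test_empty_result_warns_not_crashes(self):
        design = StudyDesign(treatments=("A",), replicates=2)
        t = _table(np.array([[1.0, 0.0]]), samples=design.sample_ids())
        with pytest.warns(UserWarning):
            kept = prevalence_filter(t, design)
        assert kept.shape[0] == 0


class TestCorrelationEdges:
    def test_duplicated_profiles_make_candidate(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 100, size=8).astype(float)
        counts = np.vstack([base, base * 3, rng.integers(1, 100, size=8)])
        cand = correlation_edges(_table(counts), relative=False)
        pairs = set(map(tuple, cand[["otu_a", "otu_b"]].to_numpy()))
        assert ("o0", "o1") in pairs
        r01 = cand.set_index(["otu_a", "otu_b"]).loc[("o0", "o1"), "r"]
        assert r01 == pytest.approx(1.0)

    def test_matches_bruteforce_all_pairs(self):
        """Candidate set equals exhaustive pairwise pearsonr evaluation."""
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 500, size=(5, 10)).astype(float)
        t = _table(counts)
        cand = correlation_edges(t)
        rel = t.relative_abundance().to_numpy()
        expected = set()
        for i, j in itertools.combinations(range(5), 2):
            r, p = pearsonr(rel[i], rel[j])
            if abs(r) > 0.7 and p < 0.05:
                expected.add((f"o{i}", f"o{j}"))
        got = set(map(tuple, cand[["otu_a", "otu_b"]].to_numpy()))
        assert got == expected

    def test_zero_variance_pair_skipped(self):
        counts = np.vstack([np.full(8, 5.0), np.arange(1.0, 9.0)])
        with pytest.warns(UserWarning):
            cand = correlation_edges(_table(counts), relative=False)
        assert len(cand) == 0

    def test_needs_four_samples(self):
        with pytest.raises(ValueError):
            correlation_edges(_table(np.ones((3, 3))))


class TestValidateEdges:
    def _candidate_table(self, n=15, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(10, 100, size=n)
        counts = np.vstack([base, base * 2.0, rng.uniform(10, 100, size=n)])
        t = _table(counts)
        return t, correlation_edges(t, relative=False)

    def test_collinear_pair_min_permutation_p(self):
        t, cand = self._candidate_table()
        out = validate_edges(cand, t, n_iter=1000, relative=False, seed=1)
        row = out.set_index(["otu_a", "otu_b"]).loc[("o0", "o1")]
        assert row["p_perm"] == pytest.approx(1.0 / 1001.0)
        assert bool(row["validated"])

    def test_deterministic_given_seed(self):
        t, cand = self._candidate_table()
        a = validate_edges(cand, t, n_iter=200, relative=False, seed=7)
        b = validate_edges(cand, t, n_iter=200, relative=False, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_validated_subset_of_candidates_and_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        counts = rng.uniform(1, 100, size=(8, 12))
        counts[1] = counts[0] * (1 + rng.normal(0, 0.05, 12))
        counts[3] = counts[2] * (1 + rng.normal(0, 0.1, 12))
        t = _table(counts)
        lo = correlation_edges(t, r_threshold=0.6, relative=False)
        hi = correlation_edges(t, r_threshold=0.8, relative=False)
        lo_pairs = set(map(tuple, lo[["otu_a", "otu_b"]].to_numpy()))
        hi_pairs = set(map(tuple, hi[["otu_a", "otu_b"]].to_numpy()))
        assert hi_pairs <= lo_pairs
        val = validate_edges(lo, t, n_iter=200, r_threshold=0.6, relative=False, seed=0)
        val_pairs = set(map(tuple, val.loc[val["validated"], ["otu_a", "otu_b"]].to_numpy()))
        assert val_pairs <= lo_pairs

    def test_low_iteration_warning(self):
        t, cand = self._candidate_table()
        with pytest.warns(UserWarning):
            validate_edges(cand, t, n_iter=50, relative=False, seed=0)


class TestTopology:
    def test_triangle(self):
        topo = topology(nx.complete_graph(3))
        assert topo["average_degree"] == pytest.approx(2.0)
        assert topo["average_clustering"] == pytest.approx(1.0)
        assert topo["average_path_length"] == pytest.approx(1.0)

    def test_path_three_nodes(self):
        topo = topology(nx.path_graph(3))
        assert topo["average_degree"] == pytest.approx(4 / 3)
        assert topo["average_clustering"] == 0.0
        assert topo["average_path_length"] == pytest.approx(4 / 3)

    def test_star_centralization_maximal(self):
        assert degree_centralization(nx.star_graph(4)) == pytest.approx(1.0)

    def test_empty_graph_metrics_missing(self):
        topo = topology(nx.Graph())
        assert topo["n_nodes"] == 0 and topo["average_degree"] is None

    def test_invariant_under_relabeling(self):
        g = nx.erdos_renyi_graph(12, 0.3, seed=4)
        h = nx.relabel_nodes(g, {n: f"x{n}" for n in g.nodes})
        t1, t2 = topology(g), topology(h)
        for key in ("average_degree", "average_clustering", "average_path_length",
                    "degree_centralization"):
            assert t1[key] == pytest.approx(t2[key])


def _all_partitions(nodes):
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in _all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1:]
        yield part + [{first}]


class TestDetectModules:
    def test_two_disjoint_cliques_exact_split(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        labels, q = detect_modules(g, seed=0)
        assert q == pytest.approx(0.5)
        assert labels.nunique() == 2
        assert labels[[0, 1, 2, 3]].nunique() == 1
        assert labels[[4, 5, 6, 7]].nunique() == 1

    def test_single_clique_one_module(self):
        labels, q = detect_modules(nx.complete_graph(5), seed=0)
        assert labels.nunique() == 1 and labels.unique()[0] == "I"

    @pytest.mark.parametrize("maker", [
        lambda: nx.path_graph(6),
        lambda: nx.cycle_graph(8),
        lambda: nx.barbell_graph(4, 0),
        lambda: nx.star_graph(5),
        lambda: nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4)]),
    ])
    def test_matches_exhaustive_maximum_on_small_graphs(self, maker):
        g = maker()
        _, q = detect_modules(g, seed=0)
        best = max(nx.community.modularity(g, part) for part in _all_partitions(g.nodes))
        assert q == pytest.approx(best, abs=1e-12)

    def test_q_nonnegative_with_internal_edges(self):
        g = nx.erdos_renyi_graph(20, 0.15, seed=2)
        g.remove_nodes_from(list(nx.isolates(g)))
        _, q = detect_modules(g, seed=0)
        assert q >= 0.0

    def test_labels_ordered_by_internal_edges(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(5))
        labels, _ = detect_modules(g, seed=0)
        # 5-clique (10 internal edges) must be module I
        assert labels[[3, 4, 5, 6, 7]].unique()[0] == "I"
        assert labels[[0, 1, 2]].unique()[0] == "II"


class TestKeystones:
    def test_star_center_is_keystone(self):
        with pytest.warns(UserWarning, match="fewer than 10"):
            rep = identify_keystones(nx.star_graph(4))   # K_{1,4}
        assert rep.keystones == [0]

    def test_small_graph_warns_degenerate_thresholds(self):
        with pytest.warns(UserWarning, match="fewer than 10"):
            identify_keystones(nx.star_graph(5))

    def test_regular_graph_all_pass_degree_screen(self):
        g = nx.cycle_graph(12)
        rep = identify_keystones(g)
        assert set(rep.keystones) == set(g.nodes)   # all tie at the cutoff

    def test_empty_graph(self):
        rep = identify_keystones(nx.Graph())
        assert rep.keystones == []


class TestCooccurrenceNetworkEstimator:
    def test_sklearn_params_roundtrip(self):
        est = CooccurrenceNetwork(n_iter=123)
        assert est.get_params()["n_iter"] == 123
        est.set_params(r_threshold=0.8)
        assert est.r_threshold == 0.8

    def test_fit_populates_attributes(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(10, 100, size=12)
        counts = np.vstack([base * (1 + rng.normal(0, 0.03, 12)) for _ in range(4)]
                           + [rng.uniform(10, 100, size=12) for _ in range(3)])
        t = _table(counts)
        est = CooccurrenceNetwork(prevalence=None, n_iter=200, seed=0).fit(t)
        assert est.topology_["n_nodes"] == est.graph_.number_of_nodes()
        assert set(est.modules_.index) == set(est.graph_.nodes)
        assert est.edges_["validated"].all() or (~est.edges_["validated"]).any()
        deg = est.topology_["average_degree"]
        assert deg == pytest.approx(2 * est.topology_["n_edges"]
                                    / max(est.topology_["n_nodes"], 1))
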