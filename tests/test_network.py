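"""Network construction, RMT thresholding, topology and keystones."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from edaphonet.datatypes import OtuTable, ValidationError
from edaphonet.network import (
    CorrelationResult,
    KeystoneThresholds,
    RmtSelectionError,
    bh_fdr,
    build_network,
    filter_otus,
    global_topology,
    identify_keystones,
    rmt_select_threshold,
    sample_subgraph_topology,
    spearman_matrix,
)
from edaphonet.simulate import (
    SimulationConfig,
    block_correlation_matrix,
    generate_otu_table,
)

from _oracles import (
    bf_assortativity,
    bf_betweenness,
    bf_bh,
    bf_harmonic_closeness,
    bf_local_clustering,
    bf_transitivity,
)
from conftest import random_graph


def _table(counts, otus=None):
    counts = np.asarray(counts)
    return OtuTable(pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(counts.shape[0])],
        columns=otus or [f"o{j}" for j in range(counts.shape[1])],
    ))


class TestFilterOtus:
    def test_mean_relative_abundance_rule(self):
        # o1 at 2e-4 mean kept; o2 at exactly 1e-4 removed (strict >)
        depth = 10_000
        counts = np.zeros((2, 3), dtype=int)
        counts[:, 0] = depth - 3
        counts[:, 1] = 2
        counts[:, 2] = 1
        t = _table(counts)
        kept = filter_otus(t, 1e-4)
        assert "o1" in kept.otu_ids  # mean rel abundance 2e-4
        assert "o2" not in kept.otu_ids  # exactly 1e-4
        assert "o0" in kept.otu_ids

    def test_zero_threshold_keeps_present_otus(self):
        t = _table([[5, 0, 1], [3, 0, 2]])
        kept = filter_otus(t, 0)
        assert kept.otu_ids == ["o0", "o2"]

    def test_no_survivors_is_an_error(self):
        t = _table([[1, 1], [1, 1]])
        with pytest.raises(ValidationError):
            filter_otus(t, 0.9)


class TestSpearman:
    def test_monotone_pairs(self):
        t = _table(np.array([[1, 2, 9], [2, 4, 7], [3, 6, 5], [4, 8, 3]]))
        res = spearman_matrix(t)
        assert res.rho.loc["o0", "o1"] == pytest.approx(1.0)
        assert res.rho.loc["o0", "o2"] == pytest.approx(-1.0)

    def test_rank_difference_formula(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        t = _table(np.column_stack([x, y]))
        res = spearman_matrix(t)
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 = 4
        assert res.rho.loc["o0", "o1"] == pytest.approx(0.8, abs=1e-12)

    def test_matches_scipy_matrix(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(0)
        t = _table(rng.integers(0, 50, size=(10, 6)))
        res = spearman_matrix(t)
        rho_ref, p_ref = spearmanr(t.counts.to_numpy())
        assert np.allclose(res.rho.to_numpy(), rho_ref, atol=1e-10)
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(res.p.to_numpy()[off], p_ref[off], atol=1e-8)

    def test_constant_otu_recorded_missing(self):
        t = _table([[1, 5], [1, 6], [1, 7], [1, 8]])
        res = spearman_matrix(t)
        assert math.isnan(res.rho.loc["o0", "o1"])
        assert math.isnan(res.q.loc["o0", "o1"])

    def test_needs_four_samples(self):
        with pytest.raises(ValidationError):
            spearman_matrix(_table([[1, 2], [3, 4], [5, 6]]))


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_stepup_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            p = rng.uniform(size=rng.integers(1, 40)).round(3)
            assert np.allclose(bh_fdr(p), bf_bh(list(p)), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestRmtSelection:
    def test_identity_matrix_degenerate(self):
        with pytest.raises(RmtSelectionError):
            rmt_select_threshold(np.eye(30))

    def test_too_few_otus_rejected(self):
        with pytest.raises(ValidationError):
            rmt_select_threshold(np.eye(10))

    def test_deterministic_given_input(self):
        a = block_correlation_matrix(seed=3)
        s1 = rmt_select_threshold(a).selected
        s2 = rmt_select_threshold(a).selected
        assert s1 == s2

    def test_known_separation_recovered(self):
        # blocks near 0.9, noise bounded by 0.4: the cutoff must fall in
        # the gap between noise support and signal
        a = block_correlation_matrix(seed=0)
        scan = rmt_select_threshold(a)
        assert 0.40 < scan.selected <= 0.90
        assert scan.selected in scan.thresholds


def _corr_from_matrix(rho, q=None, otus=None):
    m = rho.shape[0]
    otus = otus or [f"o{j}" for j in range(m)]
    rho_df = pd.DataFrame(rho, index=otus, columns=otus)
    p = np.where(np.eye(m, dtype=bool), 0.0, 1e-6)
    q_df = pd.DataFrame(q if q is not None else p, index=otus, columns=otus)
    return CorrelationResult(rho=rho_df, p=pd.DataFrame(p, index=otus, columns=otus),
                             q=q_df)


class TestBuildNetwork:
    def test_empty_when_nothing_passes(self):
        corr = _corr_from_matrix(np.eye(3))
        g = build_network(corr, 0.5)
        assert g.number_of_nodes() == 0

    def test_triangle(self):
        rho = np.full((3, 3), 0.95)
        np.fill_diagonal(rho, 1.0)
        g = build_network(_corr_from_matrix(rho), 0.9)
        assert g.number_of_edges() == 3

    def test_both_conditions_required(self):
        rho = np.array([[1.0, 0.9], [0.9, 1.0]])
        q = np.array([[0.0, 0.2], [0.2, 0.0]])
        g = build_network(_corr_from_matrix(rho, q=q), 0.8, fdr_alpha=0.05)
        assert g.number_of_edges() == 0  # high rho but q above alpha

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        m = 15
        rho = rng.uniform(-1, 1, size=(m, m))
        rho = (rho + rho.T) / 2
        np.fill_diagonal(rho, 1.0)
        corr = _corr_from_matrix(rho)
        edges = [build_network(corr, t).number_of_edges()
                 for t in [0.1, 0.3, 0.5, 0.7, 0.9]]
        assert edges == sorted(edges, reverse=True)

    def test_negative_correlations_admitted_by_default(self):
        rho = np.array([[1.0, -0.95], [-0.95, 1.0]])
        g = build_network(_corr_from_matrix(rho), 0.9)
        assert g.number_of_edges() == 1
        g2 = build_network(_corr_from_matrix(rho), 0.9, positive_only=True)
        assert g2.number_of_edges() == 0


class TestGlobalTopology:
    def test_triangle_closed_forms(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        topo = global_topology(g)
        assert topo.node_number == 3
        assert topo.edge_number == 3
        assert topo.transitivity == pytest.approx(1.0)
        assert topo.betweenness == pytest.approx(0.0)

    def test_star_assortativity_minus_one(self):
        g = nx.star_graph(4)
        topo = global_topology(g)
        assert topo.assortativity == pytest.approx(-1.0)

    def test_path_middle_betweenness(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        report = identify_keystones(g)
        assert report.loc["b", "betweenness_centrality"] == pytest.approx(1.0)

    def test_empty_graph(self):
        topo = global_topology(nx.Graph())
        assert topo.node_number == 0 and topo.edge_number == 0

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            nodes, edges = random_graph(rng)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            topo = global_topology(g)
            bc = bf_betweenness(nodes, edges)
            assert topo.betweenness == pytest.approx(
                float(np.mean(list(bc.values()))), abs=1e-9
            )
            assert topo.transitivity == pytest.approx(
                bf_transitivity(nodes, edges), abs=1e-9
            )
            ref_assort = bf_assortativity(nodes, edges)
            if math.isnan(ref_assort):
                assert math.isnan(topo.assortativity)
            else:
                assert topo.assortativity == pytest.approx(ref_assort, abs=1e-9)


class TestSampleSubgraphs:
    @staticmethod
    def _net_and_table():
        g = nx.Graph()
        for u, v in [("o0", "o1"), ("o1", "o2"), ("o0", "o2"), ("o2", "o3")]:
            g.add_edge(u, v, rho=0.9, q=0.001, weight=0.9)
        counts = np.array([
            [5, 5, 5, 5],  # all nodes
            [0, 0, 0, 0],  # none
            [5, 5, 5, 0],  # triangle only
        ])
        return g, _table(counts, otus=["o0", "o1", "o2", "o3"])

    def test_full_sample_equals_global(self):
        g, t = self._net_and_table()
        per = sample_subgraph_topology(g, t)
        topo = global_topology(g)
        assert per.loc["s0", "node_number"] == topo.node_number
        assert per.loc["s0", "edge_number"] == topo.edge_number
        assert per.loc["s0", "betweenness"] == pytest.approx(topo.betweenness)

    def test_absent_sample_missing(self):
        g, t = self._net_and_table()
        per = sample_subgraph_topology(g, t)
        assert math.isnan(per.loc["s1", "node_number"])

    def test_induced_triangle_edge_count(self):
        g, t = self._net_and_table()
        per = sample_subgraph_topology(g, t)
        assert per.loc["s2", "edge_number"] == 3

    def test_matches_induced_subgraph_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            nodes, edges = random_graph(rng)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            presence = rng.integers(0, 2, size=(3, len(nodes)))
            t = _table(presence * 5, otus=list(nodes))
            per = sample_subgraph_topology(g, t)
            for si in range(3):
                present = [n for n, c in zip(nodes, presence[si]) if c]
                sub_edges = [e for e in edges
                             if e[0] in present and e[1] in present]
                if not present:
                    assert math.isnan(per.iloc[si]["node_number"])
                    continue
                assert per.iloc[si]["node_number"] == len(present)
                assert per.iloc[si]["edge_number"] == len(sub_edges)


class TestKeystones:
    def test_complete_graph_k8_all_keystone(self):
        g = nx.complete_graph(8)
        nx.set_edge_attributes(g, 1.0, "rho")
        report = identify_keystones(g)
        # degree 7 > 6, weighted degree 7 > 6, closeness 1 > 0.14,
        # betweenness 0 < 0.05, clustering 1 > 0.09
        assert report["keystone"].all()

    def test_degree_exactly_six_excluded(self):
        g = nx.complete_graph(7)  # degree 6 everywhere
        nx.set_edge_attributes(g, 1.0, "rho")
        report = identify_keystones(g)
        assert not report["keystone"].any()

    def test_empty_network_empty_report(self):
        report = identify_keystones(nx.Graph())
        assert len(report) == 0

    def test_flag_equals_direct_condition_evaluation(self):
        rng = np.random.default_rng(6)
        t = KeystoneThresholds()
        for _ in range(20):
            nodes, edges = random_graph(rng)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for u, v in edges:
                g.add_edge(u, v, rho=float(rng.uniform(-1, 1)))
            report = identify_keystones(g)
            for _, row in report.iterrows():
                expected = (
                    row["degree"] > t.degree_min
                    and row["weighted_degree"] > t.weighted_degree_min
                    and row["closeness"] > t.closeness_min
                    and row["betweenness_centrality"] < t.betweenness_max
                    and row["transitivity"] > t.transitivity_min
                )
                assert row["keystone"] == expected

    def test_centralities_match_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            nodes, edges = random_graph(rng)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for u, v in edges:
                g.add_edge(u, v, rho=0.5)
            report = identify_keystones(g)
            close = bf_harmonic_closeness(nodes, edges)
            clust = bf_local_clustering(nodes, edges)
            betw = bf_betweenness(nodes, edges)
            for n in nodes:
                assert report.loc[n, "closeness"] == pytest.approx(close[n], abs=1e-9)
                assert report.loc[n, "transitivity"] == pytest.approx(clust[n], abs=1e-9)
                assert report.loc[n, "betweenness_centrality"] == pytest.approx(
                    betw[n], abs=1e-9
                )


def test_block_structure_visible_in_spearman(small_bundle):
    """Within-guild |rho| exceeds between-guild |rho| by construction."""
    import itertools

    cfg = SimulationConfig(seed=21, n_otus=80, n_blocks=3, block_rho=0.95,
                           sequencing_depth=5000)
    table, truth = generate_otu_table(cfg)
    res = spearman_matrix(filter_otus(table))
    blocks = {k: [o for o in v if o in res.otu_ids]
              for k, v in truth["blocks"].items()}
    within, between = [], []
    for members in blocks.values():
        for a, b in itertools.combinations(members, 2):
            within.append(abs(res.rho.loc[a, b]))
    for k1, k2 in itertools.combinations(blocks, 2):
        for a in blocks[k1]:
            for b in blocks[k2]:
                between.append(abs(res.rho.loc[a, b]))
    assert np.nanmean(within) > np.nanmean(between)
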