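import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from haptonet import (
    ZotuTable,
    bh_adjust,
    build_network,
    classify_enrichment,
    detect_modules,
    filter_zotus,
    network_metrics,
    node_metrics,
    spearman_matrix,
    subnetwork,
)


def _table(counts, **kw):
    counts = np.asarray(counts)
    return ZotuTable(
        counts,
        kw.get("sample_ids", [f"s{i}" for i in range(counts.shape[0])]),
        kw.get("zotu_ids", [f"ZOTU_{j+1}" for j in range(counts.shape[1])]),
    )


class TestFilterZotus:
    @staticmethod
    def _toy():
        # grand total 100_000; prevalence over 8 samples
        counts = np.zeros((8, 5), dtype=int)
        counts[:, 0] = 12_490          # abundant, everywhere
        counts[0, 1] = 20              # 0.02% abundance, 12.5% prevalence -> keep
        counts[0, 2] = 5               # 0.005%, 12.5% -> delete
        counts[:3, 3] = [2, 2, 1]      # 0.005%, 37.5% -> keep (prevalent)
        counts[0, 4] = 3               # 0.003%, 12.5% -> delete
        counts[0, 0] += 100_000 - counts.sum()
        return _table(counts)

    def test_deletion_requires_both_conditions(self):
        out = filter_zotus(self._toy(), min_rel_abund=1e-4, min_prevalence=0.25)
        assert out.zotu_ids == ["ZOTU_1", "ZOTU_2", "ZOTU_4"]

    def test_all_deleted_raises(self):
        t = _table([[1, 1], [0, 0], [0, 0], [0, 0], [1, 1]])
        with pytest.raises(ValueError, match="min_rel_abund"):
            filter_zotus(t, min_rel_abund=1.0, min_prevalence=1.0)


class TestSpearmanMatrix:
    def test_diagonal_is_one_and_known_pair(self):
        base = np.array([[1, 2], [2, 1], [3, 4], [4, 3], [5, 5]])
        t = _table(np.column_stack([base, 7 - base[:, :1]]))
        rho, p = spearman_matrix(t)
        assert np.allclose(np.diag(rho), 1.0)
        # ranks (1..5) vs (2,1,4,3,5): rho = 1 - 6*4/120 = 0.8 on raw counts;
        # relative abundances share the total so ranks are preserved here
        sr = stats.spearmanr(t.relative_abundance()).statistic
        np.testing.assert_allclose(rho, sr, atol=1e-12)

    def test_zero_variance_pairs_flagged(self):
        # equal sample totals keep the middle taxon constant in relative
        # abundance, so its pairs are not-computed rather than rho = 0
        counts = np.array([
            [10, 10, 80],
            [20, 10, 70],
            [30, 10, 60],
            [40, 10, 50],
            [50, 10, 40],
        ])
        rho, p = spearman_matrix(_table(counts))
        assert np.isnan(rho[0, 1]) and np.isnan(p[1, 2])
        assert rho[0, 2] == pytest.approx(-1.0)

    def test_requires_five_samples(self):
        with pytest.raises(ValueError):
            spearman_matrix(_table([[1, 2], [3, 4]]))


class TestBhAdjust:
    def test_stepup_toy_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_capped(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_statsmodels_and_dominates_raw_p(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(5):
            p = rng.uniform(size=17)
            q = bh_adjust(p)
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_ref, atol=1e-12)
            assert (q >= p - 1e-15).all()
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-15).all()


class TestBuildNetwork:
    def test_no_significance_gives_empty_network(self):
        rho = np.full((3, 3), 0.9)
        q = np.ones((3, 3))
        G = build_network(rho, q, ["a", "b", "c"])
        assert G.number_of_edges() == 0

    def test_strong_triangle(self):
        rho = np.full((3, 3), 0.9)
        np.fill_diagonal(rho, 1.0)
        q = np.full((3, 3), 1e-6)
        G = build_network(rho, q, ["a", "b", "c"])
        assert G.number_of_edges() == 3
        assert G["a"]["b"]["sign"] == "+"

    def test_negative_edges_only_with_abs_policy(self):
        rho = np.array([[1.0, -0.9], [-0.9, 1.0]])
        q = np.full((2, 2), 1e-6)
        assert build_network(rho, q, ["a", "b"]).number_of_edges() == 0
        G = build_network(rho, q, ["a", "b"], use_abs=True)
        assert G.number_of_edges() == 1
        assert G["a"]["b"]["sign"] == "-"

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        m = 12
        rho = np.clip((lambda a: (a + a.T) / 2)(rng.uniform(-1, 1, (m, m))), -1, 1)
        np.fill_diagonal(rho, 1.0)
        q = (lambda a: (a + a.T) / 2)(rng.uniform(0, 1, (m, m)))
        ids = [f"z{i}" for i in range(m)]
        base = set(map(frozenset, build_network(rho, q, ids, 0.3, 0.2).edges))
        stricter_rho = set(map(frozenset, build_network(rho, q, ids, 0.5, 0.2).edges))
        stricter_alpha = set(map(frozenset, build_network(rho, q, ids, 0.3, 0.05).edges))
        assert stricter_rho <= base
        assert stricter_alpha <= base


class TestClassifyEnrichment:
    def test_surface_only_zotu_classified_surface(self):
        rng = np.random.default_rng(0)
        n = 20
        counts = rng.integers(50, 100, size=(n, 3))
        counts[10:, 0] = 0  # absent from SCM samples
        t = _table(counts)
        hab = pd.Series(["surface"] * 10 + ["SCM"] * 10,
                        index=[f"s{i}" for i in range(n)])
        out = classify_enrichment(t, hab)
        assert out.loc["ZOTU_1", "enrichment"] == "surface"

    def test_identical_zotu_classified_none(self):
        counts = np.tile([10, 20, 30], (12, 1))
        t = _table(counts)
        hab = pd.Series(["surface"] * 6 + ["SCM"] * 6,
                        index=[f"s{i}" for i in range(12)])
        out = classify_enrichment(t, hab)
        assert (out["enrichment"] == "none").all()


class TestDetectModules:
    def test_two_disjoint_cliques(self):
        G = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        G = nx.relabel_nodes(G, {i: f"n{i}" for i in G.nodes})
        labels, q = detect_modules(G, seed=0)
        first = {labels[f"n{i}"] for i in range(5)}
        second = {labels[f"n{i}"] for i in range(5, 10)}
        assert len(first) == 1 and len(second) == 1 and first != second
        assert -0.5 <= q <= 1

    def test_single_clique_single_module(self):
        G = nx.complete_graph(6)
        labels, _ = detect_modules(G, seed=0)
        assert len(set(labels.values())) == 1

    def test_seeded_reproducibility(self):
        G = nx.gnp_random_graph(30, 0.2, seed=5)
        l1, q1 = detect_modules(G, seed=3)
        l2, q2 = detect_modules(G, seed=3)
        assert l1 == l2 and q1 == q2

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            detect_modules(nx.Graph(), seed=0)


def _bruteforce_betweenness(G):
    """Normalized betweenness by exhaustive shortest-path enumeration."""
    nodes = list(G.nodes)
    n = len(nodes)
    bt = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        for node in nodes:
            if node in (s, t):
                continue
            frac = sum(node in p for p in paths) / len(paths)
            bt[node] += frac
    denom = (n - 1) * (n - 2) / 2
    return {v: b / denom for v, b in bt.items()}


class TestNodeMetrics:
    def test_star_hub(self):
        G = nx.star_graph(3)  # hub 0 + 3 leaves
        nm = node_metrics(G)
        assert nm.loc[0, "degree"] == 3
        assert nm.loc[0, "betweenness"] == pytest.approx(1.0)

    def test_complete_graph_zero_betweenness(self):
        nm = node_metrics(nx.complete_graph(4))
        assert np.allclose(nm["betweenness"], 0.0)

    def test_component_scaled_closeness(self):
        # triangle + separate dyad in one graph of N = 5
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4)])
        nm = node_metrics(G)
        # dyad: within-component closeness 1, scaled by (2-1)/(5-1)
        assert nm.loc[3, "closeness"] == pytest.approx(0.25)
        # triangle node: closeness 1 scaled by (3-1)/(5-1)
        assert nm.loc[0, "closeness"] == pytest.approx(0.5)

    def test_betweenness_matches_bruteforce_on_random_graphs(self):
        for seed in range(3):
            G = nx.gnp_random_graph(10, 0.35, seed=seed)
            nm = node_metrics(G)
            ref = _bruteforce_betweenness(G)
            for v in G.nodes:
                assert nm.loc[v, "betweenness"] == pytest.approx(ref[v], abs=1e-10)


class TestNetworkMetrics:
    def test_complete_graph(self):
        m = network_metrics(nx.complete_graph(4))
        assert m.density == pytest.approx(1.0)
        assert m.average_degree == pytest.approx(3.0)
        assert m.clustering_coefficient == pytest.approx(1.0)
        assert m.diameter == 1

    def test_path_graph(self):
        m = network_metrics(nx.path_graph(4))
        assert m.diameter == 3
        assert m.average_path_length == pytest.approx(5 / 3)

    def test_reachable_pairs_only(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4)])
        m = network_metrics(G)
        assert m.diameter == 1
        assert m.n_components == 2
        assert m.largest_component_size == 3


class TestSubnetwork:
    def test_full_subset_is_identity(self):
        G = nx.complete_graph(4)
        H = subnetwork(G, list(G.nodes))
        assert set(H.edges) == set(G.edges)

    def test_induced_k3_from_k4(self):
        H = subnetwork(nx.complete_graph(4), [0, 1, 2])
        assert H.number_of_nodes() == 3 and H.number_of_edges() == 3

    def test_disjoint_subset_rejected(self):
        with pytest.raises(ValueError):
            subnetwork(nx.complete_graph(3), [99])
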