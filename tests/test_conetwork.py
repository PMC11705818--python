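import numpy as np
import pandas as pd
import pytest

from mycoscan import AbundanceTable, simulate_abundance_study
from mycoscan.conetwork import (
    CoNetwork,
    build_network,
    correlation_matrix,
    nnsd_poisson_pvalue,
    prevalence_filter,
    remove_indirect_edges,
    rmt_threshold,
    threshold_network,
    topology,
)
from _synth import random_tpm_table


def table_with_prevalence(present_counts, n_samples=100):
    """One column per entry of present_counts, nonzero in that many samples."""
    data = {}
    for i, k in enumerate(present_counts):
        col = np.zeros(n_samples)
        col[:k] = 100.0
        data[f"t{i}"] = col
    df = pd.DataFrame(data, index=[f"s{j}" for j in range(n_samples)])
    return AbundanceTable(df)


class TestPrevalenceFilter:
    def test_strictly_more_than_cutoff(self):
        t = table_with_prevalence([5, 10, 11, 100])
        kept = prevalence_filter(t, min_prev=0.10).taxa
        assert kept == ["t2", "t3"]  # 5% and exactly 10% dropped

    def test_all_present_kept(self):
        t = table_with_prevalence([100, 100])
        assert prevalence_filter(t).taxa == ["t0", "t1"]


class TestCorrelationMatrix:
    def test_diagonal_one_and_monotone_invariance(self, rng):
        x = rng.lognormal(size=50)
        df = pd.DataFrame(
            {"a": x, "b": 2 * x, "c": rng.lognormal(size=50)},
            index=[f"s{i}" for i in range(50)],
        )
        r = correlation_matrix(AbundanceTable(df))
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_null_pairs_mostly_weak(self, rng):
        t = random_tpm_table(rng, n_samples=200, n_taxa=30)
        r = correlation_matrix(t).to_numpy()
        off = np.abs(r[np.triu_indices(30, 1)])
        assert (off < 0.2).mean() >= 0.9

    def test_zero_variance_taxon_warned_and_zeroed(self):
        df = pd.DataFrame(
            {"a": np.arange(20.0) + 1, "b": np.ones(20), "c": np.arange(20.0)[::-1] + 1},
            index=[f"s{i}" for i in range(20)],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            r = correlation_matrix(AbundanceTable(df))
        assert r.loc["a", "b"] == 0.0
        assert r.loc["b", "b"] == 1.0

    def test_too_few_samples_rejected(self, rng):
        t = random_tpm_table(rng, n_samples=5, n_taxa=10)
        with pytest.raises(ValueError):
            correlation_matrix(t)


class TestNnsdPoissonPvalue:
    def test_poisson_spectrum_accepted(self):
        rng = np.random.default_rng(1)
        m = np.diag(rng.uniform(0, 1, 120))
        assert nnsd_poisson_pvalue(m, 0.0) > 0.05

    def test_goe_spectrum_rejected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(120, 120))
        assert nnsd_poisson_pvalue((a + a.T) / np.sqrt(2), 0.0) < 0.05

    def test_equal_spacings_rejected(self):
        # arithmetic spectrum: all unfolded spacings identical, nothing
        # like the exponential law
        m = np.diag(np.linspace(0.0, 1.0, 60))
        assert nnsd_poisson_pvalue(m, 0.0) < 0.05

    def test_too_few_distinct_eigenvalues(self):
        with pytest.raises(ValueError, match="distinct eigenvalues"):
            nnsd_poisson_pvalue(np.eye(30), 0.0)


class TestRmtThreshold:
    def test_identity_like_matrix_returns_scan_floor(self):
        rng = np.random.default_rng(3)
        m = np.diag(rng.uniform(0.5, 1.5, 100))
        assert rmt_threshold(m) == pytest.approx(0.30)

    def test_all_ones_returns_t_max_with_warning(self):
        m = np.ones((40, 40))
        with pytest.warns(UserWarning, match="t_max"):
            assert rmt_threshold(m) == pytest.approx(0.99)


def star_network():
    nodes = {f"n{i}": "fungal" for i in range(5)}
    edges = [("n0", f"n{i}", 1.0) for i in range(1, 5)]
    return CoNetwork(nodes=nodes, edges=edges, threshold=0.5)


class TestTopology:
    def test_star_hand_computed(self):
        m = topology(star_network())
        assert (m.n_nodes, m.n_edges) == (5, 4)
        assert m.avg_neighbors == pytest.approx(1.6)
        assert m.density == pytest.approx(0.4)
        assert m.char_path_length == pytest.approx(1.6)  # 4 pairs at 1, 6 at 2
        assert m.heterogeneity == pytest.approx(0.75)
        assert m.centralization == pytest.approx(1.0)
        assert m.top_hubs[0] == ("n0", 4, "fungal")

    def test_complete_graph(self):
        nodes = {f"n{i}": "bacterial" for i in range(4)}
        edges = [
            (f"n{i}", f"n{j}", 0.9) for i in range(4) for j in range(i + 1, 4)
        ]
        m = topology(CoNetwork(nodes=nodes, edges=edges, threshold=0.5))
        assert m.density == pytest.approx(1.0)
        assert m.char_path_length == pytest.approx(1.0)
        assert m.heterogeneity == pytest.approx(0.0)
        assert m.centralization == pytest.approx(0.0)

    def test_disjoint_edges_connected_pairs_only(self):
        nodes = {c: "fungal" for c in "abcd"}
        net = CoNetwork(
            nodes=nodes, edges=[("a", "b", 1.0), ("c", "d", 1.0)], threshold=0.5
        )
        assert topology(net).char_path_length == pytest.approx(1.0)

    def test_degree_sum_is_twice_edges(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 15))
            nodes = {f"n{i}": "fungal" for i in range(n)}
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.3:
                        edges.append((f"n{i}", f"n{j}", 0.8))
            net = CoNetwork(nodes=nodes, edges=edges, threshold=0.5)
            assert sum(net.degree.values()) == 2 * len(edges)

    def test_matches_igraph_oracle_on_random_graphs(self, rng):
        """Independent graph-library cross-check of the topology panel."""
        import igraph

        for trial in range(50):
            n = int(rng.integers(5, 25))
            p = float(rng.uniform(0.1, 0.6))
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < p:
                        edges.append((f"n{i}", f"n{j}", 0.9))
            net = CoNetwork(
                nodes={f"n{i}": "fungal" for i in range(n)},
                edges=edges,
                threshold=0.5,
            )
            m = topology(net)
            g = igraph.Graph()
            g.add_vertices([f"n{i}" for i in range(n)])
            g.add_edges([(i, j) for i, j, _ in edges])
            assert m.n_nodes == g.vcount()
            assert m.n_edges == g.ecount()
            assert m.density == pytest.approx(
                g.density(loops=False) if n > 1 else 0.0, abs=1e-9
            )
            deg = np.array(g.degree(), dtype=float)
            if deg.mean() > 0:
                assert m.heterogeneity == pytest.approx(
                    deg.std() / deg.mean(), abs=1e-9
                )
            if m.n_edges >= 1:
                assert m.char_path_length == pytest.approx(
                    g.average_path_length(directed=False, unconn=True), abs=1e-9
                )


class TestRemoveIndirectEdges:
    def test_triangle_indirect_edge_pruned(self):
        # the 0.81 edge is the product of the two 0.9 paths; deconvolution
        # suppresses it below the network threshold while keeping directs
        net = CoNetwork(
            nodes={"a": "f", "b": "f", "c": "f"},
            edges=[("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", 0.81)],
            threshold=0.7,
        )
        out = remove_indirect_edges(net)
        assert [(i, j) for i, j, _ in out.edges] == [("a", "b"), ("b", "c")]

    def test_no_triangles_unchanged(self):
        net = CoNetwork(
            nodes={"a": "f", "b": "f", "c": "f", "d": "f"},
            edges=[("a", "b", 0.9), ("b", "c", 0.9), ("c", "d", 0.85)],
            threshold=0.5,
        )
        out = remove_indirect_edges(net)
        assert out.edges == net.edges

    def test_pathological_edge_removed(self):
        net = CoNetwork(
            nodes={"a": "f", "b": "f"},
            edges=[("a", "b", 0.9995)],
            threshold=0.5,
        )
        assert remove_indirect_edges(net).edges == []

    def test_output_subset_of_input(self, rng):
        for trial in range(5):
            n = 12
            nodes = {f"n{i}": "fungal" for i in range(n)}
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        edges.append((f"n{i}", f"n{j}", float(rng.uniform(0.5, 0.95))))
            net = CoNetwork(nodes=nodes, edges=edges, threshold=0.5)
            out = remove_indirect_edges(net)
            assert set((i, j) for i, j, _ in out.edges) <= set(
                (i, j) for i, j, _ in net.edges
            )

    def test_self_loops_rejected_by_container(self):
        with pytest.raises(ValueError, match="self-loop"):
            CoNetwork(nodes={"a": "f"}, edges=[("a", "a", 1.0)], threshold=0.5)


class TestThresholding:
    def test_raising_threshold_never_adds_edges(self, rng):
        t = random_tpm_table(rng, n_samples=30, n_taxa=25)
        corr = correlation_matrix(t)
        prev = None
        for thr in (0.1, 0.3, 0.5, 0.7):
            net = threshold_network(corr, thr)
            es = set((i, j) for i, j, _ in net.edges)
            if prev is not None:
                assert es <= prev
            prev = es

    def test_edge_weights_at_least_threshold(self, rng):
        t = random_tpm_table(rng, n_samples=30, n_taxa=25)
        net = threshold_network(correlation_matrix(t), 0.3)
        assert all(abs(w) >= 0.3 for _, _, w in net.edges)


class TestBuildNetwork:
    def test_empty_diff_taxa_rejected(self, rng):
        t = random_tpm_table(rng, n_samples=30, n_taxa=25)
        with pytest.raises(ValueError, match="empty"):
            build_network(t, [])

    def test_too_few_taxa_rejected(self, rng):
        t = random_tpm_table(rng, n_samples=30, n_taxa=25)
        with pytest.raises(ValueError, match="RMT"):
            build_network(t, t.taxa[:5])

    def test_planted_block_hubs(self):
        # community-scale pool: the spacing test needs the few dozen weak
        # null couplings of a ~200-taxon matrix to form a usable spectrum
        taxa = [(f"f{i}", "fungal") for i in range(15)] + [
            (f"b{i}", "bacterial") for i in range(185)
        ]
        block = [f"f{i}" for i in range(15)]
        names = [n for n, _ in taxa]
        table, _, _ = simulate_abundance_study(
            (60, 60), taxa, corr_blocks=[(block, 0.95)],
            base_mean={n: 1e-3 for n in names}, seed=7,
        )
        net = build_network(table, names, min_prev=0.0)
        assert net.metrics is not None
        hubs = [h for h, _, _ in net.metrics.top_hubs[:5]]
        assert sum(h in block for h in hubs) >= 3
        kingdoms = {h[2] for h in net.metrics.top_hubs}
        assert "fungal" in kingdoms
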