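"""Interactome cleaning, interconnectivity, resampling nulls, degree GSEA."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fibronet.network import (
    Interactome,
    clean_interactome,
    degree_enrichment,
    interconnectivity,
    mean_degree,
    null_distribution,
    read_edge_list,
    size_curve,
    z_score,
)
from tests.oracles import lcc_union_find


def interactome_from_edges(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return Interactome(g)


def rows(*triples):
    return pd.DataFrame(
        [{"symbol_a": a, "symbol_b": b, "interaction_type": t} for a, b, t in triples]
    )


class TestCleaning:
    def test_removal_rules(self):
        """Reverse duplicates collapse, self-loops go, genetic edges go."""
        raw = rows(("A", "B", "physical"), ("B", "A", "physical"),
                   ("A", "A", "physical"), ("A", "C", "genetic"))
        inter = clean_interactome(raw)
        assert set(inter.graph.edges) == {("A", "B")}

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            clean_interactome(pd.DataFrame(columns=["symbol_a", "symbol_b",
                                                    "interaction_type"]))
        with pytest.raises(ValueError):
            clean_interactome(rows(("A", "C", "genetic")))

    def test_organism_filter_drops_cross_species_pairs(self):
        raw = rows(("A", "B", "physical"), ("A", "C", "physical"))
        raw["organism_a"] = ["9606", "9606"]
        raw["organism_b"] = ["9606", "10090"]
        inter = clean_interactome(raw, organism="9606")
        assert set(inter.graph.edges) == {("A", "B")}

    def test_planted_duplicates_match_set_based_dedup(self):
        rng = np.random.default_rng(0)
        names = [f"N{i}" for i in range(200)]
        pairs = []
        while len(pairs) < 1000:
            a, b = rng.choice(200, 2, replace=False)
            pairs.append((names[a], names[b]))
        # plant ~10% duplicates, half of them reversed
        dupes = [pairs[i] if i % 2 else pairs[i][::-1]
                 for i in rng.choice(1000, 100, replace=False)]
        allrows = rows(*[(a, b, "physical") for a, b in pairs + dupes])
        inter = clean_interactome(allrows)
        assert inter.n_edges == len({frozenset(p) for p in pairs})

    def test_edge_list_round_trip(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("symbol_a\tsymbol_b\nA\tB\nB\tC\n")
        inter = read_edge_list(path)
        assert set(inter.graph.edges) == {("A", "B"), ("B", "C")}


class TestInterconnectivity:
    def test_triangle_is_fully_connected(self):
        inter = interactome_from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        res = interconnectivity(inter, ["A", "B", "C"])
        assert res.fraction == 100.0 and res.lcc_size == 3

    def test_absent_genes_dropped_and_reported(self):
        inter = interactome_from_edges([("A", "B")])
        res = interconnectivity(inter, ["A", "B", "ghost"])
        assert res.dropped == ("ghost",) and res.n_set_in_graph == 2
        with pytest.raises(ValueError):
            interconnectivity(inter, ["ghost"])

    def test_outside_neighbors_do_not_bridge_set_components(self):
        """Two set genes joined only through a non-set hub stay separate."""
        inter = interactome_from_edges([("A", "hub"), ("B", "hub")])
        res = interconnectivity(inter, ["A", "B"])
        assert res.lcc_size == 1 and res.fraction == 50.0

    def test_matches_union_find_oracle_on_random_graphs(self):
        """BFS-derived LCC equals an exhaustive union-find recount on 200
        seeded random graphs of up to 12 nodes, for random query sets."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            p = float(rng.uniform(0.05, 0.9))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            g.add_nodes_from(range(n))
            if g.number_of_edges() == 0:
                continue
            inter = Interactome(nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)}))
            k = int(rng.integers(1, n + 1))
            subset = [f"n{i}" for i in rng.choice(n, k, replace=False)]
            res = interconnectivity(inter, subset)
            expected = lcc_union_find(subset,
                                      [(u, v) for u, v in inter.graph.edges])
            assert res.lcc_size == expected
            assert res.fraction == pytest.approx(100.0 * expected / k)

    def test_invariant_under_relabeling_and_external_edges(self):
        edges = [("A", "B"), ("B", "C"), ("D", "E")]
        inter = interactome_from_edges(edges)
        base = interconnectivity(inter, ["A", "B", "D"])
        relabeled = interactome_from_edges([(u + "x", v + "x") for u, v in edges])
        assert interconnectivity(relabeled, ["Ax", "Bx", "Dx"]).fraction == base.fraction
        extra = interactome_from_edges(edges + [("D", "F"), ("F", "E")])
        assert interconnectivity(extra, ["A", "B", "D"]).fraction == base.fraction

    def test_adding_internal_edge_never_decreases_fraction(self):
        edges = [("A", "B"), ("C", "D"), ("E", "F")]
        inter = interactome_from_edges(edges)
        before = interconnectivity(inter, ["A", "B", "C"]).fraction
        after = interconnectivity(interactome_from_edges(edges + [("B", "C")]),
                                  ["A", "B", "C"]).fraction
        assert after >= before


class TestNullDistribution:
    def test_full_graph_sample_has_zero_sd(self):
        inter = interactome_from_edges([("A", "B"), ("B", "C"), ("D", "E")])
        whole = interconnectivity(inter, inter.nodes).fraction
        null = null_distribution(inter, inter.n_nodes, n_samples=10, seed=1)
        assert null.sd == 0.0
        assert np.all(null.fractions == whole)

    def test_oversized_sample_is_an_error(self):
        inter = interactome_from_edges([("A", "B")])
        with pytest.raises(ValueError):
            null_distribution(inter, 3, n_samples=5, seed=0)

    def test_z_from_printed_moments(self):
        assert round(z_score(56.31, 13.9, 7.9), 2) == 5.37
        with pytest.raises(ValueError):
            z_score(1.0, 0.0, 0.0)

    def test_fixed_seed_bit_identical(self):
        g = nx.gnp_random_graph(60, 0.08, seed=5)
        inter = Interactome(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
        a = null_distribution(inter, 15, n_samples=50, seed=123)
        b = null_distribution(inter, 15, n_samples=50, seed=123)
        assert np.array_equal(a.fractions, b.fractions)

    def test_erdos_renyi_giant_component_regimes(self):
        """Sampling the whole node set of a supercritical random graph gives
        null fractions near the giant-component size; far below the
        percolation threshold they stay small."""
        n = 2000
        dense = Interactome(nx.relabel_nodes(nx.gnp_random_graph(n, 3.0 / n, seed=8),
                                             {i: f"n{i}" for i in range(n)}))
        null = null_distribution(dense, dense.n_nodes, n_samples=3, seed=0)
        # analytic giant fraction: s = 1 - exp(-c s) for c = 3 -> ~0.94
        assert abs(null.mean - 94.0) < 3.0
        sparse = nx.gnp_random_graph(n, 0.3 / n, seed=9)
        sparse.add_nodes_from(range(n))
        sparse = Interactome(nx.relabel_nodes(sparse, {i: f"n{i}" for i in range(n)}))
        null2 = null_distribution(sparse, sparse.n_nodes, n_samples=3, seed=0)
        assert null2.mean < 5.0


class TestSizeCurve:
    def test_degenerate_sizes(self):
        g = nx.gnp_random_graph(40, 0.15, seed=3)
        inter = Interactome(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
        curve = size_curve(inter, sizes=[1, inter.n_nodes], reps=5, seed=7)
        whole = interconnectivity(inter, inter.nodes).fraction
        assert curve.points.iloc[0]["mean_fraction"] == 100.0  # single node is its own LCC
        assert curve.points.iloc[1]["mean_fraction"] == pytest.approx(whole)

    def test_monotone_in_expectation_and_deterministic(self):
        g = nx.barabasi_albert_graph(800, 6, seed=21)
        inter = Interactome(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
        curve = size_curve(inter, sizes=range(50, 751, 100), reps=20, seed=17)
        again = size_curve(inter, sizes=range(50, 751, 100), reps=20, seed=17)
        assert curve.points.equals(again.points)
        means = curve.points["mean_fraction"].to_numpy()
        # monotone within noise: allow 2 SE dips between adjacent sizes
        se = 100.0 / np.sqrt(20)
        assert np.all(np.diff(means) > -2 * se)

    def test_empty_and_oversized_errors(self):
        inter = interactome_from_edges([("A", "B")])
        with pytest.raises(ValueError):
            size_curve(inter, sizes=[], reps=3, seed=0)
        with pytest.raises(ValueError):
            size_curve(inter, sizes=[5], reps=3, seed=0)


class TestDegreeEnrichment:
    def toy(self):
        # degrees: a=5, b=3, c=2, d=2, e=1, f=1
        return interactome_from_edges(
            [("a", "b"), ("a", "c"), ("a", "d"), ("a", "e"), ("a", "f"),
             ("b", "c"), ("b", "d")]
        )

    def test_running_sum_matches_hand_table(self):
        """Set {a, b} on the toy graph: hits weighted 5/8 and 3/8, misses
        -1/4 each, running sum [0.625, 1.0, 0.75, 0.5, 0.25, 0.0]."""
        res = degree_enrichment(self.toy(), ["a", "b"])
        assert res.running_sum == pytest.approx([0.625, 1.0, 0.75, 0.5, 0.25, 0.0])
        assert res.es == pytest.approx(1.0)
        assert res.set_mean_degree == pytest.approx(4.0)
        assert res.background_mean_degree == pytest.approx(14 / 6)

    def test_top_degree_set_scores_near_one(self):
        g = nx.barabasi_albert_graph(300, 3, seed=2)
        inter = Interactome(nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes}))
        degs = dict(inter.graph.degree)
        top = sorted(degs, key=lambda x: (-degs[x], x))[:20]
        res = degree_enrichment(inter, top)
        assert res.es > 1 - 1 / (300 - 20)

    def test_random_sets_score_small_on_average(self):
        g = nx.gnp_random_graph(1000, 8 / 999, seed=13)
        inter = Interactome(nx.relabel_nodes(g, {i: f"n{i:04d}" for i in g.nodes}))
        rng = np.random.default_rng(99)
        nodes = inter.nodes
        scores = []
        for _ in range(200):
            subset = [nodes[i] for i in rng.choice(1000, 100, replace=False)]
            scores.append(abs(degree_enrichment(inter, subset).es))
        assert np.mean(scores) < 0.2

    def test_full_cover_set_is_an_error(self):
        inter = self.toy()
        with pytest.raises(ValueError):
            degree_enrichment(inter, inter.nodes)


class TestMeanDegree:
    def test_triangle_and_star(self):
        tri = interactome_from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        assert mean_degree(tri) == 2.0
        star = interactome_from_edges([("hub", x) for x in "ABCD"])
        assert mean_degree(star, ["hub"]) == 4.0

    def test_handshake_lemma_on_random_graph(self):
        g = nx.gnp_random_graph(120, 0.1, seed=4)
        inter = Interactome(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
        assert mean_degree(inter) == pytest.approx(2 * inter.n_edges / inter.n_nodes)

    def test_empty_query_is_an_error(self):
        inter = interactome_from_edges([("A", "B")])
        with pytest.raises(ValueError):
            mean_degree(inter, ["ghost"])
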