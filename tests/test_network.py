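"""Network construction against independent brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from anticoex import network
from anticoex.types import AntiCoexNetwork, ExpressionMatrix, OrthologyMap, ProbesetGeneMap, ValidationError


def expr_from(values, probesets=None, samples=None, dataset_id="d", species="human"):
    arr = np.asarray(values, dtype=float)
    probesets = probesets or [f"p{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(dataset_id, species, pd.DataFrame(arr, index=probesets, columns=samples))


def pearson_oracle(x, y):
    """Independent per-pair Pearson formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


class TestCorrelationMatrix:
    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        expr = expr_from([x, -x, x * 2 + 1])
        corr = network.correlation_matrix(expr)
        assert corr.loc["p0", "p1"] == pytest.approx(-1.0)
        assert corr.loc["p0", "p2"] == pytest.approx(1.0)

    def test_diagonal_is_one(self):
        rng = np.random.default_rng(0)
        corr = network.correlation_matrix(expr_from(rng.normal(size=(6, 10))))
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_matches_per_pair_oracle(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(size=(50, 20))
        corr = network.correlation_matrix(expr_from(vals))
        for i in range(0, 50, 7):
            for j in range(i + 1, 50, 11):
                assert corr.iloc[i, j] == pytest.approx(
                    pearson_oracle(vals[i], vals[j]), abs=1e-12
                )

    def test_missing_values_use_pairwise_complete(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(4, 12))
        vals[0, :3] = np.nan
        corr = network.correlation_matrix(expr_from(vals), min_overlap=4)
        mask = ~np.isnan(vals[0])
        expected = pearson_oracle(vals[0][mask], vals[1][mask])
        assert corr.loc["p0", "p1"] == pytest.approx(expected, abs=1e-12)

    def test_insufficient_overlap_is_undefined(self):
        vals = np.full((2, 10), np.nan)
        vals[0, :5] = [1, 2, 3, 4, 5]
        vals[1, 3:] = [2, 1, 7, 3, 9, 4, 5]  # only samples 3,4 shared
        corr = network.correlation_matrix(expr_from(vals), min_overlap=4)
        assert np.isnan(corr.loc["p0", "p1"])

    def test_all_constant_input_rejected(self):
        expr = expr_from(np.ones((3, 6)))
        with pytest.raises(ValidationError, match="non-constant"):
            network.correlation_matrix(expr)

    def test_too_few_samples_refused(self):
        expr = expr_from(np.random.default_rng(0).normal(size=(3, 3)))
        with pytest.raises(ValidationError, match="minimum"):
            network.correlation_matrix(expr)


def directed_oracle(corr: pd.DataFrame, fraction: float):
    """Full per-column sort, strictly negative only, lexicographic ties."""
    ids = list(corr.index)
    n = len(ids)
    k = max(1, math.floor(fraction * (n - 1)))
    edges = set()
    for p2 in ids:
        cands = [
            (corr.at[p1, p2], p1)
            for p1 in ids
            if p1 != p2 and np.isfinite(corr.at[p1, p2]) and corr.at[p1, p2] < 0
        ]
        cands.sort()
        for _, p1 in cands[:k]:
            edges.add((p1, p2))
    return edges


class TestDirectedEdges:
    def test_k_formula_single_partner(self):
        rng = np.random.default_rng(5)
        n = 101
        m = rng.uniform(-1, 1, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ids = [f"p{i:03d}" for i in range(n)]
        corr = pd.DataFrame(m, index=ids, columns=ids)
        edges = network.directed_anticorr_edges(corr, fraction=0.01)
        assert network.anticorr_fraction_k(n, 0.01) == 1
        incoming = {}
        for p1, p2 in edges:
            incoming.setdefault(p2, []).append(p1)
        assert all(len(v) == 1 for v in incoming.values())

    def test_no_negative_column_gets_no_incoming_edges(self):
        m = np.array([[1.0, 0.5, -0.8], [0.5, 1.0, 0.2], [-0.8, 0.2, 1.0]])
        ids = ["a", "b", "c"]
        corr = pd.DataFrame(m, index=ids, columns=ids)
        edges = network.directed_anticorr_edges(corr, fraction=0.5)
        assert not any(p2 == "b" for _, p2 in edges)

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(99)
        n = 100
        m = rng.uniform(-1, 1, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ids = [f"p{i:03d}" for i in range(n)]
        corr = pd.DataFrame(m, index=ids, columns=ids)
        for fraction in (0.01, 0.05, 0.2):
            assert network.directed_anticorr_edges(corr, fraction) == directed_oracle(
                corr, fraction
            )

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.1, 2.0])
    def test_fraction_out_of_range_rejected(self, fraction):
        corr = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValidationError):
            network.directed_anticorr_edges(corr, fraction)


class TestReciprocal:
    def test_reciprocity_definition(self):
        net = network.reciprocal_undirected({("a", "b"), ("b", "a"), ("a", "c")})
        assert net.edges == {frozenset({"a", "b"})}

    def test_empty_input(self):
        assert network.reciprocal_undirected(set()).edges == set()

    @settings(max_examples=50, deadline=None)
    @given(
        st.sets(
            st.tuples(
                st.integers(min_value=0, max_value=8),
                st.integers(min_value=0, max_value=8),
            ).filter(lambda t: t[0] != t[1]),
            max_size=30,
        )
    )
    def test_every_undirected_edge_has_both_directed_parents(self, pairs):
        directed = {(f"p{a}", f"p{b}") for a, b in pairs}
        net = network.reciprocal_undirected(directed)
        for edge in net.edges:
            u, v = tuple(edge)
            assert (u, v) in directed and (v, u) in directed

    def test_planted_pair_recovered_from_noise(self):
        rng = np.random.default_rng(7)
        n_samples = 40
        z = rng.normal(size=n_samples)
        vals = rng.normal(size=(30, n_samples))
        vals[0] = z
        vals[1] = -z + 0.05 * rng.normal(size=n_samples)
        expr = expr_from(vals)
        corr = network.correlation_matrix(expr)
        net = network.reciprocal_undirected(network.directed_anticorr_edges(corr, 0.05))
        assert frozenset({"p0", "p1"}) in net.edges


def collapse_oracle(net, psmap):
    gene_edges = set()
    for e in net.edges:
        p1, p2 = tuple(e)
        for g1 in psmap.genes_of(p1):
            for g2 in psmap.genes_of(p2):
                if g1 != g2:
                    gene_edges.add(frozenset({g1, g2}))
    return gene_edges


class TestCollapse:
    def test_basic_collapse(self):
        net = AntiCoexNetwork.from_edges([("p1", "p2")], "probeset", "human")
        psmap = ProbesetGeneMap({("p1", "g1"), ("p2", "g2")})
        assert network.collapse_to_genes(net, psmap).edges == {frozenset({"g1", "g2"})}

    def test_within_gene_edge_dropped(self):
        net = AntiCoexNetwork.from_edges([("p1", "p2")], "probeset", "human")
        psmap = ProbesetGeneMap({("p1", "g1"), ("p2", "g1")})
        assert network.collapse_to_genes(net, psmap).edges == set()

    def test_unmapped_probeset_contributes_nothing(self):
        net = AntiCoexNetwork.from_edges([("p1", "p2")], "probeset", "human")
        psmap = ProbesetGeneMap({("p1", "g1")})
        assert network.collapse_to_genes(net, psmap).edges == set()

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(13)
        probesets = [f"p{i}" for i in range(40)]
        genes = [f"g{i}" for i in range(15)]
        pairs = {
            (p, genes[rng.integers(len(genes))])
            for p in probesets
            if rng.random() > 0.2
        }
        psmap = ProbesetGeneMap(pairs)
        edges = set()
        while len(edges) < 60:
            i, j = rng.integers(40, size=2)
            if i != j:
                edges.add((probesets[i], probesets[j]))
        net = AntiCoexNetwork.from_edges(edges, "probeset", "human")
        assert network.collapse_to_genes(net, psmap).edges == collapse_oracle(net, psmap)

    def test_gene_level_input_rejected(self):
        net = AntiCoexNetwork.from_edges([("g1", "g2")], "gene", "human")
        with pytest.raises(ValidationError):
            network.collapse_to_genes(net, ProbesetGeneMap(set()))


def conserved_oracle(net_a, net_b, orth):
    kept = set()
    for e in net_a.edges:
        g1, g2 = tuple(e)
        m1, m2 = orth.ortholog(g1), orth.ortholog(g2)
        if m1 is not None and m2 is not None and frozenset({m1, m2}) in net_b.edges:
            kept.add(e)
    return kept


class TestConserved:
    def setup_method(self):
        self.orth = OrthologyMap(
            [("a1", "b1", True), ("a2", "b2", True), ("a3", "b3", False)]
        )

    def test_edge_conserved(self):
        net_a = AntiCoexNetwork.from_edges([("a1", "a2")], "gene", "human")
        net_b = AntiCoexNetwork.from_edges([("b1", "b2")], "gene", "mouse")
        net = network.build_conserved_network(net_a, net_b, self.orth)
        assert net.edges == {frozenset({"a1", "a2"})}
        assert net.species_scope == "conserved"

    def test_missing_one_to_one_drops_edge(self):
        net_a = AntiCoexNetwork.from_edges([("a1", "a3")], "gene", "human")
        net_b = AntiCoexNetwork.from_edges([("b1", "b3")], "gene", "mouse")
        assert network.build_conserved_network(net_a, net_b, self.orth).edges == set()

    def test_missing_b_edge_drops_edge(self):
        net_a = AntiCoexNetwork.from_edges([("a1", "a2")], "gene", "human")
        net_b = AntiCoexNetwork.from_edges([("b1", "b3")], "gene", "mouse")
        assert network.build_conserved_network(net_a, net_b, self.orth).edges == set()

    def test_matches_triple_condition_oracle(self):
        rng = np.random.default_rng(21)
        genes_a = [f"a{i}" for i in range(25)]
        genes_b = [f"b{i}" for i in range(25)]
        orth = OrthologyMap(
            [(genes_a[i], genes_b[i], bool(rng.random() < 0.7)) for i in range(25)]
        )

        def random_net(genes, seed):
            r = np.random.default_rng(seed)
            edges = set()
            while len(edges) < 50:
                i, j = r.integers(25, size=2)
                if i != j:
                    edges.add((genes[i], genes[j]))
            return AntiCoexNetwork.from_edges(edges, "gene", "x")

        net_a = random_net(genes_a, 1)
        net_b = random_net(genes_b, 2)
        result = network.build_conserved_network(net_a, net_b, orth)
        assert result.edges == conserved_oracle(net_a, net_b, orth)

    def test_conserved_edges_subset_of_species_a(self, default_bundle):
        expr_a, expr_b = default_bundle.expression_pairs[0]
        san_a = network.build_san(expr_a, default_bundle.psmap_a)
        san_b = network.build_san(expr_b, default_bundle.psmap_b)
        conserved = network.build_conserved_network(san_a, san_b, default_bundle.orthology)
        assert conserved.edges <= san_a.edges


class TestMergeAndExtract:
    def test_merge_single_is_identity(self):
        net = AntiCoexNetwork.from_edges([("a", "b")], "gene", "conserved", ["d1"])
        merged = network.merge_networks([net])
        assert merged.edges == net.edges
        assert merged.provenance == ["d1"]

    def test_merge_is_edge_union(self):
        n1 = AntiCoexNetwork.from_edges([("a", "b")], "gene", "conserved")
        n2 = AntiCoexNetwork.from_edges([("b", "c")], "gene", "conserved")
        assert network.merge_networks([n1, n2]).edges == {
            frozenset({"a", "b"}), frozenset({"b", "c"}),
        }

    def test_merge_idempotent(self):
        net = AntiCoexNetwork.from_edges([("a", "b"), ("b", "c")], "gene", "conserved")
        assert network.merge_networks([net, net]).edges == net.edges

    def test_mixed_id_spaces_rejected(self):
        n1 = AntiCoexNetwork.from_edges([("a", "b")], "gene", "human")
        n2 = AntiCoexNetwork.from_edges([("b", "c")], "gene", "mouse")
        with pytest.raises(ValidationError, match="mixed"):
            network.merge_networks([n1, n2])

    def test_star_cluster(self):
        net = AntiCoexNetwork.from_edges(
            [("c", "x"), ("c", "y"), ("c", "z")], "gene", "conserved"
        )
        cagc = network.extract_cagc(net, "c")
        assert cagc.centre == "c"
        assert cagc.members == frozenset({"x", "y", "z"})

    def test_absent_gene_raises(self):
        net = AntiCoexNetwork.from_edges([("a", "b")], "gene", "conserved")
        with pytest.raises(KeyError):
            network.extract_cagc(net, "zzz")

    def test_cluster_symmetry_over_all_edges(self, default_merged):
        for e in default_merged.edges:
            a, b = tuple(e)
            assert b in network.extract_cagc(default_merged, a).members
            assert a in network.extract_cagc(default_merged, b).members
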