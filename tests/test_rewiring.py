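"""Degree-preserving rewiring, permutation statistics, and term enrichment."""

import itertools
import math
from collections import Counter

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cofracnet as cfn
from cofracnet.errors import UndefinedStatisticError


def net(edges, condition="x"):
    return cfn.InteractionNetwork.from_edges(edges, condition)


def ann(mapping, aspect="biological_process", domain_pairs=None):
    return cfn.AnnotationSet(
        aspect=aspect,
        annotations={k: set(v) for k, v in mapping.items()},
        domain_pairs=domain_pairs,
    )


def graphs_with_same_degrees(network):
    """Exhaustive oracle: every simple graph on the same nodes with the same
    degree sequence (feasible for small graphs only)."""
    nodes = sorted(network.nodes)
    target = Counter()
    for a, b in network.edges:
        target[a] += 1
        target[b] += 1
    m = network.n_edges
    out = []
    for edges in itertools.combinations(itertools.combinations(nodes, 2), m):
        deg = Counter()
        for a, b in edges:
            deg[a] += 1
            deg[b] += 1
        if deg == target:
            out.append(frozenset(edges))
    return out


class TestRewire:
    def test_triangle_has_no_valid_swap(self):
        k3 = net([("A", "B"), ("B", "C"), ("A", "C")])
        assert cfn.rewire(k3, seed=1).edges == k3.edges

    def test_two_disjoint_edges_give_a_perfect_matching(self):
        g = net([("a", "b"), ("c", "d")])
        result = cfn.rewire(g, seed=3)
        matchings = [
            frozenset({("a", "b"), ("c", "d")}),
            frozenset({("a", "c"), ("b", "d")}),
            frozenset({("a", "d"), ("b", "c")}),
        ]
        assert result.edges in matchings
        assert set(cfn.degree_table(result).values()) == {1}

    @given(st.integers(0, 10_000))
    @settings(max_examples=30)
    def test_degree_sequence_preserved_and_simple(self, seed):
        g = nx.gnm_random_graph(50, 100, seed=seed)
        network = net([(f"P{u}", f"P{v}") for u, v in g.edges()])
        rewired = cfn.rewire(network, seed=seed + 1)
        assert cfn.degree_table(rewired) == cfn.degree_table(network)
        assert rewired.n_edges == network.n_edges
        assert all(a != b for a, b in rewired.edges)

    def test_deterministic_given_seed(self):
        g = nx.gnm_random_graph(20, 40, seed=5)
        network = net([(f"P{u}", f"P{v}") for u, v in g.edges()])
        assert cfn.rewire(network, seed=9).edges == cfn.rewire(network, seed=9).edges


class TestSharingProportion:
    def test_universal_term(self):
        g = net([("A", "B"), ("B", "C")])
        assert cfn.sharing_proportion(g, ann({p: {"T"} for p in "ABC"})) == 1.0

    def test_no_annotations_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cfn.sharing_proportion(net([("A", "B")]), ann({}))

    def test_half_sharing(self):
        g = net([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        a = ann({"A": {"X"}, "B": {"X"}, "C": {"Y"}, "D": {"Y"}})
        assert cfn.sharing_proportion(g, a) == 0.5

    def test_annotated_only_denominator(self):
        g = net([("A", "B"), ("C", "D")])
        a = ann({"A": {"X"}, "B": {"X"}})  # C, D unannotated
        assert cfn.sharing_proportion(g, a) == 1.0
        assert cfn.sharing_proportion(g, a, annotated_only=False) == 0.5

    def test_domain_aspect_uses_interacting_domain_pairs(self):
        g = net([("A", "B"), ("C", "D")])
        a = ann(
            {"A": {"d1"}, "B": {"d2"}, "C": {"d3"}, "D": {"d4"}},
            aspect="domain",
            domain_pairs={frozenset({"d1", "d2"})},
        )
        assert cfn.sharing_proportion(g, a) == 0.5


class TestPermutationTest:
    def test_topology_invariant_annotation_gives_p_one(self):
        g = net([("A", "B"), ("B", "C"), ("C", "D")])
        result = cfn.permutation_test(g, ann({p: {"T"} for p in "ABCD"}), seed=0)
        assert result.observed == 1.0
        assert all(v == 1.0 for v in result.null_samples)
        assert result.empirical_p == 1.0

    def test_empirical_p_formula_matches_null_samples(self):
        g = nx.gnm_random_graph(12, 24, seed=2)
        network = net([(f"P{u}", f"P{v}") for u, v in g.edges()])
        rng = np.random.default_rng(0)
        a = ann({f"P{i}": {f"T{rng.integers(5)}"} for i in range(12)})
        res = cfn.permutation_test(network, a, n_null=99, seed=4)
        null = np.array(res.null_samples)
        assert res.empirical_p == (1 + (null >= res.observed).sum()) / 100
        if null.std(ddof=1) > 0:
            assert res.z == pytest.approx(
                (res.observed - null.mean()) / null.std(ddof=1)
            )

    def test_empty_network_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cfn.permutation_test(net([]), ann({"A": {"T"}}))

    def test_sampled_p_matches_exhaustive_enumeration(self):
        # small assortative graph: two annotated modules joined by one edge
        edges = [
            ("A", "B"), ("A", "C"), ("B", "C"),
            ("C", "D"), ("D", "E"), ("E", "F"), ("D", "F"),
        ]
        network = net(edges)
        a = ann({p: {"X"} for p in "ABC"} | {p: {"Y"} for p in "DEF"})
        observed = cfn.sharing_proportion(network, a)
        ensemble = graphs_with_same_degrees(network)
        stats = [
            cfn.sharing_proportion(net(es), a) for es in ensemble
        ]
        p_exact = np.mean([s >= observed for s in stats])
        n_null = 400
        res = cfn.permutation_test(network, a, n_null=n_null, seed=11)
        tol = 3 * math.sqrt(p_exact * (1 - p_exact) / n_null) + 2 / (n_null + 1)
        assert abs(res.empirical_p - p_exact) <= tol


class TestContentLogOdds:
    def test_identical_node_sets_give_zero(self):
        g = net([("A", "B"), ("B", "C")])
        out = cfn.content_log_odds(g, g, ann({"A": {"T"}, "B": {"T"}}))
        assert out["T"].log_odds == pytest.approx(0.0)

    def test_two_by_two_arithmetic(self):
        edges_a = [(f"a{i:03d}", f"a{i+100:03d}") for i in range(50)]
        edges_b = [(f"b{i:03d}", f"b{i+100:03d}") for i in range(50)]
        a, b = net(edges_a), net(edges_b)
        annotated = {p: {"T"} for p in sorted(a.nodes)[:10]}
        annotated |= {p: {"T"} for p in sorted(b.nodes)[:5]}
        out = cfn.content_log_odds(a, b, ann(annotated))
        expected = math.log((10 * 95) / (90 * 5))
        assert out["T"].log_odds == pytest.approx(expected, abs=1e-9)

    def test_zero_cell_is_finite_via_correction(self):
        a = net([("A", "B")])
        b = net([("C", "D")])
        out = cfn.content_log_odds(a, b, ann({"A": {"T"}, "B": {"T"}}))
        assert math.isfinite(out["T"].log_odds)
        assert math.isfinite(out["T"].z)


class TestDifferentialTermEnrichment:
    def _module_networks(self):
        """Term MOD proteins densely wired only in network a."""
        mod = [f"M{i}" for i in range(6)]
        other = [f"O{i}" for i in range(30)]
        ring = [(other[i], other[(i + 1) % 30]) for i in range(30)]
        a_edges = ring + [p for p in itertools.combinations(mod, 2)]
        chain = [(m, other[i]) for i, m in enumerate(mod)]
        b_edges = ring + chain
        annotations = {p: {"MOD"} for p in mod}
        annotations.update({p: {f"BG{i % 7}"} for i, p in enumerate(other)})
        return net(a_edges, "a"), net(b_edges, "b"), ann(annotations)

    def test_identical_networks_have_no_significant_terms(self):
        a, _, annotations = self._module_networks()
        records = cfn.differential_term_enrichment(
            a, a, annotations, n_null=50, seed=0
        )
        assert records
        assert all(r.delta == 0 for r in records)
        assert not any(r.significant for r in records)

    def test_sparse_terms_excluded(self):
        a, b, _ = self._module_networks()
        annotations = ann({"M0": {"RARE"}, "M1": {"RARE"}})
        records = cfn.differential_term_enrichment(
            a, b, annotations, min_annotated=3, n_null=20, seed=0
        )
        assert records == []

    def test_planted_module_detected_with_direction(self):
        a, b, annotations = self._module_networks()
        records = cfn.differential_term_enrichment(
            a, b, annotations, n_null=100, fdr=0.10, seed=1
        )
        by_term = {r.term: r for r in records}
        mod = by_term["MOD"]
        assert mod.direction == "enriched_in_a"
        assert mod.significant
        assert mod.q >= mod.p

    def test_bh_q_values_monotone_in_p(self):
        a, b, annotations = self._module_networks()
        records = cfn.differential_term_enrichment(
            a, b, annotations, n_null=60, seed=2
        )
        by_p = sorted(records, key=lambda r: r.p)
        qs = [r.q for r in by_p]
        assert qs == sorted(qs)


class TestEnrichmentMap:
    def _records(self, terms):
        return [
            cfn.TermEnrichmentRecord(
                term=t, n_edges_a=1, n_edges_b=0, delta=1, z=3.0, p=0.001,
                q=0.01, direction="enriched_in_a", content_log_odds_z=1.0,
                significant=True,
            )
            for t in terms
        ]

    def test_identical_sets_connected(self):
        a = ann({"A": {"T1", "T2"}, "B": {"T1", "T2"}})
        edges = cfn.enrichment_map(self._records(["T1", "T2"]), a)
        assert edges == [cfn.EnrichmentMapEdge("T1", "T2", 1.0)]

    def test_disjoint_sets_not_connected(self):
        a = ann({"A": {"T1"}, "B": {"T2"}})
        assert cfn.enrichment_map(self._records(["T1", "T2"]), a) == []

    def test_partial_overlap_against_cutoff(self):
        a = ann(
            {"A": {"T1"}, "B": {"T1", "T2"}, "C": {"T1", "T2"}, "D": {"T2"}}
        )
        edges = cfn.enrichment_map(self._records(["T1", "T2"]), a, jaccard_cutoff=0.33)
        assert len(edges) == 1
        assert edges[0].jaccard == pytest.approx(0.5)
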