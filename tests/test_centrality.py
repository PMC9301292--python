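"""Eight centrality measures against brute-force oracles; consensus rule."""

import math

import networkx as nx
import numpy as np
import pytest

from herbnet.centrality import (
    MEASURES,
    compute_centralities,
    profiles_frame,
    select_core,
    select_core_ingredients,
)
from herbnet.networks import build_hitd, build_target_net
from herbnet.screening import IngredientRecord

from conftest import random_simple_graph
from oracles import BRUTE_ORACLES


def as_dicts(profiles):
    return {m: {p.node: getattr(p, m) for p in profiles} for m in MEASURES}


class TestMeasures:
    def test_triangle_values(self):
        profiles = compute_centralities(nx.complete_graph(3))
        expected_subgraph = (math.e ** 2 + 2 * math.e ** -1) / 3
        for p in profiles:
            assert p.degree == 2
            assert p.betweenness == 0
            assert p.lac == pytest.approx(1.0)
            assert p.network_c == pytest.approx(2.0)  # both edges at ECC 1
            assert p.subgraph == pytest.approx(expected_subgraph, rel=1e-12)
            assert p.eigenvector == pytest.approx(1 / math.sqrt(3), rel=1e-9)

    def test_path_betweenness(self):
        g = nx.path_graph(3)  # a - b - c
        vals = {p.node: p.betweenness for p in compute_centralities(g)}
        assert vals[1] == 1.0
        assert vals[0] == 0.0 and vals[2] == 0.0

    def test_matches_brute_force_on_random_small_graphs(self, rng):
        for _ in range(40):
            g = random_simple_graph(rng)
            mine = as_dicts(compute_centralities(g))
            for measure, oracle in BRUTE_ORACLES.items():
                ref = oracle(g)
                for v in g:
                    assert mine[measure][v] == pytest.approx(
                        ref[v], rel=1e-8, abs=1e-8), (measure, sorted(g.edges()))

    def test_relabeling_invariance(self, rng):
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        perm = rng.permutation(12)
        mapping = {i: int(perm[i]) for i in range(12)}
        h = nx.relabel_nodes(g, mapping)
        a = as_dicts(compute_centralities(g))
        b = as_dicts(compute_centralities(h))
        for m in MEASURES:
            for v in g:
                assert a[m][v] == pytest.approx(b[m][mapping[v]], rel=1e-8, abs=1e-10)

    def test_estrada_index_identity(self, rng):
        """Subgraph centralities sum to the Estrada index sum(exp(lambda_i))."""
        g = nx.gnp_random_graph(15, 0.3, seed=3)
        profiles = compute_centralities(g)
        eigvals = np.linalg.eigvalsh(nx.to_numpy_array(g))
        assert sum(p.subgraph for p in profiles) == pytest.approx(
            np.exp(eigvals).sum(), rel=1e-10)

    def test_all_values_finite_nonnegative_and_degree_exact(self, rng):
        g = random_simple_graph(rng)
        for p in compute_centralities(g):
            vals = p.values()
            assert np.isfinite(vals).all()
            assert (vals >= 0).all()
            assert p.degree == g.degree(p.node)

    def test_disconnected_graph_handled_per_component(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
        profiles = {p.node: p for p in compute_centralities(g)}
        assert profiles["x"].closeness == pytest.approx(1.0)  # (2-1)/1
        assert np.isfinite(profiles["x"].information)

    @pytest.mark.parametrize("graph", [
        nx.DiGraph([(0, 1)]),
        nx.MultiGraph([(0, 1), (0, 1)]),
        nx.Graph([(0, 0), (0, 1)]),
    ])
    def test_invalid_graphs_rejected(self, graph):
        with pytest.raises(ValueError):
            compute_centralities(graph)


class TestSelectCore:
    @pytest.mark.parametrize("graph", [
        nx.cycle_graph(6), nx.complete_graph(5), nx.petersen_graph()])
    def test_vertex_transitive_graphs_have_empty_core(self, graph):
        core, _ = select_core(compute_centralities(graph))
        assert core == []

    def test_star_center_is_sole_core_node(self):
        core, report = select_core(compute_centralities(nx.star_graph(6)))
        assert core == [0]
        # the triangle-free measures carry no information on a star
        assert set(report["degenerate"]) == {"lac", "network_c"}

    def test_monotone_in_criteria_count(self, rng):
        for _ in range(10):
            g = random_simple_graph(rng)
            profiles = compute_centralities(g)
            full, _ = select_core(profiles)
            for dropped in MEASURES:
                sub = [m for m in MEASURES if m != dropped]
                reduced, _ = select_core(profiles, measures=sub)
                assert set(full) <= set(reduced)

    def test_core_within_high_degree_nodes(self, rng):
        for _ in range(10):
            g = random_simple_graph(rng)
            profiles = compute_centralities(g)
            degrees = np.array([p.degree for p in profiles], dtype=float)
            if degrees.max() == degrees.min():
                continue
            core, _ = select_core(profiles)
            med = np.median(degrees)
            high = {p.node for p in profiles if p.degree > med}
            assert set(core) <= high

    def test_ge_rule_is_weaker(self, rng):
        g = random_simple_graph(rng)
        profiles = compute_centralities(g)
        strict, _ = select_core(profiles, rule="strict")
        ge, _ = select_core(profiles, rule="ge")
        assert set(strict) <= set(ge)

    def test_core_ingredients_filters_to_ingredient_kind(self):
        records = [IngredientRecord(f"I{i}", f"I{i}", {"CH"}) for i in range(4)]
        pairs = [("I0", "A"), ("I0", "B"), ("I0", "C"), ("I1", "A"),
                 ("I2", "B"), ("I3", "C"), ("I3", "A")]
        net = build_target_net(pairs)
        g = build_hitd(records, net, {"A", "B", "C"})
        core_ings, report = select_core_ingredients(g)
        kinds = nx.get_node_attributes(g, "kind")
        assert all(kinds[v] == "ingredient" for v in core_ings)
        assert set(core_ings) <= set(report["core_all"])


def test_profiles_frame_columns():
    frame = profiles_frame(compute_centralities(nx.path_graph(4)))
    assert list(frame.columns) == ["node", *MEASURES]
    assert len(frame) == 4
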