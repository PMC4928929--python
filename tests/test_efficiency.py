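"""Global, set, and interset efficiency, SE curves, and IE matrices."""

import numpy as np
import pytest

from conftest import floyd_warshall, random_digraph
from grnevo import (
    EvoAnnotation,
    GeneNetwork,
    cumulative_se_curve,
    global_efficiency,
    ie_matrix,
    interset_efficiency,
    set_efficiency,
)

INF = float("inf")


def brute_efficiencies(g, i_set, j_set):
    """Brute-force interset efficiency from a Floyd-Warshall table."""
    d = floyd_warshall(g.nodes, [(u, v) for u, v, _, _ in g.arcs()])
    total = sum(
        1.0 / d[(i, j)]
        for i in i_set
        for j in j_set
        if i != j and d[(i, j)] not in (0.0, INF)
    )
    denom = len(i_set) * len(j_set) - len(set(i_set) & set(j_set))
    return total / denom


class TestWorkedValues:
    def test_directed_3cycle_global(self):
        g = GeneNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "a")])
        r = global_efficiency(g)
        assert r.value == pytest.approx(0.75)  # (3*1 + 3*1/2) / 6
        assert r.contributing_pairs == 6 and r.unreachable_pairs == 0

    def test_complete_digraph_is_one(self):
        names = [f"n{i}" for i in range(5)]
        g = GeneNetwork.from_edges([(u, v) for u in names for v in names if u != v])
        assert global_efficiency(g).value == 1.0

    def test_edgeless_graph_is_zero(self):
        g = GeneNetwork()
        for x in "abcd":
            g.add_node(x)
        r = global_efficiency(g)
        assert r.value == 0.0 and r.unreachable_pairs == 12

    def test_path_graph_endpoint_set(self):
        g = GeneNetwork.from_edges([("a", "b", 1, 0), ("b", "c", 1, 0)])
        assert set_efficiency(g, {"a", "c"}).value == pytest.approx(0.5)

    def test_overlapping_triangle_interset(self):
        g = GeneNetwork.from_edges(
            [("a", "b", 1, 0), ("b", "c", 1, 0), ("a", "c", 1, 0)]
        )
        assert interset_efficiency(g, {"a", "b"}, {"b", "c"}).value == pytest.approx(1.0)

    def test_set_of_all_nodes_equals_global(self):
        rng = np.random.default_rng(30)
        g = random_digraph(rng, n=12, p=0.3)
        assert set_efficiency(g, g.nodes).value == global_efficiency(g).value

    def test_singleton_set_errors(self):
        g = GeneNetwork.from_edges([("a", "b")])
        with pytest.raises(ValueError, match="singleton"):
            set_efficiency(g, {"a"})

    def test_disjoint_components_zero(self):
        g = GeneNetwork.from_edges([("a", "b", 1, 0), ("x", "y", 1, 0)])
        assert interset_efficiency(g, {"a", "b"}, {"x", "y"}).value == 0.0

    def test_unknown_gene_keyerror(self):
        g = GeneNetwork.from_edges([("a", "b")])
        with pytest.raises(KeyError):
            set_efficiency(g, {"a", "zz"})


class TestOracleEquivalence:
    def test_matches_brute_force_and_bounds(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            g = random_digraph(rng, n=int(rng.integers(5, 20)))
            nodes = g.nodes
            assert abs(
                global_efficiency(g).value - brute_efficiencies(g, nodes, nodes)
            ) < 1e-12
            k = int(rng.integers(2, len(nodes)))
            m = list(rng.choice(nodes, size=k, replace=False))
            se = set_efficiency(g, m).value
            assert abs(se - brute_efficiencies(g, m, m)) < 1e-12
            j = list(rng.choice(nodes, size=int(rng.integers(2, len(nodes))), replace=False))
            ie = interset_efficiency(g, m, j).value
            assert abs(ie - brute_efficiencies(g, m, j)) < 1e-12
            assert 0.0 <= se <= 1.0 and 0.0 <= ie <= 1.0

    def test_e_ii_equals_e_i_exactly(self):
        rng = np.random.default_rng(32)
        g = random_digraph(rng, n=15, p=0.3)
        for _ in range(20):
            m = list(rng.choice(g.nodes, size=int(rng.integers(2, 15)), replace=False))
            assert interset_efficiency(g, m, m).value == set_efficiency(g, m).value

    def test_adding_edges_never_decreases_efficiency(self):
        rng = np.random.default_rng(33)
        g = random_digraph(rng, n=12, p=0.2)
        base = global_efficiency(g).value
        g2 = g.copy()
        missing = [
            (u, v) for u in g.nodes for v in g.nodes
            if u != v and not g.has_arc(u, v)
        ]
        for u, v in list(missing)[:5]:
            g2.add_edge(u, v)
        assert global_efficiency(g2).value >= base


class TestSECurve:
    def _bundle(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        g = random_digraph(rng, n=n, p=0.15)
        er = {x: float(rng.random()) for x in g.nodes}
        return g, EvoAnnotation(er=er)

    def test_window_grid(self):
        g, ann = self._bundle()
        c = cumulative_se_curve(g, ann, "er", start=20, step=10, n_controls=5, seed=1)
        assert list(c.ranks) == [20, 30, 40, 50, 60]
        assert len(c.se_values) == len(c.control_mean) == len(c.control_sd)

    def test_final_window_equals_every_control_exactly(self):
        g, ann = self._bundle(seed=1)
        c = cumulative_se_curve(g, ann, "er", start=20, step=10, n_controls=10, seed=2)
        assert np.all(c.control_curves[:, -1] == c.se_values[-1])

    def test_constant_attribute_within_control_band(self):
        rng = np.random.default_rng(34)
        g = random_digraph(rng, n=60, p=0.15)
        ann = EvoAnnotation(er={x: 1.0 for x in g.nodes})
        c = cumulative_se_curve(g, ann, "er", start=20, step=10, n_controls=30, seed=3)
        # ordering carries no information: real curve is one random ordering
        inside = np.abs(c.se_values - c.control_mean) <= 3 * np.maximum(c.control_sd, 1e-15)
        assert inside[:-1].all()
        assert np.all(c.control_curves[:, -1] == c.se_values[-1])

    def test_prefix_matches_direct_set_efficiency(self):
        g, ann = self._bundle(seed=2, n=40)
        c = cumulative_se_curve(g, ann, "er", start=10, step=10, n_controls=2, seed=4)
        values = ann.values("er")
        coldest = sorted(g.nodes, key=lambda x: (values[x], x))[:10]
        assert c.se_values[0] == pytest.approx(set_efficiency(g, coldest).value, abs=1e-12)

    def test_start_exceeding_annotated_count_errors(self):
        g, ann = self._bundle()
        with pytest.raises(ValueError):
            cumulative_se_curve(g, ann, "er", start=1000)


class TestIEMatrix:
    def test_diagonal_is_set_efficiency_and_order_by_age(self):
        rng = np.random.default_rng(35)
        g = random_digraph(rng, n=20, p=0.3)
        nodes = g.nodes
        groups = {"old_set": nodes[:6], "young_set": nodes[6:12], "mid_set": nodes[12:18]}
        ages = {}
        for x in nodes[:6]:
            ages[x] = 1
        for x in nodes[6:12]:
            ages[x] = 11
        for x in nodes[12:18]:
            ages[x] = 5
        for x in nodes[18:]:
            ages[x] = 6
        ann = EvoAnnotation(age=ages)
        iem = ie_matrix(g, groups, ann)
        assert iem.names == ["old_set", "mid_set", "young_set"]  # oldest first
        for k, name in enumerate(iem.names):
            assert iem.matrix[k, k] == set_efficiency(g, groups[name]).value

    def test_entries_match_elementwise_oracle(self):
        rng = np.random.default_rng(36)
        g = random_digraph(rng, n=14, p=0.3)
        nodes = g.nodes
        groups = {"g1": nodes[:5], "g2": nodes[5:10]}
        ann = EvoAnnotation(age={x: (2 if i < 5 else 9) for i, x in enumerate(nodes)})
        iem = ie_matrix(g, groups, ann)
        for i, tgt in enumerate(iem.names):
            for j, src in enumerate(iem.names):
                expected = brute_efficiencies(g, sorted(groups[tgt]), sorted(groups[src]))
                assert iem.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_identical_groups_give_identical_rows(self):
        rng = np.random.default_rng(37)
        g = random_digraph(rng, n=12, p=0.3)
        nodes = g.nodes
        groups = {"a_set": nodes[:5], "b_set": nodes[:5], "c_set": nodes[5:10]}
        ann = EvoAnnotation(age={x: 4 for x in nodes})
        iem = ie_matrix(g, groups, ann)
        ia, ib = iem.names.index("a_set"), iem.names.index("b_set")
        assert np.array_equal(iem.matrix[ia], iem.matrix[ib])
        assert np.array_equal(iem.matrix[:, ia], iem.matrix[:, ib])
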