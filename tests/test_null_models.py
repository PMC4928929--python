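"""Degree-preserving rewiring and random-set group tests."""

import numpy as np
import pytest

from conftest import random_digraph
from grnevo import (
    EvoAnnotation,
    GeneNetwork,
    edge_diff_test,
    group_mean_test,
    rewire,
    shuffled_community_control,
)
from grnevo.community import partition_from_assignment


class TestRewire:
    def test_degree_sequences_preserved_exactly(self):
        rng = np.random.default_rng(0)
        for s in range(10):
            g = random_digraph(rng, n=25, p=0.25)
            r = rewire(g, seed=s)
            assert r.in_degree() == g.in_degree()
            assert r.out_degree() == g.out_degree()
            assert r.n == g.n and r.n_arcs == g.n_arcs

    def test_no_self_loops_or_duplicates(self):
        rng = np.random.default_rng(1)
        g = random_digraph(rng, n=20, p=0.3)
        r = rewire(g, n_swaps=5000, seed=7)
        arcs = [(u, v) for u, v, _, _ in r.arcs()]
        assert all(u != v for u, v in arcs)
        assert len(arcs) == len(set(arcs))

    def test_directed_3cycle_immutable(self):
        g = GeneNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "a")])
        r = rewire(g, n_swaps=1000, seed=3)
        assert sorted(r.arcs()) == sorted(g.arcs())

    def test_zero_swaps_identity(self):
        rng = np.random.default_rng(2)
        g = random_digraph(rng, n=15)
        r = rewire(g, n_swaps=0, seed=1)
        assert sorted(r.arcs()) == sorted(g.arcs())

    def test_actually_rewires_dense_graph(self):
        rng = np.random.default_rng(3)
        g = random_digraph(rng, n=30, p=0.3, undirected_frac=0.0)
        r = rewire(g, seed=5)
        assert sorted(r.arcs()) != sorted(g.arcs())


class TestEdgeDiffTest:
    def test_constant_values_zero_width(self):
        rng = np.random.default_rng(4)
        g = random_digraph(rng, n=15, p=0.3)
        ann = EvoAnnotation(er={x: 1.0 for x in g.nodes})
        r = edge_diff_test(g, ann, "er", n_random=20, seed=0)
        assert r.width == 0.0 and np.all(r.diffs == 0)

    def test_empirical_p_estimator(self):
        rng = np.random.default_rng(5)
        g = random_digraph(rng, n=20, p=0.3)
        ann = EvoAnnotation(er={x: float(i) for i, x in enumerate(g.nodes)})
        n_random = 50
        r = edge_diff_test(g, ann, "er", n_random=n_random, seed=1)
        rank = int(np.sum(r.null_widths <= r.width))
        assert r.p_upper == (rank + 1) / (n_random + 1)
        assert 0 < r.p_upper <= 1

    def test_degenerate_null_flagged(self):
        # 3-cycle cannot be rewired: all null widths identical -> z undefined
        g = GeneNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "a")])
        ann = EvoAnnotation(er={"A": 0.0, "B": 1.0, "C": 2.0})
        r = edge_diff_test(g, ann, "er", n_random=10, seed=0)
        assert r.degenerate

    def test_diff_count_matches_annotated_arcs(self):
        g = GeneNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d", 1, 0)])
        ann = EvoAnnotation(er={"A": 1.0, "B": 2.0, "C": 3.0})  # D unannotated
        r = edge_diff_test(g, ann, "er", n_random=5, seed=0)
        assert r.n_edges == 2  # a->b, b->c; both c-d arcs lack an endpoint


class TestGroupMeanTest:
    def test_whole_universe_is_average(self):
        rng = np.random.default_rng(6)
        g = random_digraph(rng, n=20, p=0.3)
        ann = EvoAnnotation(er={x: float(rng.random()) for x in g.nodes})
        st = group_mean_test(g, ann, g.nodes, "er", n_sets=50, seed=0)
        assert st.diff_in_mean == 0.0 and st.label == "average"
        assert st.ks_stat == 0.0  # identical distributions

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        g = random_digraph(rng, n=20, p=0.3)
        values = [float(v) for v in rng.normal(size=20)]
        values = [v - min(values) for v in values]  # keep ER >= 0
        ann1 = EvoAnnotation(er=dict(zip(g.nodes, values)))
        group1 = g.nodes[:6]
        # relabel genes by reversing the node <-> value association
        mapping = dict(zip(g.nodes, reversed(g.nodes)))
        g2 = GeneNetwork.from_edges(
            [(mapping[u], mapping[v], w, d) for u, v, w, d in g.arcs()]
        )
        for x in g.nodes:
            g2.add_node(mapping[x])
        ann2 = EvoAnnotation(er={mapping[x]: ann1.er[x] for x in g.nodes})
        group2 = [mapping[x] for x in group1]
        st1 = group_mean_test(g, ann1, group1, "er", n_sets=100, seed=5)
        st2 = group_mean_test(g2, ann2, group2, "er", n_sets=100, seed=5)
        assert st1.p == pytest.approx(st2.p)
        assert st1.diff_in_mean == pytest.approx(st2.diff_in_mean)

    def test_group_exceeding_universe_errors(self):
        g = GeneNetwork.from_edges([("a", "b")])
        ann = EvoAnnotation(er={"A": 1.0, "B": 2.0})
        with pytest.raises(ValueError):
            group_mean_test(g, ann, ["a", "b", "c"], "er")

    def test_age_labels_young_old(self):
        rng = np.random.default_rng(8)
        g = random_digraph(rng, n=40, p=0.2)
        ages = {x: (12 if i < 8 else 1) for i, x in enumerate(g.nodes)}
        ann = EvoAnnotation(age=ages)
        young = group_mean_test(g, ann, g.nodes[:8], "age", n_sets=300, seed=1)
        assert young.label == "young" and young.p < 1e-3


class TestShuffledCommunityControl:
    def _partition(self):
        g = GeneNetwork.from_edges([("a", "b"), ("c", "d"), ("e", "f")])
        return g, partition_from_assignment(
            g, {"A": 0, "B": 0, "C": 0, "D": 1, "E": 1, "F": 2}
        )

    def test_sizes_preserved_exactly(self):
        g, p = self._partition()
        for s in range(5):
            sp = shuffled_community_control(p, seed=s, g=g)
            assert sorted(sp.sizes()) == sorted(p.sizes())

    def test_single_community_identity(self):
        g = GeneNetwork.from_edges([("a", "b")])
        p = partition_from_assignment(g, {"A": 0, "B": 0})
        sp = shuffled_community_control(p, seed=3, g=g)
        assert sp.assignment == p.assignment

    def test_genes_actually_move(self):
        g, p = self._partition()
        moved = any(
            shuffled_community_control(p, seed=s).assignment != p.assignment
            for s in range(5)
        )
        assert moved
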