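import itertools
import math

import numpy as np
import pytest

from shellprint import cycles, synthetic
from shellprint.cycles import (
    CyclicStructure,
    describe_cycle,
    feature_dimension,
    match_structures,
    min_cycle_basis_oracle,
    sdfs_cycles,
)
from shellprint.skeletongraph import SkeletonGraph, prune_to_cycle_graph


def _edge_vector_space(g: SkeletonGraph, cycle_nodes) -> frozenset:
    """Cycle as a set of undirected node-pair edges (GF(2) vector)."""
    n = len(cycle_nodes)
    return frozenset(
        frozenset((cycle_nodes[i], cycle_nodes[(i + 1) % n])) for i in range(n)
    )


def _independent_over_gf2(vectors: list[frozenset]) -> bool:
    """Exact independence check by exhaustive subset XOR (small inputs)."""
    for r in range(1, len(vectors) + 1):
        for combo in itertools.combinations(vectors, r):
            acc: set = set()
            for v in combo:
                acc ^= set(v)
            if not acc:
                return False
    return True


class TestSDFS:
    def test_two_triangles(self):
        g = synthetic.toy_planar_graph("two_triangles_shared_edge")
        found = sdfs_cycles(g, 6)
        assert sorted(tuple(sorted(c.node_ids)) for c in found) == [
            (0, 1, 2),
            (0, 1, 3),
        ]

    def test_grid_unit_squares(self):
        g = synthetic.toy_planar_graph("grid_2x2")
        found = sdfs_cycles(g, 4)
        assert len(found) == 4
        assert all(c.n == 4 for c in found)
        expected = [
            {0, 1, 3, 4}, {1, 2, 4, 5}, {3, 4, 6, 7}, {4, 5, 7, 8},
        ]
        got = sorted((set(c.node_ids) for c in found), key=sorted)
        assert got == expected

    def test_hexagon_single_cycle(self):
        g = synthetic.toy_planar_graph("hexagon")
        found = sdfs_cycles(g, 6)
        assert len(found) == 1
        assert found[0].n == 6

    def test_max_cycle_len_filter(self):
        g = synthetic.toy_planar_graph("hexagon")
        assert sdfs_cycles(g, 5) == []

    def test_empty_graph(self):
        assert sdfs_cycles(SkeletonGraph(), 6) == []

    def test_no_duplicate_cycles(self, phantom_artifacts):
        pruned = prune_to_cycle_graph(phantom_artifacts.graph)
        found = sdfs_cycles(pruned, 6)
        keys = set()
        for c in found:
            rots = {
                tuple(c.node_ids[s:] + c.node_ids[:s]) for s in range(c.n)
            } | {
                tuple(reversed(c.node_ids[s:] + c.node_ids[:s]))
                for s in range(c.n)
            }
            canon = min(rots)
            assert canon not in keys
            keys.add(canon)

    @pytest.mark.parametrize("name", synthetic.TOY_GRAPH_NAMES)
    def test_equals_minimum_cycle_basis_on_fixtures(self, name):
        """SDFS faces form a minimum cycle basis on every planar fixture."""
        g = prune_to_cycle_graph(synthetic.toy_planar_graph(name))
        found = sdfs_cycles(g, 6)
        basis = min_cycle_basis_oracle(g)
        rank = g.number_of_edges() - g.number_of_nodes() + 1
        if g.number_of_nodes() == 0:
            assert found == []
            return
        assert len(found) == len(basis) == rank
        # same multiset of cycle lengths -> same total weight (minimality)
        assert sorted(c.n for c in found) == sorted(len(b) for b in basis)
        # and the SDFS cycles are linearly independent over GF(2)
        vectors = [_edge_vector_space(g, list(c.node_ids)) for c in found]
        assert _independent_over_gf2(vectors)


class TestFeatureDimension:
    @pytest.mark.parametrize("n,dim", [(3, 18), (4, 24), (5, 30), (6, 36)])
    def test_dimensions(self, n, dim):
        assert feature_dimension(n) == dim

    @pytest.mark.parametrize("n", [2, 7, 0])
    def test_out_of_range(self, n):
        with pytest.raises(ValueError):
            feature_dimension(n)


def _square_graph(side=10.0):
    g = SkeletonGraph()
    pos = [(0.0, 0.0), (0.0, side), (side, side), (side, 0.0)]
    for i, p in enumerate(pos):
        g.add_node(i, p)
    for i in range(4):
        g.add_edge(i, (i + 1) % 4)
    return g


class TestDescribeCycle:
    def test_unit_square_descriptor(self):
        g = _square_graph()
        (c,) = sdfs_cycles(g, 4)
        v = describe_cycle(c, g)
        assert v.shape == (24,)
        # 4 equal cycle-edge lengths, normalized
        assert np.allclose(v[:4], 0.25)
        # each degree-2 corner: two angular gaps of 90 and 270 degrees
        gaps = v[4:20].reshape(4, 4)
        for row in gaps:
            assert sorted(np.round(row, 6)) == [0.0, 0.0, 0.25, 0.75]
        # corner angles 90/360
        assert np.allclose(v[20:], 0.25)

    def test_lengths_normalized(self, phantom_artifacts):
        for vec, c in zip(
            phantom_artifacts.vectors, phantom_artifacts.structures
        ):
            assert vec.sum() >= 0
            assert np.isclose(vec[: c.n].sum(), 1.0)
            assert ((vec >= 0) & (vec <= 1)).all()
            assert vec.shape == (feature_dimension(c.n),)

    def test_hand_computed_right_triangle_with_branch(self):
        # 3-4-5 right triangle, one external branch at the right angle
        g = SkeletonGraph()
        g.add_node(0, (0.0, 0.0))
        g.add_node(1, (0.0, 4.0))
        g.add_node(2, (3.0, 0.0))
        g.add_node(3, (-5.0, 0.0))   # branch from node 0, straight "up"
        for u, v in [(0, 1), (1, 2), (2, 0), (0, 3)]:
            g.add_edge(u, v)
        pruned = prune_to_cycle_graph(g)
        (c,) = sdfs_cycles(pruned, 3)
        v = describe_cycle(c, g)
        assert v.shape == (18,)
        assert np.isclose(v[:3].sum(), 1.0)
        lengths = sorted(v[:3])
        assert np.allclose(lengths, np.array([3.0, 4.0, 5.0]) / 12.0)
        # corner angles of the 3-4-5 triangle: 90, atan(3/4)-complement
        corners = sorted(v[15:] * 360.0)
        expect = sorted(
            [90.0, math.degrees(math.atan2(4, 3)), math.degrees(math.atan2(3, 4))]
        )
        assert np.allclose(corners, expect, atol=1e-9)
        # the branch at node 0 splits its full angle into three gaps that
        # sum to 360 degrees; nodes of degree 2 have two gaps summing to 360
        gaps = v[3:15].reshape(3, 4) * 360.0
        for row in gaps:
            assert np.isclose(row.sum(), 360.0)
        assert sorted((gaps > 0).sum(axis=1)) == [2, 2, 3]


class TestMatching:
    def test_identical_sets_ms_zero(self, phantom_artifacts):
        res = match_structures(phantom_artifacts.vectors, phantom_artifacts.vectors)
        assert res.valid
        assert res.ms == 0.0

    def test_no_equal_size_pairs_flagged(self):
        a = [np.zeros(18)]
        b = [np.zeros(24)]
        res = match_structures(a, b)
        assert not res.valid
        assert res.ms is None

    def test_cityblock_metric(self):
        a = [np.zeros(18)]
        b = [np.full(18, 0.1)]
        res = match_structures(a, b, metric="cityblock")
        assert res.ms == pytest.approx(1.8)

    def test_rotation_scale_invariance_of_descriptors(self, phantom_artifacts):
        """Re-extracting after a 37-degree rotation and 2x scaling of the
        skeleton geometry reproduces every descriptor (ms ~ 0)."""
        a = math.radians(37.0)
        R = 2.0 * np.array(
            [[math.cos(a), math.sin(a)], [-math.sin(a), math.cos(a)]]
        )
        gT = phantom_artifacts.graph.transformed(
            linear=R, translation=np.array([11.0, -7.0])
        )
        pruned = prune_to_cycle_graph(gT)
        structs = sdfs_cycles(pruned, 6)
        vecs = [describe_cycle(c, gT) for c in structs]
        res = match_structures(phantom_artifacts.vectors, vecs)
        assert res.valid
        assert res.ms <= 1e-6
        # every original structure has an exact transformed counterpart
        for i in range(len(phantom_artifacts.vectors)):
            best = min(s for ii, _, s in res.pairs if ii == i)
            assert best <= 1e-6
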