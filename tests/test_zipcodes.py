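"""Zip codes and zip-tree distance traversal."""

import numpy as np
import pytest

from glite.distance import build_distance_index
from glite.graph import FORWARD, REVERSE, GraphPosition
from glite.seeds import SeedHit
from glite.snarls import decompose
from glite.zipcodes import (
    ChainLevel,
    LeafLevel,
    SnarlLevel,
    build_zip_forest,
    compute_zipcode,
    iter_seed_distances,
)

from conftest import make_sim_graph


def mk_seed(read_offset, node, orient, offset):
    pos = GraphPosition(node, orient, offset)
    return SeedHit(read_offset, "+", pos, pos, 0, 1)


@pytest.fixture
def g1_ctx(g1):
    tree = decompose(g1)
    return g1, tree, build_distance_index(g1, tree)


class TestZipCode:
    def test_bubble_allele_address(self, g1_ctx):
        g, tree, di = g1_ctx
        zc = compute_zipcode(GraphPosition(2, "+", 0), tree, di)
        chain_lvl, snarl_lvl, leaf_chain, leaf = zc.levels
        assert isinstance(chain_lvl, ChainLevel)
        assert chain_lvl.offset == 3 and chain_lvl.rank == 1  # after node 1
        assert isinstance(snarl_lvl, SnarlLevel)
        assert snarl_lvl.boundary_distances[:2] == (0, 0)
        assert isinstance(leaf, LeafLevel)
        assert leaf.node_id == 2 and leaf.length == 1 and leaf.offset == 0 and leaf.forward

    def test_top_level_node_has_depth_one_address(self, g1_ctx):
        g, tree, di = g1_ctx
        zc = compute_zipcode(GraphPosition(1, "+", 1), tree, di)
        assert len(zc.levels) == 2  # chain level + leaf
        assert isinstance(zc.levels[0], ChainLevel) and isinstance(zc.levels[1], LeafLevel)

    def test_same_node_positions_differ_only_in_leaf(self, g1_ctx):
        g, tree, di = g1_ctx
        a = compute_zipcode(GraphPosition(4, "+", 0), tree, di)
        b = compute_zipcode(GraphPosition(4, "+", 2), tree, di)
        assert a.levels[:-1] == b.levels[:-1]
        assert a.leaf.offset == 0 and b.leaf.offset == 2


class TestForest:
    def test_two_seeds_one_tree_distance(self, g1_ctx):
        g, tree, di = g1_ctx
        seeds = [mk_seed(0, 1, "+", 0), mk_seed(4, 4, "+", 0)]
        forest = build_zip_forest(seeds, tree, di)
        assert len(forest.trees) == 1
        t = forest.trees[0]
        ((s2, d),) = list(iter_seed_distances(t, t.seeds[0]))
        assert d == 4

    def test_single_seed_tree(self, g1_ctx):
        g, tree, di = g1_ctx
        forest = build_zip_forest([mk_seed(0, 2, "+", 0)], tree, di)
        t = forest.trees[0]
        assert len(t.seeds) == 1
        assert list(iter_seed_distances(t, t.seeds[0])) == []

    def test_sibling_alleles_unreachable_but_boundary_reachable(self, g1_ctx):
        g, tree, di = g1_ctx
        seeds = [mk_seed(0, 1, "+", 0), mk_seed(3, 2, "+", 0),
                 mk_seed(3, 3, "+", 0), mk_seed(4, 4, "+", 0)]
        forest = build_zip_forest(seeds, tree, di)
        t = forest.trees[0]
        by_node = {z.pos.node_id: z for z in t.seeds}
        from_boundary = dict(
            (s.pos.node_id, d) for s, d in iter_seed_distances(t, by_node[1])
        )
        assert from_boundary == {2: 3, 3: 3, 4: 4}
        from_allele = dict(
            (s.pos.node_id, d) for s, d in iter_seed_distances(t, by_node[2])
        )
        assert from_allele[3] is None and from_allele[4] == 1

    def test_every_seed_in_exactly_one_tree(self, g1_ctx):
        g, tree, di = g1_ctx
        rng = np.random.default_rng(0)
        seeds = []
        for i in range(30):
            n = int(rng.integers(1, 5))
            o = FORWARD if rng.random() < 0.5 else REVERSE
            off = int(rng.integers(g.node_length(n)))
            seeds.append(mk_seed(i, n, o, off))
        forest = build_zip_forest(seeds, tree, di)
        collected = [z.seed for t in forest.trees for z in t.seeds]
        assert len(collected) == len(seeds)
        assert {id(s) for s in collected} == {id(s) for s in seeds}

    def test_backward_iteration_mirrors_forward(self, g1_ctx):
        g, tree, di = g1_ctx
        seeds = [mk_seed(0, 1, "+", 0), mk_seed(4, 4, "+", 0)]
        t = build_zip_forest(seeds, tree, di).trees[0]
        ((s, d),) = list(iter_seed_distances(t, t.seeds[1], "backward"))
        assert s is t.seeds[0] and d == 4


def _random_seeds(g, rng, n, forward_only):
    nodes = sorted(g.nodes)
    seeds = []
    for i in range(n):
        node = nodes[int(rng.integers(len(nodes)))]
        o = FORWARD if (forward_only or rng.random() < 0.5) else REVERSE
        off = int(rng.integers(len(g.nodes[node])))
        seeds.append(mk_seed(i * 7, node, o, off))
    return seeds


class TestSoundness:
    @pytest.mark.parametrize("seed", range(8))
    def test_acyclic_distances_exact(self, seed):
        g = make_sim_graph(seed, backbone=400, inv=0.0, dup=0.0)
        tree = decompose(g)
        di = build_distance_index(g, tree)
        rng = np.random.default_rng(seed)
        seeds = _random_seeds(g, rng, 14, forward_only=True)
        forest = build_zip_forest(seeds, tree, di)
        for t in forest.trees:
            for z in t.seeds:
                for other, d in iter_seed_distances(t, z):
                    assert d == di.min_distance(z.pos, other.pos)

    @pytest.mark.parametrize("seed", range(8))
    def test_cyclic_inversion_distances_never_under_report(self, seed):
        g = make_sim_graph(seed + 100, backbone=400, inv=0.008, dup=0.008)
        tree = decompose(g)
        di = build_distance_index(g, tree)
        rng = np.random.default_rng(seed)
        seeds = _random_seeds(g, rng, 14, forward_only=False)
        forest = build_zip_forest(seeds, tree, di)
        for t in forest.trees:
            for z in t.seeds:
                for other, d in iter_seed_distances(t, z):
                    if d is None:
                        continue
                    true = di.min_distance(z.pos, other.pos)
                    assert true is not None and d >= true
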