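"""Snarl/chain decomposition against the exhaustive connectivity oracle."""

import pytest

from glite.graph import HaplotypeWalk, VariationGraph
from glite.snarls import decompose, is_separable

from conftest import make_sim_graph
from oracles import oracle_snarl_set, snarl_set_of_tree


def _nested_graph():
    """Insertion bubble whose inserted allele contains a SNP bubble."""
    g = VariationGraph()
    for nid, seq in [(1, "GGG"), (2, "AC"), (3, "T"), (4, "G"), (5, "CA"), (6, "TTT")]:
        g.add_node(nid, seq)
    g.add_walk(HaplotypeWalk("ref", [(1, "+"), (6, "+")]))
    g.add_walk(HaplotypeWalk("insA", [(1, "+"), (2, "+"), (3, "+"), (5, "+"), (6, "+")]))
    g.add_walk(HaplotypeWalk("insB", [(1, "+"), (2, "+"), (4, "+"), (5, "+"), (6, "+")]))
    return g


class TestSeparability:
    def test_bubble_boundaries(self, g1):
        ok, contents = is_separable(g1, (1, "R"), (4, "L"))
        assert ok and contents == {2, 3}

    def test_adjacent_pair_is_trivially_separable(self, g1):
        ok, contents = is_separable(g1, (1, "R"), (2, "L"))
        assert ok and contents == frozenset()

    def test_outward_facing_pair_is_not_separable(self, g1):
        ok, contents = is_separable(g1, (1, "L"), (4, "L"))
        assert not ok and contents is None

    def test_same_side_rejected(self, g1):
        with pytest.raises(ValueError):
            is_separable(g1, (1, "R"), (1, "R"))


class TestDecompose:
    def test_bubble_fixture_tree(self, g1):
        tree = decompose(g1)
        assert len(tree.root_chains) == 1
        chain = tree.root_chains[0]
        assert chain.node_ids() == [1, 4]
        (snarl,) = chain.snarl_items()
        assert snarl.start_side == (1, "R") and snarl.end_side == (4, "L")
        assert snarl.content_nodes == {2, 3}
        assert sorted(c.node_ids() for c in snarl.children) == [[2], [3]]
        assert not snarl.cyclic

    def test_single_node_graph(self):
        g = VariationGraph()
        g.add_node(1, "ACGT")
        g.add_walk(HaplotypeWalk("w", [(1, "+")]))
        tree = decompose(g)
        assert len(tree.root_chains) == 1
        assert tree.root_chains[0].node_ids() == [1]
        assert not tree.all_snarls()

    def test_nested_snarl_in_insertion(self):
        tree = decompose(_nested_graph())
        snarls = tree.all_snarls()
        assert len(snarls) == 2
        outer = tree.root_chains[0].snarl_items()[0]
        assert outer.content_nodes == {2, 3, 4, 5}
        inner = [s for c in outer.children for s in c.snarl_items()][0]
        assert inner.content_nodes == {3, 4}

    def test_duplication_back_edge_is_cyclic_snarl(self):
        g = VariationGraph()
        for nid, seq in [(1, "GATT"), (2, "ACGTA"), (3, "CCA")]:
            g.add_node(nid, seq)
        g.add_walk(HaplotypeWalk("ref", [(1, "+"), (2, "+"), (3, "+")]))
        g.add_walk(HaplotypeWalk("dup", [(1, "+"), (2, "+"), (2, "+"), (3, "+")]))
        tree = decompose(g)
        (snarl,) = tree.all_snarls()
        assert snarl.content_nodes == {2} and snarl.cyclic
        assert snarl.children[0].circular

    def test_inversion_snarl_not_cyclic(self):
        g = VariationGraph()
        for nid, seq in [(1, "GATT"), (2, "ACGTA"), (3, "CCA")]:
            g.add_node(nid, seq)
        g.add_walk(HaplotypeWalk("ref", [(1, "+"), (2, "+"), (3, "+")]))
        g.add_walk(HaplotypeWalk("inv", [(1, "+"), (2, "-"), (3, "+")]))
        tree = decompose(g)
        (snarl,) = tree.all_snarls()
        assert snarl.content_nodes == {2} and not snarl.cyclic

    def test_walk_free_component_rejected(self, g1):
        g1.add_node(99, "TTTT")
        g1.add_node(100, "AAAA")
        g1.add_edge((99, "R"), (100, "L"))
        with pytest.raises(ValueError, match="no walk"):
            decompose(g1)


class TestAncestry:
    def test_bubble_node_ancestry(self, g1):
        tree = decompose(g1)
        anc = tree.ancestry(2)
        assert len(anc) == 3
        assert anc[0].node_ids() == [2]
        assert anc[1].content_nodes == {2, 3}
        assert anc[2].node_ids() == [1, 4]

    def test_top_level_node_ancestry(self, g1):
        tree = decompose(g1)
        assert len(tree.ancestry(1)) == 1

    def test_nested_depth(self):
        tree = decompose(_nested_graph())
        assert len(tree.ancestry(3)) == 5

    def test_unknown_node(self, g1):
        tree = decompose(g1)
        with pytest.raises(KeyError):
            tree.ancestry(42)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_connectivity_oracle(self, seed):
        g = make_sim_graph(seed, backbone=350, inv=0.004, dup=0.004)
        tree = decompose(g)
        assert snarl_set_of_tree(tree) == oracle_snarl_set(g)
        assert tree.node_partition_ok()

    @pytest.mark.parametrize("seed", range(12))
    def test_chain_structure_invariants(self, seed):
        g = make_sim_graph(seed + 50, backbone=400, inv=0.004, dup=0.004)
        tree = decompose(g)
        assert tree.node_partition_ok()

        def check_chain(chain):
            # alternation: starts and ends with a node, snarls between
            kinds = [k for k, _ in chain.items]
            assert kinds[0] == "node" and kinds[-1] == "node"
            for a, b in zip(kinds, kinds[1:]):
                assert not (a == "snarl" and b == "snarl")
            # consecutive snarls share their boundary nodes with chain nodes
            for i, (kind, payload) in enumerate(chain.items):
                if kind == "snarl":
                    prev_node = chain.items[i - 1][1][0]
                    next_node = chain.items[i + 1][1][0]
                    assert set(payload.boundary_nodes) == {prev_node, next_node}
                    for child in payload.children:
                        check_chain(child)

        for chain in tree.root_chains:
            check_chain(chain)
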