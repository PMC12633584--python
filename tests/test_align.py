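"""Base-level aligners: WFA vs dense DP, graph DP vs path enumeration."""

import numpy as np
import pytest

from glite.align import (
    HaplotypeCoords,
    ScoringParams,
    banded_graph_global,
    extend_chain,
    score_edits,
    wfa_align,
    xdrop_tail,
)
from glite.chaining import ChainingParams, chain_forest
from glite.distance import build_distance_index
from glite.graph import GraphPosition, HaplotypeWalk, VariationGraph, reverse_complement
from glite.seeds import MinimizerParams, build_minimizer_index, find_seeds
from glite.snarls import decompose
from glite.zipcodes import build_zip_forest

from conftest import make_sim_graph
from oracles import best_path_alignment, gotoh_global

SP = ScoringParams()
BASES = "ACGT"


def _mutate(s, rate, rng):
    out = []
    for ch in s:
        r = rng.random()
        if r < rate / 3:
            continue
        if r < 2 * rate / 3:
            out.append(BASES[rng.integers(4)])
        else:
            out.append(ch)
        if rng.random() < rate / 3:
            out.append(BASES[rng.integers(4)])
    return "".join(out) or "A"


class TestWFA:
    def test_identity(self):
        res = wfa_align("ACGT", "ACGT", SP)
        assert res.ok and res.score == 4 and res.edits == [("=", 4)]

    def test_single_substitution(self):
        res = wfa_align("ACGT", "AGGT", SP)
        assert res.score == 3 * 1 - 4 == -1
        assert res.edits == [("=", 1), ("X", 1), ("=", 2)]

    def test_empty_query_is_deletion(self):
        res = wfa_align("", "ACG", SP)
        assert res.edits == [("D", 3)] and res.score == -6 - 3

    @pytest.mark.parametrize("batch", range(4))
    def test_matches_dense_gotoh(self, batch):
        rng = np.random.default_rng(batch)
        for _ in range(40):
            L = int(rng.integers(4, 160))
            t = "".join(BASES[i] for i in rng.integers(0, 4, L))
            q = _mutate(t, 0.15, rng)
            res = wfa_align(q, t, SP)
            assert res.ok
            exp = gotoh_global(q, t, SP.match, SP.mismatch, SP.gap_open, SP.gap_extend)
            assert res.score == exp
            assert score_edits(res.edits, SP) == res.score

    def test_cost_budget_failure_is_declared(self):
        rng = np.random.default_rng(1)
        q = "".join(BASES[i] for i in rng.integers(0, 4, 400))
        t = "".join(BASES[i] for i in rng.integers(0, 4, 400))
        res = wfa_align(q, t, SP, max_cost=30)
        assert not res.ok  # failure, not an exception

    def test_anchored_prefix_stops_at_divergence(self):
        q = "ACGTACGT" + "TTTTTTTT"
        t = "ACGTACGT" + "CCCCCCCC"
        res = wfa_align(q, t, SP, mode="anchored_prefix")
        assert res.ok and res.score == 8 and res.query_end == 8


class TestBandedGraph:
    def test_bubble_allele_a(self, g1):
        path, edits, score = banded_graph_global(
            "ATAT", g1, GraphPosition(1, "+", 1), GraphPosition(4, "+", 1), SP
        )
        assert edits == [("=", 4)] and score == 4
        assert [p.node_id for p in path] == [1, 1, 2, 4]

    def test_bubble_allele_c(self, g1):
        path, edits, score = banded_graph_global(
            "TCTA", g1, GraphPosition(1, "+", 2), GraphPosition(4, "+", 2), SP
        )
        assert edits == [("=", 4)]
        assert 3 in {p.node_id for p in path}

    def test_empty_interval_is_pure_insertion(self, g1):
        path, edits, score = banded_graph_global(
            "GG", g1, GraphPosition(2, "+", 0), GraphPosition(2, "+", 0), SP
        )
        assert path == [] and edits == [("I", 2)]

    def test_unreachable_endpoints_raise(self, g1):
        with pytest.raises(ValueError):
            banded_graph_global(
                "A", g1, GraphPosition(4, "+", 2), GraphPosition(1, "+", 0), SP
            )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_path_enumeration_oracle(self, seed):
        # small acyclic bubble graphs; align across a few bubbles
        g = make_sim_graph(seed, backbone=60, snv=0.05, indel=0.03, max_indel=6)
        rng = np.random.default_rng(seed)
        walk = g.walks[int(rng.integers(len(g.walks)))]
        spelled = g.spell_walk(walk)
        if len(spelled) < 20:
            pytest.skip("fixture too small")
        a, b = 2, min(len(spelled) - 2, 2 + 25)
        # positions of offsets a and b on the walk
        from glite.seeds import _WalkCoords

        coords = _WalkCoords(g, walk)
        p_a, p_b = coords.position(a), coords.position(b)
        query = _mutate(spelled[a:b], 0.1, rng)
        path, edits, score = banded_graph_global(query, g, p_a, p_b, SP, band=12)
        exp = best_path_alignment(
            g, query,
            (p_a.node_id, p_a.orientation, p_a.offset),
            (p_b.node_id, p_b.orientation, p_b.offset),
            SP, max_len=(b - a) + 14,
        )
        assert score == exp
        assert score_edits(edits, SP) == score


class TestXDrop:
    def test_exact_continuation_extends_fully(self, g1):
        path, edits, score, used = xdrop_tail("TACA", g1, GraphPosition(2, "+", 0), SP)
        assert edits == [("=", 4)] and used == 4 and score == 4

    def test_garbage_tail_clipped(self, g1):
        path, edits, score, used = xdrop_tail("GGGGGGGG", g1, GraphPosition(2, "+", 0), SP)
        assert used <= 1 and score <= 1

    def test_net_loss_mismatch_stops_extension(self, g1):
        # graph continues TACA; tail TGCA: crossing the mismatch never pays,
        # so the local optimum keeps only the leading match
        path, edits, score, used = xdrop_tail("TGCA", g1, GraphPosition(2, "+", 0), SP)
        assert used == 1 and score == 1

    def test_worthwhile_mismatch_is_crossed(self):
        g = VariationGraph()
        g.add_node(1, "GATTACAGGGGGGGG")
        g.add_walk(HaplotypeWalk("w", [(1, "+")]))
        tail = "TACAGCGGGGGG"  # one error six bases in, long match beyond
        path, edits, score, used = xdrop_tail(tail, g, GraphPosition(1, "+", 2), SP)
        assert used == len(tail)
        assert score == (len(tail) - 1) * SP.match + SP.mismatch


class TestExtendChain:
    def _map_chain(self, g, read, k=3, w=2):
        tree = decompose(g)
        di = build_distance_index(g, tree)
        p = MinimizerParams(k=k, w=w)
        idx = build_minimizer_index(g, p)
        seeds = find_seeds(idx, read, p)
        forest = build_zip_forest(seeds, tree, di)
        chains, _ = chain_forest(forest, k, ChainingParams())
        coords = HaplotypeCoords(g)
        return extend_chain(chains[0], g, coords, SP, k=k, read=read, read_name="r")

    def test_error_free_haplotype_read(self, g1):
        aln = self._map_chain(g1, "GATATACA")
        assert aln.path == [(1, "+"), (2, "+"), (4, "+")]
        assert aln.edits == [("=", 8)] and aln.score == 8
        aln.check_invariants(g1)

    def test_one_interior_mismatch_in_node_4(self, g1):
        read = "GATAGACA"  # node 4's first base T -> G, flanked by seeds
        aln = self._map_chain(g1, read, w=1)
        assert aln.path == [(1, "+"), (2, "+"), (4, "+")]
        assert aln.score == 7 * SP.match + SP.mismatch
        assert ("X", 1) in aln.edits
        aln.check_invariants(g1)

    def test_recombinant_read_picks_best_alleles(self):
        # two SNP sites; the read takes ref at site 1 and alt at site 2 --
        # a haplotype combination absent from the walks
        g = VariationGraph()
        for nid, seq in [(1, "GGATC"), (2, "A"), (3, "C"), (4, "TTAGG"),
                         (5, "G"), (6, "T"), (7, "CCATA")]:
            g.add_node(nid, seq)
        g.add_walk(HaplotypeWalk("h1", [(1, "+"), (2, "+"), (4, "+"), (5, "+"), (7, "+")]))
        g.add_walk(HaplotypeWalk("h2", [(1, "+"), (3, "+"), (4, "+"), (6, "+"), (7, "+")]))
        read = "GGATC" + "A" + "TTAGG" + "T" + "CCATA"
        aln = self._map_chain(g, read, k=4, w=2)
        assert aln.score == len(read) * SP.match
        assert aln.edits == [("=", len(read))]
        path_nodes = [n for n, _ in aln.path]
        assert 2 in path_nodes and 6 in path_nodes
        aln.check_invariants(g)

    def test_reverse_strand_read(self, g1):
        aln = self._map_chain(g1, reverse_complement("GATCTACA"))
        assert aln.score == 8
        assert aln.path == [(4, "-"), (3, "-"), (1, "-")]
        aln.check_invariants(g1)

    @pytest.mark.parametrize("seed", range(4))
    def test_score_consistency_on_noisy_reads(self, seed):
        g = make_sim_graph(seed, backbone=800, n_hap=4)
        from glite.sim import ReadSimParams, simulate_reads

        reads, _ = simulate_reads(
            g,
            ReadSimParams(n_reads=4, mean_length=250, sd_length=20, min_length=100,
                          mismatch_rate=0.02, insertion_rate=0.01,
                          deletion_rate=0.01, seed=seed),
        )
        tree = decompose(g)
        di = build_distance_index(g, tree)
        p = MinimizerParams(k=13, w=5)
        idx = build_minimizer_index(g, p)
        coords = HaplotypeCoords(g)
        for name, seq in reads:
            seeds = find_seeds(idx, seq, p)
            if not seeds:
                continue
            forest = build_zip_forest(seeds, tree, di)
            chains, _ = chain_forest(forest, 13, ChainingParams())
            if not chains:
                continue
            aln = extend_chain(chains[0], g, coords, SP, k=13, read=seq, read_name=name)
            aln.check_invariants(g)
            assert score_edits(aln.edits, SP) == aln.score
            # read accounting: clipped + aligned = read length
            clipped = aln.read_start + (aln.read_length - aln.read_end)
            aligned = sum(ln for op, ln in aln.edits if op in "=XI")
            assert clipped + aligned == aln.read_length
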