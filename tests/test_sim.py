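"""Synthetic pangenome generator, read simulator and evaluator."""

import io

import numpy as np
import pandas as pd
import pytest

from glite.graph import parse_gfa, gfa_to_string
from glite.sim import (
    GraphSimParams,
    ReadSimParams,
    evaluate_mapping,
    simulate_graph,
    simulate_reads,
)
from glite.snarls import decompose


class TestSimulateGraph:
    def test_zero_rates_gives_single_node(self):
        g = simulate_graph(GraphSimParams(backbone_length=500, n_haplotypes=3,
                                          snv_bubble_rate=0, indel_bubble_rate=0,
                                          inversion_rate=0, tandem_duplication_rate=0,
                                          seed=1))
        assert len(g.nodes) == 1 and len(g.walks) == 3
        spells = {g.spell_walk(w) for w in g.walks}
        assert len(spells) == 1

    def test_snv_only_gives_two_allele_substitution_bubbles(self):
        g = simulate_graph(GraphSimParams(backbone_length=800, n_haplotypes=4,
                                          snv_bubble_rate=0.02, indel_bubble_rate=0,
                                          inversion_rate=0, tandem_duplication_rate=0,
                                          seed=2))
        tree = decompose(g)
        snarls = tree.all_snarls()
        assert snarls
        for s in snarls:
            assert len(s.children) == 2
            for c in s.children:
                ids = c.node_ids()
                assert len(ids) == 1 and g.node_length(ids[0]) == 1

    def test_fixed_seed_reproduces_gfa_bytes(self):
        p = GraphSimParams(backbone_length=700, n_haplotypes=4, seed=9)
        a = gfa_to_string(simulate_graph(p))
        b = gfa_to_string(simulate_graph(p))
        assert a == b

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_graph(GraphSimParams(snv_bubble_rate=1.5))

    def test_decompose_succeeds_on_generated_graphs(self):
        for seed in range(4):
            g = simulate_graph(GraphSimParams(backbone_length=600, n_haplotypes=4,
                                              snv_bubble_rate=0.01,
                                              indel_bubble_rate=0.005,
                                              inversion_rate=0.003,
                                              tandem_duplication_rate=0.003,
                                              seed=seed))
            assert decompose(g).node_partition_ok()


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self):
        g = simulate_graph(GraphSimParams(backbone_length=2000, n_haplotypes=3, seed=3))
        reads, truth = simulate_reads(
            g, ReadSimParams(n_reads=20, mean_length=300, sd_length=30,
                             min_length=100, seed=3)
        )
        spells = {w.name: g.spell_walk(w) for w in g.walks}
        from glite.graph import reverse_complement

        for (name, seq), row in zip(reads, truth.to_dict("records")):
            frag = spells[row["haplotype"]][row["start"]:row["end"]]
            if row["strand"] == "-":
                frag = reverse_complement(frag)
            assert seq == frag

    def test_error_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            ReadSimParams(deletion_rate=1.0).validate()

    def test_error_counts_near_binomial_expectation(self):
        g = simulate_graph(GraphSimParams(backbone_length=4000, n_haplotypes=2,
                                          snv_bubble_rate=0, indel_bubble_rate=0,
                                          inversion_rate=0, tandem_duplication_rate=0,
                                          seed=4))
        rate = 0.05
        reads, truth = simulate_reads(
            g, ReadSimParams(n_reads=300, mean_length=500, sd_length=0,
                             min_length=100, mismatch_rate=rate, seed=4)
        )
        spells = {w.name: g.spell_walk(w) for w in g.walks}
        mismatches = 0
        total = 0
        from glite.graph import reverse_complement

        for (name, seq), row in zip(reads, truth.to_dict("records")):
            frag = spells[row["haplotype"]][row["start"]:row["end"]]
            if row["strand"] == "-":
                frag = reverse_complement(frag)
            assert len(seq) == len(frag)  # substitutions only
            mismatches += sum(a != b for a, b in zip(seq, frag))
            total += len(frag)
        # within 3 sigma of Binomial(total, rate); substitutions draw a
        # different base, so the observed rate is the full mismatch rate
        sigma = np.sqrt(total * rate * (1 - rate))
        assert abs(mismatches - total * rate) < 3 * sigma


class TestEvaluate:
    def _perfect_gaf(self, g, truth):
        walks = {w.name: w for w in g.walks}
        lines = []
        for row in truth.to_dict("records"):
            w = walks[row["haplotype"]]
            # exact node interval of the truth slice
            off = 0
            runs = []
            first_node_off = None
            for n, o in w.steps:
                ln = g.node_length(n)
                lo, hi = max(off, row["start"]), min(off + ln, row["end"])
                if hi > lo:
                    if first_node_off is None:
                        first_node_off = off
                    runs.append((n, o))
                off += ln
            path = "".join((">" if o == "+" else "<") + g.name_of[n] for n, o in runs)
            plen = sum(g.node_length(n) for n, _ in runs)
            span = row["end"] - row["start"]
            pstart = row["start"] - first_node_off
            lines.append(
                "\t".join(
                    [row["name"], str(span), "0", str(span), "+", path,
                     str(plen), str(pstart), str(pstart + span), str(span),
                     str(span), "60"]
                )
            )
        return lines

    def test_perfect_mapping_is_all_correct(self):
        g = simulate_graph(GraphSimParams(backbone_length=1500, n_haplotypes=3, seed=6))
        reads, truth = simulate_reads(
            g, ReadSimParams(n_reads=15, mean_length=200, sd_length=10,
                             min_length=100, seed=6)
        )
        table = evaluate_mapping(self._perfect_gaf(g, truth), truth, g)
        row60 = table[table.mapq == 60].iloc[0]
        assert row60["correct"] == 15 and row60["incorrect"] == 0
        assert row60["cum_precision"] == 1.0

    def test_shifted_alignments_are_incorrect(self):
        g = simulate_graph(GraphSimParams(backbone_length=3000, n_haplotypes=2, seed=7))
        reads, truth = simulate_reads(
            g, ReadSimParams(n_reads=10, mean_length=200, sd_length=0,
                             min_length=100, seed=7)
        )
        # deliberately report a far-away interval for every read
        shifted = truth.copy()
        shifted["start"] = (shifted["start"] + 1000) % 1500
        shifted["end"] = shifted["start"] + 200
        lines = self._perfect_gaf(g, shifted)
        table = evaluate_mapping(lines, truth, g)
        row60 = table[table.mapq == 60].iloc[0]
        assert row60["correct"] == 0 and row60["incorrect"] == 10

    def test_read_missing_from_truth_errors(self):
        g = simulate_graph(GraphSimParams(backbone_length=1000, n_haplotypes=2, seed=8))
        reads, truth = simulate_reads(
            g, ReadSimParams(n_reads=3, mean_length=200, sd_length=0,
                             min_length=100, seed=8)
        )
        lines = self._perfect_gaf(g, truth)
        with pytest.raises(KeyError):
            evaluate_mapping(lines, truth[truth.name != "read0"], g)

    def test_unmapped_reads_get_their_own_row(self):
        g = simulate_graph(GraphSimParams(backbone_length=1000, n_haplotypes=2, seed=9))
        reads, truth = simulate_reads(
            g, ReadSimParams(n_reads=5, mean_length=200, sd_length=0,
                             min_length=100, seed=9)
        )
        lines = self._perfect_gaf(g, truth)[:3]  # two reads missing
        table = evaluate_mapping(lines, truth, g)
        unmapped = table[table.mapq == "unmapped"]
        assert int(unmapped.iloc[0]["n"]) == 2
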