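"""Synthetic pangenomes, simulated reads and mapping evaluation.

The generator emulates the graph features a long-read pangenome mapper has
to cope with: SNV and indel bubbles, inversions (a node traversed in
reverse by some haplotypes) and tandem duplications (a node traversed twice,
creating a back edge and hence a cycle).  Haplotype walks are generated
first and the graph is built from them, so the edge set is exactly the set
of walk-supported adjacencies.

Reads are sampled uniformly from haplotype spellings on both strands with
i.i.d. per-base mismatch/insertion/deletion errors, and each read carries a
ground-truth record locating its error-free origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import (
    FORWARD,
    REVERSE,
    HaplotypeWalk,
    VariationGraph,
    reverse_complement,
)

__all__ = [
    "GraphSimParams",
    "ReadSimParams",
    "simulate_graph",
    "simulate_reads",
    "evaluate_mapping",
]

_BASES = "ACGT"


@dataclass
class GraphSimParams:
    """Knobs of the pangenome generator.

    Rates are per backbone base, i.e. the expected number of variant sites
    of a given class is rate x backbone_length.  Defaults give a human-like
    density of heterozygous sites across a small haplotype panel.
    """

    backbone_length: int = 20_000
    n_haplotypes: int = 8
    snv_bubble_rate: float = 0.004
    indel_bubble_rate: float = 0.0008
    inversion_rate: float = 0.0001
    tandem_duplication_rate: float = 0.0001
    max_indel_length: int = 50
    seed: int = 0

    def validate(self) -> None:
        for name in ("snv_bubble_rate", "indel_bubble_rate", "inversion_rate",
                     "tandem_duplication_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if self.backbone_length < 1 or self.n_haplotypes < 1:
            raise ValueError("backbone_length and n_haplotypes must be positive")


@dataclass
class ReadSimParams:
    n_reads: int = 1000
    mean_length: int = 1000
    sd_length: int = 100
    min_length: int = 100
    mismatch_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("mismatch_rate", "insertion_rate", "deletion_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 0.3:
                raise ValueError(f"{name} must be in [0, 0.3], got {r}")
        if self.min_length < 1 or self.mean_length < self.min_length:
            raise ValueError("bad read length configuration")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def simulate_graph(params: GraphSimParams) -> VariationGraph:
    """Generate a variation graph realizing the requested variant bubbles.

    Haplotype 0 always takes the reference allele at every site and is
    emitted with role "reference"; every alternate allele is guaranteed to
    be used by at least one haplotype so no node is walk-free.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    L = params.backbone_length
    backbone = _random_seq(rng, L)

    # Draw non-overlapping variant sites left to right, >= 1 backbone base
    # between consecutive sites so every bubble has distinct flanking nodes.
    kinds = ["snv", "indel", "inversion", "dup"]
    rates = np.array([
        params.snv_bubble_rate,
        params.indel_bubble_rate,
        params.inversion_rate,
        params.tandem_duplication_rate,
    ])
    total_rate = float(rates.sum())
    sites: list[dict] = []
    if total_rate > 0 and params.n_haplotypes > 1:
        pos = 1
        while pos < L - 1:
            # geometric waiting time between site starts
            gap = int(rng.geometric(min(total_rate, 0.5)))
            pos += gap
            if pos >= L - 1:
                break
            kind = kinds[int(rng.choice(4, p=rates / total_rate))]
            if kind == "snv":
                span = 1
            elif kind == "indel":
                span = 0 if rng.random() < 0.5 else int(rng.integers(1, params.max_indel_length + 1))
            elif kind == "inversion":
                span = int(rng.integers(3, params.max_indel_length + 1))
            else:  # dup
                span = int(rng.integers(5, params.max_indel_length + 1))
            if pos + span >= L:  # keep a trailing backbone chunk
                break
            site = {"kind": kind, "start": pos, "end": pos + span}
            if kind == "snv":
                ref_base = backbone[pos]
                site["alt_seq"] = _BASES[(_BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
            elif kind == "indel" and span == 0:
                site["alt_seq"] = _random_seq(rng, int(rng.integers(1, params.max_indel_length + 1)))
                site["indel_kind"] = "insertion"
            elif kind == "indel":
                site["indel_kind"] = "deletion"
            sites.append(site)
            pos = site["end"] + 1

    graph = VariationGraph()
    next_id = 1

    def new_node(seq: str) -> int:
        nonlocal next_id
        nid = next_id
        graph.add_node(nid, seq)
        next_id += 1
        return nid

    # Allele choice per haplotype per site: 0 = reference, 1 = alternate.
    n_hap = params.n_haplotypes
    alleles = np.zeros((n_hap, len(sites)), dtype=int)
    if n_hap > 1 and sites:
        alleles[1:, :] = rng.integers(0, 2, size=(n_hap - 1, len(sites)))
        for j in range(len(sites)):  # force every alt allele to be realized
            if alleles[1:, j].sum() == 0:
                alleles[1 + int(rng.integers(0, n_hap - 1)), j] = 1

    # Lay out nodes left to right and collect per-haplotype steps.
    hap_steps: list[list[tuple[int, str]]] = [[] for _ in range(n_hap)]

    def emit_all(node_id: int) -> None:
        for steps in hap_steps:
            steps.append((node_id, FORWARD))

    cursor = 0
    for j, site in enumerate(sites):
        if site["start"] > cursor:
            emit_all(new_node(backbone[cursor : site["start"]]))
        kind = site["kind"]
        if kind == "snv":
            ref_node = new_node(backbone[site["start"] : site["end"]])
            alt_node = new_node(site["alt_seq"])
            for h in range(n_hap):
                hap_steps[h].append((alt_node if alleles[h, j] else ref_node, FORWARD))
        elif kind == "indel" and site.get("indel_kind") == "insertion":
            ins_node = new_node(site["alt_seq"])
            for h in range(n_hap):
                if alleles[h, j]:
                    hap_steps[h].append((ins_node, FORWARD))
        elif kind == "indel":  # deletion bubble: alt haplotypes skip the node
            ref_node = new_node(backbone[site["start"] : site["end"]])
            for h in range(n_hap):
                if not alleles[h, j]:
                    hap_steps[h].append((ref_node, FORWARD))
        elif kind == "inversion":
            node = new_node(backbone[site["start"] : site["end"]])
            for h in range(n_hap):
                hap_steps[h].append((node, REVERSE if alleles[h, j] else FORWARD))
        else:  # tandem duplication: alt haplotypes traverse the node twice
            node = new_node(backbone[site["start"] : site["end"]])
            for h in range(n_hap):
                hap_steps[h].append((node, FORWARD))
                if alleles[h, j]:
                    hap_steps[h].append((node, FORWARD))
        cursor = site["end"]
    if cursor < L or next_id == 1:
        emit_all(new_node(backbone[cursor:] if cursor < L else backbone))

    for h in range(n_hap):
        role = "reference" if h == 0 else "haplotype"
        graph.add_walk(HaplotypeWalk(f"H{h}", hap_steps[h], role=role))
    graph.validate()
    return graph


def _apply_errors(seq: str, params: ReadSimParams, rng: np.random.Generator) -> str:
    p_mis, p_ins, p_del = params.mismatch_rate, params.insertion_rate, params.deletion_rate
    if p_mis == p_ins == p_del == 0.0:
        return seq
    out = []
    for base in seq:
        r = rng.random()
        if r < p_del:
            continue
        if r < p_del + p_mis:
            base = _BASES[(_BASES.index(base) + int(rng.integers(1, 4))) % 4]
        out.append(base)
        if rng.random() < p_ins:
            out.append(_BASES[int(rng.integers(0, 4))])
    return "".join(out) if out else seq[:1]


def simulate_reads(
    graph: VariationGraph, params: ReadSimParams
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sample reads from haplotype spellings.

    Returns ``(reads, truth)`` where reads is a list of (name, sequence) and
    truth is a table with one row per read: source haplotype, strand and the
    half-open interval of the error-free read on the haplotype spelling.
    """
    params.validate()
    if not graph.walks:
        raise ValueError("graph has no walks to sample reads from")
    rng = np.random.default_rng(params.seed)
    spellings = [(w.name, graph.spell_walk(w)) for w in graph.walks]
    usable = [(n, s) for n, s in spellings if len(s) >= params.min_length]
    if not usable:
        raise ValueError("all haplotypes are shorter than min_length")
    reads: list[tuple[str, str]] = []
    rows = []
    for i in range(params.n_reads):
        while True:
            name, spelling = usable[int(rng.integers(0, len(usable)))]
            length = int(rng.normal(params.mean_length, params.sd_length))
            length = max(params.min_length, length)
            if length <= len(spelling):
                break
        start = int(rng.integers(0, len(spelling) - length + 1))
        fragment = spelling[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = reverse_complement(fragment)
        read_seq = _apply_errors(fragment, params, rng)
        read_name = f"read{i}"
        reads.append((read_name, read_seq))
        rows.append(
            {
                "name": read_name,
                "haplotype": name,
                "strand": strand,
                "start": start,
                "end": start + length,
            }
        )
    return reads, pd.DataFrame(rows)


def write_fastq(reads: list[tuple[str, str]], stream) -> None:
    for name, seq in reads:
        stream.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def _walk_footprint(
    graph: VariationGraph, walk: HaplotypeWalk, start: int, end: int
) -> dict[int, list[tuple[int, int]]]:
    """Node -> base intervals of [start, end), in forward node coordinates."""
    fp: dict[int, list[tuple[int, int]]] = {}
    off = 0
    for node_id, orient in walk.steps:
        ln = graph.node_length(node_id)
        lo, hi = max(off, start), min(off + ln, end)
        if hi > lo:
            a, b = lo - off, hi - off
            if orient == REVERSE:
                a, b = ln - b, ln - a
            fp.setdefault(node_id, []).append((a, b))
        off += ln
        if off >= end:
            break
    return fp


def _gaf_footprint(
    graph: VariationGraph, path: list[tuple[int, str]], pstart: int, pend: int
) -> dict[int, list[tuple[int, int]]]:
    fp: dict[int, list[tuple[int, int]]] = {}
    off = 0
    for node_id, orient in path:
        ln = graph.node_length(node_id)
        lo, hi = max(off, pstart), min(off + ln, pend)
        if hi > lo:
            a, b = lo - off, hi - off
            if orient == REVERSE:
                a, b = ln - b, ln - a
            fp.setdefault(node_id, []).append((a, b))
        off += ln
    return fp


def _footprint_overlap(rep, truth) -> int:
    shared = 0
    for node, intervals in rep.items():
        for a, b in intervals:
            for c, d in truth.get(node, []):
                shared += max(0, min(b, d) - max(a, c))
    return shared


def parse_gaf_path(path_str: str, name_to_id: dict[str, int]) -> list[tuple[int, str]]:
    steps = []
    i = 0
    while i < len(path_str):
        mark = path_str[i]
        j = i + 1
        while j < len(path_str) and path_str[j] not in "><":
            j += 1
        steps.append((name_to_id[path_str[i + 1 : j]], FORWARD if mark == ">" else REVERSE))
        i = j
    return steps


def evaluate_mapping(gaf_lines, truth: pd.DataFrame, graph: VariationGraph) -> pd.DataFrame:
    """Adjudicate mapped reads against truth and stratify by MAPQ.

    A read is judged correct when at least 50% of the node-bases of its
    reported walk interval fall on node-bases of the true source slice
    (orientation ignored, so inverted segments still count).  Returns a
    table with one row per MAPQ value present plus an "unmapped" row, and
    cumulative precision for reads at or above each MAPQ.
    """
    truth_by_name = {r["name"]: r for r in truth.to_dict("records")}
    walks = {w.name: w for w in graph.walks}
    name_to_id = {v: k for k, v in graph.name_of.items()}
    records = []
    seen = set()
    for line in gaf_lines:
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        name = f[0]
        if name not in truth_by_name:
            raise KeyError(f"GAF read {name!r} missing from truth table")
        seen.add(name)
        mapq = int(f[11])
        path = parse_gaf_path(f[5], name_to_id)
        pstart, pend = int(f[7]), int(f[8])
        t = truth_by_name[name]
        truth_fp = _walk_footprint(graph, walks[t["haplotype"]], t["start"], t["end"])
        rep_fp = _gaf_footprint(graph, path, pstart, pend)
        rep_total = sum(b - a for iv in rep_fp.values() for a, b in iv)
        shared = _footprint_overlap(rep_fp, truth_fp)
        correct = rep_total > 0 and shared >= 0.5 * rep_total
        records.append({"name": name, "mapq": mapq, "correct": correct})
    for name in truth_by_name:
        if name not in seen:
            records.append({"name": name, "mapq": -1, "correct": False})
    df = pd.DataFrame(records)
    rows = []
    mapped = df[df.mapq >= 0]
    for q in sorted(df.mapq.unique()):
        sub = df[df.mapq == q]
        at_or_above = mapped[mapped.mapq >= q]
        n_corr = int(at_or_above.correct.sum())
        rows.append(
            {
                "mapq": q if q >= 0 else "unmapped",
                "n": len(sub),
                "correct": int(sub.correct.sum()),
                "incorrect": int((~sub.correct).sum()),
                "cum_precision": (n_corr / len(at_or_above)) if q >= 0 and len(at_or_above) else math.nan,
            }
        )
    return pd.DataFrame(rows)
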