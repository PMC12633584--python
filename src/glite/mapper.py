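"""End-to-end read mapping: seed, chain, extend, score, emit GAF.

The pipeline per read is deterministic: find weighted-minimizer seeds,
arrange them in a zip code forest, chain each tree by dynamic programming,
extend the best chains to base level, rank by alignment score and assign a
mapping quality.  MAPQ is a Phred-style gap to the best competitor,
``clamp(0, 60, round(6 * (primary - best_secondary) / match))``, with the
cap of 60 and a score-tie mapping to 0; reads with no seeds or no finite
alignment are reported unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import (
    GraphAlignment,
    HaplotypeCoords,
    ScoringParams,
    extend_chain,
)
from .chaining import ChainingParams, chain_forest
from .distance import DistanceIndex, build_distance_index
from .graph import FORWARD, VariationGraph
from .seeds import MinimizerIndex, MinimizerParams, build_minimizer_index, find_seeds
from .snarls import SnarlTree, decompose
from .zipcodes import build_zip_forest

__all__ = [
    "MapperIndexes",
    "MappingResult",
    "build_indexes",
    "map_read",
    "compute_mapq",
    "write_gaf",
    "cs_tag",
]

MAPQ_CAP = 60


@dataclass
class MapperIndexes:
    graph: VariationGraph
    snarl_tree: SnarlTree
    distance_index: DistanceIndex
    minimizer_index: MinimizerIndex
    coords: HaplotypeCoords
    minimizer_params: MinimizerParams


def build_indexes(
    graph: VariationGraph,
    minimizer_params: MinimizerParams | None = None,
    precompute_distances: bool = True,
) -> MapperIndexes:
    params = minimizer_params or MinimizerParams()
    tree = decompose(graph)
    dindex = build_distance_index(graph, tree)
    if precompute_distances:
        dindex.precompute_all()
    mindex = build_minimizer_index(graph, params)
    coords = HaplotypeCoords(graph)
    return MapperIndexes(graph, tree, dindex, mindex, coords, params)


@dataclass
class MappingResult:
    read_name: str
    primary: GraphAlignment | None
    secondaries: list[GraphAlignment] = field(default_factory=list)
    mapq: int = 0
    unmapped: bool = False
    ambiguous: bool = False
    n_seeds: int = 0
    n_chains: int = 0


def compute_mapq(
    primary_score: float,
    secondary_scores: list[float],
    match_score: int = 1,
    fallback_competitor: float = 0.0,
) -> int:
    """Phred-style confidence from the score margin over the best competitor.

    ``fallback_competitor`` carries the chain score of the best unreported
    alternative placement, so it competes alongside any extended secondary
    alignments (0 when the read has no competitor at all)."""
    best_secondary = max(secondary_scores, default=0.0)
    best_secondary = max(best_secondary, fallback_competitor)
    if primary_score < best_secondary:
        raise ValueError("primary score must be >= secondary scores")
    raw = round(6.0 * (primary_score - best_secondary) / match_score)
    return max(0, min(MAPQ_CAP, raw))


def _placement_overlap(a: GraphAlignment, b: GraphAlignment) -> float:
    """Shared node-base fraction of the smaller of two walk placements."""

    def footprint(aln):
        fp: dict[int, list[tuple[int, int]]] = {}
        for n, _, lo, hi in aln.runs:
            fp.setdefault(n, []).append((lo, hi))
        return fp

    fa, fb = footprint(a), footprint(b)
    shared = 0
    for n, ivs in fa.items():
        for lo, hi in ivs:
            for lo2, hi2 in fb.get(n, []):
                shared += max(0, min(hi, hi2) - max(lo, lo2))
    size_a = sum(hi - lo for _, _, lo, hi in a.runs)
    size_b = sum(hi - lo for _, _, lo, hi in b.runs)
    denom = min(size_a, size_b)
    return shared / denom if denom else 0.0


def map_read(
    read_name: str,
    read: str,
    indexes: MapperIndexes,
    chaining_params: ChainingParams | None = None,
    scoring: ScoringParams | None = None,
) -> MappingResult:
    chaining_params = chaining_params or ChainingParams()
    scoring = scoring or ScoringParams()
    k = indexes.minimizer_params.k
    seeds = find_seeds(indexes.minimizer_index, read, indexes.minimizer_params)
    if not seeds:
        return MappingResult(read_name, None, unmapped=True)
    forest = build_zip_forest(seeds, indexes.snarl_tree, indexes.distance_index)
    chains, chain_competitor = chain_forest(forest, k, chaining_params)
    if not chains:
        return MappingResult(read_name, None, unmapped=True, n_seeds=len(seeds))
    alignments: list[GraphAlignment] = []
    chain_score_of: dict[int, float] = {}
    for chain in chains:
        try:
            aln = extend_chain(
                chain,
                indexes.graph,
                indexes.coords,
                scoring,
                k=k,
                read=read,
                read_name=read_name,
                dindex=indexes.distance_index,
            )
        except ValueError:
            continue
        chain_score_of[id(aln)] = chain.score
        alignments.append(aln)
    if not alignments:
        return MappingResult(read_name, None, unmapped=True, n_seeds=len(seeds))
    alignments.sort(key=lambda a: (-a.score, a.read_start))
    primary = alignments[0]
    # different chains over one locus converge to the same placement once
    # their tails are extended; such duplicates are not competitors
    rest = [
        a for a in alignments[1:] if _placement_overlap(primary, a) <= 0.5
    ]
    # A suppressed alternative placement competes through its chain score,
    # credited with the same extension gain the primary realized over its
    # own chain (an unextended chain's tails would extend comparably).
    competitor = 0.0
    if chain_competitor > 0:
        gain = max(0.0, primary.score - chain_score_of.get(id(primary), primary.score))
        competitor = min(float(chain_competitor) + gain, float(primary.score))
    mapq = compute_mapq(
        primary.score,
        [a.score for a in rest],
        scoring.match,
        fallback_competitor=competitor,
    )
    primary.mapq = mapq
    return MappingResult(
        read_name,
        primary,
        secondaries=rest,
        mapq=mapq,
        ambiguous=(bool(rest) and rest[0].score == primary.score)
        or competitor >= primary.score,
        n_seeds=len(seeds),
        n_chains=len(chains),
    )


# ---------------------------------------------------------------------------
# GAF output


def _path_string(aln: GraphAlignment, graph: VariationGraph) -> str:
    return "".join(
        (">" if o == FORWARD else "<") + graph.name_of[n] for n, o in aln.path
    )


def _target_spelling(aln: GraphAlignment, graph: VariationGraph) -> str:
    out = []
    for n, o, lo, hi in aln.runs:
        out.append(graph.oriented_sequence((n, o))[lo:hi])
    return "".join(out)


def cs_tag(aln: GraphAlignment, read: str, graph: VariationGraph) -> str:
    """Difference string (cs:Z) reconstructed from the edits."""
    q = read[aln.read_start : aln.read_end]
    t = _target_spelling(aln, graph)
    qi = ti = 0
    parts = []
    for op, ln in aln.edits:
        if op == "=":
            parts.append(f":{ln}")
            qi += ln
            ti += ln
        elif op == "X":
            for _ in range(ln):
                parts.append(f"*{t[ti].lower()}{q[qi].lower()}")
                qi += 1
                ti += 1
        elif op == "I":
            parts.append("+" + q[qi : qi + ln].lower())
            qi += ln
        else:
            parts.append("-" + t[ti : ti + ln].lower())
            ti += ln
    return "".join(parts)


def cigar_tag(aln: GraphAlignment) -> str:
    return "".join(f"{ln}{op}" for op, ln in aln.edits)


def write_gaf(
    results,
    stream,
    graph: VariationGraph,
    reads: dict[str, str] | None = None,
    secondaries: bool = False,
) -> dict:
    """Write mapped results as GAF lines; returns run summary counters."""
    n_mapped = n_unmapped = 0
    for res in results:
        if res.primary is None:
            n_unmapped += 1
            continue
        n_mapped += 1
        alns = [res.primary] + (res.secondaries if secondaries else [])
        for rank, aln in enumerate(alns):
            plen = aln.path_length(graph)
            pstart, pend = aln.path_interval(graph)
            fields = [
                aln.read_name,
                str(aln.read_length),
                str(aln.read_start),
                str(aln.read_end),
                "+",
                _path_string(aln, graph),
                str(plen),
                str(pstart),
                str(pend),
                str(aln.residue_matches()),
                str(aln.block_length()),
                str(aln.mapq if rank == 0 else 255),
                f"AS:i:{aln.score}",
                f"cg:Z:{cigar_tag(aln)}",
            ]
            if reads is not None and aln.read_name in reads:
                fields.append(f"cs:Z:{cs_tag(aln, reads[aln.read_name], graph)}")
            if rank > 0:
                fields.append("tp:A:S")
            stream.write("\t".join(fields) + "\n")
    return {"mapped": n_mapped, "unmapped": n_unmapped}


def parse_gaf_line(line: str, graph: VariationGraph) -> dict:
    """Re-parse a GAF line into its core fields (round-trip support)."""
    f = line.rstrip("\n").split("\t")
    name_to_id = {v: k for k, v in graph.name_of.items()}
    steps = []
    s = f[5]
    i = 0
    while i < len(s):
        mark = s[i]
        j = i + 1
        while j < len(s) and s[j] not in "><":
            j += 1
        steps.append((name_to_id[s[i + 1 : j]], "+" if mark == ">" else "-"))
        i = j
    out = {
        "name": f[0],
        "read_length": int(f[1]),
        "read_start": int(f[2]),
        "read_end": int(f[3]),
        "path": steps,
        "path_length": int(f[6]),
        "path_start": int(f[7]),
        "path_end": int(f[8]),
        "matches": int(f[9]),
        "block_length": int(f[10]),
        "mapq": int(f[11]),
    }
    for tag in f[12:]:
        if tag.startswith("AS:i:"):
            out["score"] = int(tag[5:])
    return out
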