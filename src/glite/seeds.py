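"""Weighted-minimizer seeding over haplotype sequences.

The index stores, for each canonical k-mer selected as a window minimizer
on any haplotype spelling, its occurrences as oriented graph positions.
K-mer order is a *weighted* hash order: k-mers whose global occurrence
count exceeds ``weight_threshold`` sort after all rarer k-mers, so
repetitive sequence loses minimizer elections to unique sequence and reads
seed preferentially in informative regions.  Minimizers with more than
``hard_hit_cap`` index occurrences produce no seeds at all.

A seed pairs a read offset with the graph position of the read k-mer's
first base, oriented so that reading onward from the position spells the
read k-mer exactly; seed positions therefore feed straight into distance
queries and chaining regardless of which strand the read came from.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import deque
from dataclasses import dataclass, field

from .graph import GraphPosition, VariationGraph

__all__ = ["MinimizerParams", "MinimizerIndex", "SeedHit", "build_minimizer_index", "find_seeds"]

# splitmix64 finalizer: invertible 64-bit mixer (fixed constants)
_M1 = 0xBF58476D1CE4E5B9
_M2 = 0x94D049BB133111EB
_MASK = (1 << 64) - 1

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _mix64(x: int) -> int:
    x &= _MASK
    x ^= x >> 30
    x = (x * _M1) & _MASK
    x ^= x >> 27
    x = (x * _M2) & _MASK
    x ^= x >> 31
    return x


@dataclass
class MinimizerParams:
    k: int = 19
    w: int = 11
    weight_threshold: int = 256
    hard_hit_cap: int = 500

    def validate(self) -> None:
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if not 3 <= self.k <= 31:
            raise ValueError("k must fit in a 64-bit 2-bit encoding (k <= 31)")


@dataclass
class SeedHit:
    read_offset: int
    read_strand: str  # '+': read k-mer spelled forward from position
    position: GraphPosition  # first base of the read k-mer, read orientation
    end_position: GraphPosition  # last base of the read k-mer, read orientation
    kmer: int  # canonical 2-bit code
    count: int  # index occurrence count of the minimizer

    def sort_key(self):
        return (self.read_offset, self.position.node_id, self.position.orientation,
                self.position.offset)


class MinimizerIndex:
    def __init__(self, graph: VariationGraph, params: MinimizerParams):
        self.graph = graph
        self.params = params
        self.counts: dict[int, int] = {}  # canonical k-mer -> global count
        # canonical k-mer -> list of (start GraphPosition, end GraphPosition,
        # strand of the walk occurrence relative to the canonical form)
        self.occurrences: dict[int, list[tuple[GraphPosition, GraphPosition, str]]] = {}

    def n_distinct(self) -> int:
        return len(self.occurrences)

    def n_positions(self) -> int:
        return sum(len(v) for v in self.occurrences.values())


def _kmer_codes(seq: str, k: int):
    """Yield (offset, forward code, canonical code, strand) per N-free k-mer."""
    n = len(seq)
    if n < k:
        return
    mask = (1 << (2 * k)) - 1
    fwd = 0
    rev = 0
    valid = 0  # run length of non-N bases ending here
    for i, ch in enumerate(seq):
        code = _CODE.get(ch)
        if code is None:
            valid = 0
            fwd = rev = 0
            continue
        valid += 1
        fwd = ((fwd << 2) | code) & mask
        rev = (rev >> 2) | ((3 - code) << (2 * (k - 1)))
        if valid >= k:
            off = i - k + 1
            if fwd <= rev:
                yield off, fwd, fwd, "+"
            else:
                yield off, fwd, rev, "-"


def _select_minimizers(seq: str, k: int, w: int, order_key) -> list[tuple[int, int, str]]:
    """Leftmost-minimum sliding-window selection.

    Returns distinct (offset, canonical code, strand) selections such that
    every window of w consecutive k-mer starts contains one of them (the
    standard minimizer guarantee; windows of all-N k-mers select nothing).
    """
    entries = list(_kmer_codes(seq, k))
    if not entries:
        return []
    n_starts = len(seq) - k + 1
    by_off = {off: (canon, strand) for off, _, canon, strand in entries}
    keys = {off: order_key(canon) for off, (canon, _) in by_off.items()}
    selected: dict[int, tuple[int, str]] = {}
    dq: deque[int] = deque()  # offsets, keys increasing front to back
    for start in range(n_starts):
        if start in keys:
            while dq and keys[dq[-1]] > keys[start]:
                dq.pop()
            dq.append(start)
        lo = start - w + 1  # current window is [lo, start]
        while dq and dq[0] < lo:
            dq.popleft()
        if start >= w - 1 and dq:
            off = dq[0]
            selected[off] = by_off[off]
    if n_starts < w:  # short sequence: single partial window
        if dq:
            off = dq[0]
            selected[off] = by_off[off]
    return [(off, c, s) for off, (c, s) in sorted(selected.items())]


class _WalkCoords:
    """Map offsets on a walk's spelling back to oriented graph positions."""

    def __init__(self, graph: VariationGraph, walk):
        self.steps = walk.steps
        self.starts = []
        self.lens = []
        off = 0
        for n, _ in walk.steps:
            self.starts.append(off)
            ln = graph.node_length(n)
            self.lens.append(ln)
            off += ln
        self.total = off

    def position(self, offset: int) -> GraphPosition:
        i = bisect_right(self.starts, offset) - 1
        node, orient = self.steps[i]
        return GraphPosition(node, orient, offset - self.starts[i])


def build_minimizer_index(graph: VariationGraph, params: MinimizerParams | None = None) -> MinimizerIndex:
    params = params or MinimizerParams()
    params.validate()
    if not graph.walks:
        raise ValueError("graph has no walks to index")
    index = MinimizerIndex(graph, params)
    k, w = params.k, params.w

    spellings = [(walk, graph.spell_walk(walk)) for walk in graph.walks]
    for _, seq in spellings:  # global counting pass (drives the weighting)
        for _, _, canon, _ in _kmer_codes(seq, k):
            index.counts[canon] = index.counts.get(canon, 0) + 1

    def order_key(canon: int):
        frequent = index.counts.get(canon, 0) > params.weight_threshold
        return (frequent, _mix64(canon), canon)

    seen: dict[int, set] = {}
    for walk, seq in spellings:
        coords = _WalkCoords(graph, walk)
        for off, canon, strand in _select_minimizers(seq, k, w, order_key):
            start = coords.position(off)
            end = coords.position(off + k - 1)
            dedup_key = (start.node_id, start.orientation, start.offset, strand)
            bucket = seen.setdefault(canon, set())
            if dedup_key in bucket:
                continue
            bucket.add(dedup_key)
            index.occurrences.setdefault(canon, []).append((start, end, strand))
    for canon in index.occurrences:
        index.occurrences[canon].sort(
            key=lambda t: (t[0].node_id, t[0].orientation, t[0].offset, t[2])
        )
    return index


def find_seeds(index: MinimizerIndex, read: str, params: MinimizerParams | None = None) -> list[SeedHit]:
    """Match read minimizers against the index, producing seeds.

    Reads shorter than k produce no seeds.  Minimizers whose index count
    exceeds the hard hit cap are skipped entirely.
    """
    params = params or index.params
    read = read.upper()
    if len(read) < params.k:
        return []

    def order_key(canon: int):
        frequent = index.counts.get(canon, 0) > params.weight_threshold
        return (frequent, _mix64(canon), canon)

    k = params.k
    seeds: list[SeedHit] = []
    node_len = index.graph.node_length
    for off, canon, read_strand in _select_minimizers(read, k, params.w, order_key):
        occs = index.occurrences.get(canon)
        if not occs:
            continue
        count = index.counts.get(canon, 0)
        if count > params.hard_hit_cap:
            continue
        for start, end, occ_strand in occs:
            if read_strand == occ_strand:
                pos, epos, strand = start, end, "+"
            else:
                # read k-mer is the reverse complement of the walk occurrence
                pos = end.reverse(node_len(end.node_id))
                epos = start.reverse(node_len(start.node_id))
                strand = "-"
            seeds.append(SeedHit(off, strand, pos, epos, canon, count))
    seeds.sort(key=SeedHit.sort_key)
    return seeds
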