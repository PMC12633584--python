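"""Bidirected variation-graph data model with embedded haplotype walks.

A variation graph is a bidirected graph whose nodes carry nucleotide
sequences and whose edges join *node sides* (left or right end of a node).
A valid walk enters a node on one side and leaves on the opposite side, so
every node visit has an orientation: a forward visit spells the node
sequence, a reverse visit spells its reverse complement.  Haplotypes and
reference sequences are stored as named walks; following GBZ semantics the
walk set implicitly defines the edge set (edges present in an input GFA but
unsupported by any walk are retained but flagged).

Offsets are 0-based throughout and intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "LEFT",
    "RIGHT",
    "FORWARD",
    "REVERSE",
    "NodeSide",
    "OrientedNode",
    "GraphPosition",
    "HaplotypeWalk",
    "VariationGraph",
    "GFAParseError",
    "reverse_complement",
    "parse_gfa",
    "write_gfa",
]

LEFT = "L"
RIGHT = "R"
FORWARD = "+"
REVERSE = "-"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_DNA_OK = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# A node side is the tuple (node_id, LEFT|RIGHT); kept as a plain tuple for
# speed, with a tiny named constructor for readability in user code.
def NodeSide(node_id: int, side: str) -> tuple[int, str]:
    if side not in (LEFT, RIGHT):
        raise ValueError(f"side must be {LEFT!r} or {RIGHT!r}, got {side!r}")
    return (node_id, side)


def opposite_side(side: tuple[int, str]) -> tuple[int, str]:
    node_id, s = side
    return (node_id, RIGHT if s == LEFT else LEFT)


# An oriented node is (node_id, FORWARD|REVERSE).
def OrientedNode(node_id: int, orientation: str) -> tuple[int, str]:
    if orientation not in (FORWARD, REVERSE):
        raise ValueError(f"orientation must be '+' or '-', got {orientation!r}")
    return (node_id, orientation)


def flip_oriented(step: tuple[int, str]) -> tuple[int, str]:
    node_id, o = step
    return (node_id, REVERSE if o == FORWARD else FORWARD)


def exit_side(step: tuple[int, str]) -> tuple[int, str]:
    """Side through which a walk leaves this oriented node visit."""
    node_id, o = step
    return (node_id, RIGHT if o == FORWARD else LEFT)


def entry_side(step: tuple[int, str]) -> tuple[int, str]:
    """Side through which a walk enters this oriented node visit."""
    node_id, o = step
    return (node_id, LEFT if o == FORWARD else RIGHT)


@dataclass(frozen=True)
class GraphPosition:
    """A 0-based base position on an oriented node traversal.

    ``offset`` is counted in traversal orientation: offset 0 of a reverse
    position is the last stored base of the node (complemented).
    """

    node_id: int
    orientation: str
    offset: int

    def reverse(self, node_length: int) -> "GraphPosition":
        """Same physical base read in the opposite direction."""
        return GraphPosition(
            self.node_id,
            REVERSE if self.orientation == FORWARD else FORWARD,
            node_length - 1 - self.offset,
        )


@dataclass
class HaplotypeWalk:
    name: str
    steps: list[tuple[int, str]]
    role: str = "haplotype"  # or "reference"
    # W-line coordinates, if the walk came from a W line.
    metadata: dict = field(default_factory=dict)

    def reversed_walk(self) -> "HaplotypeWalk":
        return HaplotypeWalk(
            self.name + "_rev",
            [flip_oriented(s) for s in reversed(self.steps)],
            self.role,
            dict(self.metadata),
        )


def _edge_key(a: tuple[int, str], b: tuple[int, str]) -> tuple:
    """Canonical unordered representation of an edge between two sides."""
    return (a, b) if a <= b else (b, a)


class VariationGraph:
    """Nodes, side edges and named haplotype walks.

    Node ids are positive integers.  GFA segment names are mapped to dense
    integer ids on parse; the mapping is preserved for serialization.
    """

    def __init__(self) -> None:
        self.nodes: dict[int, str] = {}
        # edge key -> True if supported by >= 1 walk
        self.edges: dict[tuple, bool] = {}
        self.walks: list[HaplotypeWalk] = []
        self.name_of: dict[int, str] = {}  # node id -> original GFA name

    # -- construction -------------------------------------------------

    def add_node(self, node_id: int, sequence: str, name: str | None = None) -> None:
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id}")
        if node_id <= 0:
            raise ValueError(f"node ids must be positive, got {node_id}")
        if not sequence:
            raise ValueError(f"node {node_id} has an empty sequence")
        up = sequence.upper()
        if not set(up) <= _DNA_OK:
            raise ValueError(f"node {node_id} sequence has non-ACGTN characters")
        self.nodes[node_id] = up
        self.name_of[node_id] = name if name is not None else str(node_id)

    def add_edge(self, a: tuple[int, str], b: tuple[int, str], haplotype: bool = False) -> None:
        for side in (a, b):
            if side[0] not in self.nodes:
                raise ValueError(f"edge endpoint names unknown node {side[0]}")
        key = _edge_key(a, b)
        self.edges[key] = self.edges.get(key, False) or haplotype

    def add_walk(self, walk: HaplotypeWalk, define_edges: bool = True) -> None:
        """Add a walk; by default its step adjacencies define/support edges."""
        for node_id, _ in walk.steps:
            if node_id not in self.nodes:
                raise ValueError(f"walk {walk.name!r} visits unknown node {node_id}")
        for prev, nxt in zip(walk.steps, walk.steps[1:]):
            a, b = exit_side(prev), entry_side(nxt)
            if define_edges:
                self.add_edge(a, b, haplotype=True)
            elif not self.has_edge(a, b):
                raise ValueError(
                    f"walk {walk.name!r} step {prev}->{nxt} is not supported by an edge"
                )
        self.walks.append(walk)

    # -- queries ------------------------------------------------------

    def node_length(self, node_id: int) -> int:
        return len(self.nodes[node_id])

    def has_edge(self, a: tuple[int, str], b: tuple[int, str]) -> bool:
        return _edge_key(a, b) in self.edges

    def side_adjacency(self) -> dict[tuple[int, str], list[tuple[int, str]]]:
        """Adjacency over sides: for each side, the sides it shares an edge with."""
        adj: dict[tuple[int, str], list[tuple[int, str]]] = {}
        for n in self.nodes:
            adj[(n, LEFT)] = []
            adj[(n, RIGHT)] = []
        for (a, b) in self.edges:
            adj[a].append(b)
            if b != a:
                adj[b].append(a)
        return adj

    def side_neighbours(self, side: tuple[int, str]) -> list[tuple[int, str]]:
        """All sides connected to ``side`` by an edge (self-edges included)."""
        return self.side_adjacency()[side]

    def oriented_sequence(self, step: tuple[int, str]) -> str:
        node_id, orientation = step
        if node_id not in self.nodes:
            raise KeyError(f"unknown node {node_id}")
        seq = self.nodes[node_id]
        return seq if orientation == FORWARD else reverse_complement(seq)

    def spell_walk(self, walk: HaplotypeWalk) -> str:
        for prev, nxt in zip(walk.steps, walk.steps[1:]):
            if not self.has_edge(exit_side(prev), entry_side(nxt)):
                raise ValueError(
                    f"walk step {prev}->{nxt} violates edge support in {walk.name!r}"
                )
        return "".join(self.oriented_sequence(s) for s in walk.steps)

    def walk_by_name(self, name: str) -> HaplotypeWalk:
        for w in self.walks:
            if w.name == name:
                return w
        raise KeyError(f"no walk named {name!r}")

    def components(self) -> list[set[int]]:
        """Connected components over nodes, ignoring sidedness."""
        adj: dict[int, set[int]] = {n: set() for n in self.nodes}
        for (a, b) in self.edges:
            adj[a[0]].add(b[0])
            adj[b[0]].add(a[0])
        seen: set[int] = set()
        comps = []
        for start in sorted(self.nodes):
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if v not in comp:
                        comp.add(v)
                        stack.append(v)
            seen |= comp
            comps.append(comp)
        return comps

    def validate(self) -> None:
        """Check all structural invariants; raise ValueError on violation."""
        for (a, b) in self.edges:
            for side in (a, b):
                if side[0] not in self.nodes:
                    raise ValueError(f"edge endpoint names unknown node {side[0]}")
        for walk in self.walks:
            for prev, nxt in zip(walk.steps, walk.steps[1:]):
                if not self.has_edge(exit_side(prev), entry_side(nxt)):
                    raise ValueError(
                        f"walk {walk.name!r} has unsupported step {prev}->{nxt}"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariationGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and set(self.edges) == set(other.edges)
            and [(w.name, w.steps) for w in self.walks]
            == [(w.name, w.steps) for w in other.walks]
        )


class GFAParseError(ValueError):
    def __init__(self, message: str, line_number: int):
        super().__init__(f"GFA line {line_number}: {message}")
        self.line_number = line_number


def _orient_char_to_sides(name_a: str, oa: str, name_b: str, ob: str, ids: dict[str, int]):
    """L-line (a, oa, b, ob) -> the pair of sides the edge joins."""
    a = (ids[name_a], RIGHT if oa == "+" else LEFT)
    b = (ids[name_b], LEFT if ob == "+" else RIGHT)
    return a, b


def parse_gfa(stream: Iterable[str]) -> VariationGraph:
    """Parse GFA v1.1 (S, L, P, W lines) into a :class:`VariationGraph`.

    Segment names become dense integer ids; if every name is a positive
    integer the numeric values are kept.  L-line overlaps must be 0M or *.
    Edges named only on L lines are retained but flagged non-haplotype.
    """
    s_lines: list[tuple[int, str, str]] = []
    l_lines: list[tuple[int, list[str]]] = []
    path_lines: list[tuple[int, str, list[str]]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "H":
            continue
        if tag == "S":
            if len(fields) < 3:
                raise GFAParseError("S line needs name and sequence", lineno)
            s_lines.append((lineno, fields[1], fields[2]))
        elif tag == "L":
            if len(fields) < 6:
                raise GFAParseError("L line needs 5 fields", lineno)
            if fields[5] not in ("0M", "*"):
                raise GFAParseError(f"unsupported overlap {fields[5]!r}", lineno)
            l_lines.append((lineno, fields[1:5]))
        elif tag in ("P", "W"):
            path_lines.append((lineno, tag, fields))
        else:
            raise GFAParseError(f"unknown record type {tag!r}", lineno)

    graph = VariationGraph()
    names = [name for _, name, _ in s_lines]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})[0]
        raise GFAParseError(f"duplicate segment name {dup!r}", s_lines[0][0])
    if names and all(n.isdigit() and int(n) > 0 for n in names):
        ids = {n: int(n) for n in names}
    else:
        ids = {n: i + 1 for i, n in enumerate(names)}
    for lineno, name, seq in s_lines:
        try:
            graph.add_node(ids[name], seq, name=name)
        except ValueError as exc:
            raise GFAParseError(str(exc), lineno) from exc

    pending_edges = []
    for lineno, (na, oa, nb, ob) in l_lines:
        for n in (na, nb):
            if n not in ids:
                raise GFAParseError(f"L line references unknown segment {n!r}", lineno)
        if oa not in "+-" or ob not in "+-":
            raise GFAParseError("L orientations must be + or -", lineno)
        pending_edges.append(_orient_char_to_sides(na, oa, nb, ob, ids))

    for lineno, tag, fields in path_lines:
        if tag == "P":
            if len(fields) < 3:
                raise GFAParseError("P line needs a name and a segment list", lineno)
            name = fields[1]
            steps = []
            for tok in fields[2].split(","):
                if len(tok) < 2 or tok[-1] not in "+-":
                    raise GFAParseError(f"bad path step {tok!r}", lineno)
                seg = tok[:-1]
                if seg not in ids:
                    raise GFAParseError(f"path references unknown segment {seg!r}", lineno)
                steps.append((ids[seg], tok[-1]))
            walk = HaplotypeWalk(name, steps)
        else:  # W line: sample, hap index, contig, start, end, walk string
            if len(fields) < 7:
                raise GFAParseError("W line needs 6 fields", lineno)
            sample, hap, contig, start, end, wstr = fields[1:7]
            steps = []
            i = 0
            while i < len(wstr):
                mark = wstr[i]
                if mark not in "><":
                    raise GFAParseError(f"bad walk string near {wstr[i:i+8]!r}", lineno)
                j = i + 1
                while j < len(wstr) and wstr[j] not in "><":
                    j += 1
                seg = wstr[i + 1 : j]
                if seg not in ids:
                    raise GFAParseError(f"walk references unknown segment {seg!r}", lineno)
                steps.append((ids[seg], FORWARD if mark == ">" else REVERSE))
                i = j
            walk = HaplotypeWalk(
                "#".join((sample, hap, contig)),
                steps,
                metadata={"sample": sample, "haplotype": hap, "contig": contig,
                          "start": start, "end": end, "w_line": True},
            )
        if not walk.steps:
            raise GFAParseError("empty path", lineno)
        try:
            graph.add_walk(walk, define_edges=True)
        except ValueError as exc:
            raise GFAParseError(str(exc), lineno) from exc

    # L-line edges not already defined by a walk are non-haplotype edges.
    for a, b in pending_edges:
        if not graph.has_edge(a, b):
            graph.add_edge(a, b, haplotype=False)
    return graph


def _side_pair_to_l_fields(a: tuple[int, str], b: tuple[int, str], graph: VariationGraph):
    na, sa = a
    nb, sb = b
    return (
        graph.name_of[na],
        "+" if sa == RIGHT else "-",
        graph.name_of[nb],
        "+" if sb == LEFT else "-",
    )


def write_gfa(graph: VariationGraph, stream) -> None:
    """Serialize as GFA v1.1 with S, L and P/W lines (tab separated)."""
    stream.write("H\tVN:Z:1.1\n")
    for node_id in sorted(graph.nodes):
        stream.write(f"S\t{graph.name_of[node_id]}\t{graph.nodes[node_id]}\n")
    for a, b in sorted(graph.edges):
        na, oa, nb, ob = _side_pair_to_l_fields(a, b, graph)
        stream.write(f"L\t{na}\t{oa}\t{nb}\t{ob}\t0M\n")
    for walk in graph.walks:
        if walk.metadata.get("w_line"):
            m = walk.metadata
            wstr = "".join(
                (">" if o == FORWARD else "<") + graph.name_of[n] for n, o in walk.steps
            )
            stream.write(
                f"W\t{m['sample']}\t{m['haplotype']}\t{m['contig']}\t"
                f"{m['start']}\t{m['end']}\t{wstr}\n"
            )
        else:
            path = ",".join(graph.name_of[n] + o for n, o in walk.steps)
            stream.write(f"P\t{walk.name}\t{path}\t*\n")


def gfa_to_string(graph: VariationGraph) -> str:
    import io

    buf = io.StringIO()
    write_gfa(graph, buf)
    return buf.getvalue()
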