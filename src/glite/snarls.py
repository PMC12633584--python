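"""Snarl/chain decomposition of a bidirected variation graph.

A *snarl* is a subgraph bounded by two node sides that are separable
(cutting the two boundary nodes into their component sides disconnects the
interior from the rest of the graph) and minimal (no side inside the
subgraph is separable with either boundary).  Runs of nodes with snarls
between them form *chains*; the simplest chain is a single node, so every
node belongs to exactly one chain.  Nesting of snarls and chains forms the
snarl tree, which the distance index and zip codes are built on.

Decomposition here is a deliberate desk-scale brute force: candidate
boundary pairs are tested for separability by component analysis of the
side-split graph.  On graphs above ``EXHAUSTIVE_NODE_LIMIT`` nodes the
candidate search is restricted to node pairs within ``max_span`` hops and
snarl contents are capped, which is exact for the bubble-scale variation
this package's graphs contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import (
    FORWARD,
    LEFT,
    REVERSE,
    RIGHT,
    VariationGraph,
    opposite_side,
)

__all__ = ["Snarl", "SnarlChain", "SnarlTree", "is_separable", "decompose"]

EXHAUSTIVE_NODE_LIMIT = 200
DEFAULT_MAX_SPAN = 12
DEFAULT_MAX_CONTENT = 64  # side-vertex cap for bounded-mode separability BFS


@dataclass
class Snarl:
    start_side: tuple[int, str]
    end_side: tuple[int, str]
    content_nodes: frozenset[int]
    children: list["SnarlChain"] = field(default_factory=list)
    cyclic: bool = False
    parent_chain: "SnarlChain | None" = None

    @property
    def boundary_nodes(self) -> tuple[int, int]:
        return (self.start_side[0], self.end_side[0])

    def __repr__(self) -> str:
        return f"Snarl({self.start_side}->{self.end_side}, n={len(self.content_nodes)})"


@dataclass
class SnarlChain:
    # alternating ('node', (id, orientation)) and ('snarl', Snarl) items
    items: list[tuple]
    parent_snarl: Snarl | None = None
    circular: bool = False

    def node_items(self) -> list[tuple[int, str]]:
        return [payload for kind, payload in self.items if kind == "node"]

    def node_ids(self) -> list[int]:
        return [n for n, _ in self.node_items()]

    def snarl_items(self) -> list[Snarl]:
        return [payload for kind, payload in self.items if kind == "snarl"]

    def __repr__(self) -> str:
        return f"Chain({self.node_ids()}{' circular' if self.circular else ''})"


class SnarlTree:
    def __init__(self, graph: VariationGraph):
        self.graph = graph
        self.root_chains: list[SnarlChain] = []
        self.chain_of: dict[int, SnarlChain] = {}

    def all_snarls(self) -> list[Snarl]:
        out: list[Snarl] = []

        def rec(chain: SnarlChain) -> None:
            for s in chain.snarl_items():
                out.append(s)
                for c in s.children:
                    rec(c)

        for chain in self.root_chains:
            rec(chain)
        return out

    def ancestry(self, node_id: int) -> list:
        """Enclosing [chain, snarl, chain, ..., root chain], innermost first."""
        if node_id not in self.chain_of:
            raise KeyError(f"node {node_id} is not in the snarl tree")
        out: list = []
        chain = self.chain_of[node_id]
        while chain is not None:
            out.append(chain)
            snarl = chain.parent_snarl
            if snarl is None:
                break
            out.append(snarl)
            chain = snarl.parent_chain
        return out

    def depth(self, node_id: int) -> int:
        return (len(self.ancestry(node_id)) - 1) // 2

    def node_partition_ok(self) -> bool:
        """Every graph node occurs in exactly one chain, exactly once."""
        seen: list[int] = []

        def rec(chain: SnarlChain) -> None:
            seen.extend(chain.node_ids())
            for s in chain.snarl_items():
                for c in s.children:
                    rec(c)

        for chain in self.root_chains:
            rec(chain)
        return sorted(seen) == sorted(self.graph.nodes)

    def dump_jsonl(self, stream) -> None:
        import json

        for s in self.all_snarls():
            parent = s.parent_chain.parent_snarl if s.parent_chain else None
            stream.write(
                json.dumps(
                    {
                        "start": list(s.start_side),
                        "end": list(s.end_side),
                        "contents": sorted(s.content_nodes),
                        "cyclic": s.cyclic,
                        "parent": list(parent.start_side) + list(parent.end_side)
                        if parent
                        else None,
                    }
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# separability


def _strict_separable(
    adj: dict,
    a: tuple[int, str],
    b: tuple[int, str],
    max_sides: int | None = None,
) -> frozenset[int] | None:
    """Component test on the side-split graph.

    The two tested nodes are cut into disconnected halves; every other node
    contributes an internal edge between its sides.  Separable iff the
    component of ``a`` contains ``b`` and neither node's opposite half.
    Returns the content node set (excluding boundaries) or None.
    """
    if a[0] == b[0]:
        return None
    cut = (a[0], b[0])
    opp_a, opp_b = opposite_side(a), opposite_side(b)
    seen = {a}
    stack = [a]
    while stack:
        s = stack.pop()
        neighbours = adj[s]
        if s[0] not in cut:
            internal = opposite_side(s)
            if internal not in seen:
                seen.add(internal)
                if internal in (opp_a, opp_b):
                    return None
                stack.append(internal)
        for t in neighbours:
            if t not in seen:
                seen.add(t)
                if t in (opp_a, opp_b):
                    return None
                if max_sides is not None and len(seen) > max_sides:
                    return None
                stack.append(t)
    if b not in seen:
        return None
    return frozenset(n for n, _ in seen if n not in cut)


def is_separable(
    graph: VariationGraph, side_a: tuple[int, str], side_b: tuple[int, str]
) -> tuple[bool, frozenset[int] | None]:
    """Public separability test.

    Besides the component test, a pair of sides joined directly by an edge
    counts as a (trivial) separable pair with empty contents; such pairs
    never become snarl objects but surface as chain adjacencies.
    """
    for side in (side_a, side_b):
        if side[0] not in graph.nodes:
            raise KeyError(f"unknown node {side[0]}")
    if side_a == side_b:
        raise ValueError("sides must differ")
    adj = graph.side_adjacency()
    contents = _strict_separable(adj, side_a, side_b)
    if contents is not None:
        return True, contents
    if graph.has_edge(side_a, side_b):
        return True, frozenset()
    return False, None


# ---------------------------------------------------------------------------
# candidate enumeration


def _candidates_exhaustive(graph: VariationGraph, adj: dict):
    """All-pairs boundary search via integer-indexed components.

    Sides are mapped to ints (node rank * 2 + side); for each unordered node
    pair the side-split component labelling is computed once and the four
    side combinations are read off it.
    """
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n_sides = 2 * len(nodes)
    int_adj: list[list[int]] = [[] for _ in range(n_sides)]
    for (a, b), _ in graph.edges.items():
        ia = idx[a[0]] * 2 + (0 if a[1] == LEFT else 1)
        ib = idx[b[0]] * 2 + (0 if b[1] == LEFT else 1)
        int_adj[ia].append(ib)
        if ib != ia:
            int_adj[ib].append(ia)
    comp = [0] * n_sides
    found = []
    for i, u in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            v = nodes[j]
            for s in range(n_sides):
                comp[s] = -1
            cid = 0
            groups: list[list[int]] = []
            for start in range(n_sides):
                if comp[start] >= 0:
                    continue
                comp[start] = cid
                group = [start]
                stack = [start]
                while stack:
                    s = stack.pop()
                    node_rank = s >> 1
                    if node_rank != i and node_rank != j:
                        o = s ^ 1
                        if comp[o] < 0:
                            comp[o] = cid
                            group.append(o)
                            stack.append(o)
                    for t in int_adj[s]:
                        if comp[t] < 0:
                            comp[t] = cid
                            group.append(t)
                            stack.append(t)
                groups.append(group)
                cid += 1
            ui, vi = 2 * i, 2 * j
            for sa_i in (ui, ui + 1):
                for sb_i in (vi, vi + 1):
                    c = comp[sa_i]
                    if comp[sb_i] != c or comp[sa_i ^ 1] == c or comp[sb_i ^ 1] == c:
                        continue
                    contents = frozenset(
                        nodes[m >> 1] for m in groups[c] if (m >> 1) not in (i, j)
                    )
                    if contents:
                        sa = (u, LEFT if sa_i % 2 == 0 else RIGHT)
                        sb = (v, LEFT if sb_i % 2 == 0 else RIGHT)
                        found.append((sa, sb, contents))
    return found


def _node_hop_adjacency(graph: VariationGraph) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {n: set() for n in graph.nodes}
    for (a, b) in graph.edges:
        adj[a[0]].add(b[0])
        adj[b[0]].add(a[0])
    return adj


def _candidates_bounded(graph: VariationGraph, adj: dict, max_span: int, max_sides: int):
    node_adj = _node_hop_adjacency(graph)
    found = []
    nodes = sorted(graph.nodes)
    for u in nodes:
        # nodes within max_span hops of u
        dist = {u: 0}
        frontier = [u]
        for _ in range(max_span):
            nxt = []
            for x in frontier:
                for y in node_adj[x]:
                    if y not in dist:
                        dist[y] = dist[x] + 1
                        nxt.append(y)
            frontier = nxt
        for v in sorted(dist):
            if v <= u:
                continue
            for sa in ((u, LEFT), (u, RIGHT)):
                for sb in ((v, LEFT), (v, RIGHT)):
                    contents = _strict_separable(adj, sa, sb, max_sides=max_sides)
                    if contents:
                        found.append((sa, sb, contents))
    return found


def _traversable(graph: VariationGraph, adj: dict, sa, sb, contents: frozenset[int]) -> bool:
    """A walk can cross the snarl from its start side to its end side.

    Rules out inside-out boundary pairs (formally separable, but with an
    interior no walk can traverse boundary to boundary), which would
    otherwise compete with the natural bubble boundaries."""
    if graph.has_edge(sa, sb):
        return True
    # directed search over traversals of content nodes
    start_travs = []
    for t in adj[sa]:
        if t[0] in contents:
            start_travs.append((t[0], FORWARD if t[1] == LEFT else REVERSE))
    seen = set(start_travs)
    stack = list(start_travs)
    while stack:
        node, orient = stack.pop()
        exit_s = (node, RIGHT if orient == FORWARD else LEFT)
        for t in adj[exit_s]:
            if t == sb:
                return True
            if t[0] in contents:
                trav = (t[0], FORWARD if t[1] == LEFT else REVERSE)
                if trav not in seen:
                    seen.add(trav)
                    stack.append(trav)
    return False


# ---------------------------------------------------------------------------
# decomposition


def _canonical_pair(sa, sb):
    return (sa, sb) if (sa[0], sb[0]) <= (sb[0], sa[0]) else (sb, sa)


def decompose(
    graph: VariationGraph,
    max_span: int | None = None,
    max_content_sides: int = DEFAULT_MAX_CONTENT,
) -> SnarlTree:
    """Build the snarl tree of ``graph``.

    Canonicalization: chains are traversed so the lowest node id comes
    first; among separable pairs with identical contents the boundary pair
    minimizing (min node id, max node id, sides) is kept.
    """
    if not graph.nodes:
        raise ValueError("cannot decompose an empty graph")
    walked = {n for w in graph.walks for n, _ in w.steps}
    for comp in graph.components():
        if not comp & walked:
            raise ValueError(
                f"component containing node {min(comp)} is touched by no walk"
            )

    adj = graph.side_adjacency()
    if max_span is None and len(graph.nodes) > EXHAUSTIVE_NODE_LIMIT:
        max_span = DEFAULT_MAX_SPAN
    if max_span is None:
        candidates = _candidates_exhaustive(graph, adj)
    else:
        candidates = _candidates_bounded(graph, adj, max_span, max_content_sides)

    candidates = [
        (sa, sb, contents)
        for sa, sb, contents in candidates
        if _traversable(graph, adj, sa, sb, contents)
        or _traversable(graph, adj, sb, sa, contents)
    ]

    # minimality: no side inside the snarl is separable with either boundary
    minimal = []
    for sa, sb, contents in candidates:
        ok = True
        for n in contents:
            for s in ((n, LEFT), (n, RIGHT)):
                if (
                    _strict_separable(adj, sa, s, max_sides=max_content_sides) is not None
                    or _strict_separable(adj, s, sb, max_sides=max_content_sides) is not None
                ):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            sa2, sb2 = _canonical_pair(sa, sb)
            minimal.append((sa2, sb2, contents))

    # accept snarls smallest-first; drop duplicates and non-nested overlaps
    minimal.sort(key=lambda t: (len(t[2]), t[0][0], t[1][0], t[0][1], t[1][1]))
    accepted: list[tuple] = []
    for sa, sb, contents in minimal:
        span = contents | {sa[0], sb[0]}
        ok = True
        for ta, tb, tcont in accepted:
            nested = tcont <= contents and ta[0] in contents and tb[0] in contents
            disjoint = not (tcont & span)
            if not (nested or disjoint):
                ok = False
                break
        if ok:
            accepted.append((sa, sb, contents))

    snarls = [
        Snarl(sa, sb, contents, cyclic=_is_cyclic(graph, sa, sb, contents))
        for sa, sb, contents in accepted
    ]
    # parent: smallest accepted snarl strictly containing this one
    parent_of: dict[int, int | None] = {}
    for i, s in enumerate(snarls):
        best = None
        for j, t in enumerate(snarls):
            if i == j:
                continue
            if s.content_nodes <= t.content_nodes and set(s.boundary_nodes) <= t.content_nodes:
                if best is None or len(t.content_nodes) < len(snarls[best].content_nodes):
                    best = j
        parent_of[i] = best

    tree = SnarlTree(graph)
    by_parent: dict[int | None, list[int]] = {}
    for i, p in parent_of.items():
        by_parent.setdefault(p, []).append(i)

    all_contents: set[int] = set()
    for s in snarls:
        all_contents |= s.content_nodes

    def build_region(region_nodes: set[int], level_ids: list[int], parent: Snarl | None):
        level = [snarls[i] for i in level_ids]
        inner = set()
        for s in level:
            inner |= s.content_nodes
        top = region_nodes - inner
        links: dict[tuple[int, str], list] = {}

        def add_link(side, link):
            links.setdefault(side, []).append(link)

        for s in level:
            add_link(s.start_side, ("snarl", s))
            add_link(s.end_side, ("snarl", s))
        span_sides = [
            {s.start_side, s.end_side} | {(n, sd) for n in s.content_nodes for sd in (LEFT, RIGHT)}
            for s in level
        ]
        for (x, y) in graph.edges:
            if x[0] not in top or y[0] not in top:
                continue
            if any(x in ss and y in ss for ss in span_sides):
                continue
            add_link(x, ("edge", y))
            if y != x:
                add_link(y, ("edge", x))

        def usable(side):
            ls = links.get(side, [])
            return ls[0] if len(ls) == 1 else None

        chains: list[SnarlChain] = []
        visited: set[int] = set()

        def walk_chain(start: int, entry: str) -> tuple[list, bool]:
            items: list[tuple] = []
            node, ent = start, entry
            circular = False
            while True:
                visited.add(node)
                items.append(("node", (node, FORWARD if ent == LEFT else REVERSE)))
                exit_s = (node, RIGHT if ent == LEFT else LEFT)
                link = usable(exit_s)
                if link is None:
                    break
                if link[0] == "snarl":
                    s = link[1]
                    other = s.end_side if exit_s == s.start_side else s.start_side
                    nxt, nxt_side = other[0], other[1]
                    items.append(("snarl", s))
                else:
                    nxt, nxt_side = link[1]
                if nxt in visited:
                    if nxt == start:
                        circular = True
                    if items[-1][0] == "snarl":
                        items.pop()  # re-attach when canonicalizing circular chains
                    break
                node, ent = nxt, nxt_side
            return items, circular

        def reverse_items(items):
            out = []
            for kind, payload in reversed(items):
                if kind == "node":
                    n, o = payload
                    out.append(("node", (n, REVERSE if o == FORWARD else FORWARD)))
                else:
                    out.append((kind, payload))
            return out

        # chains starting at a free (unlinked) side first, then cycles
        starts = []
        for n in sorted(top):
            for ent in (LEFT, RIGHT):
                other = (n, RIGHT if ent == LEFT else LEFT)
                if usable((n, ent)) is None and usable(other) is not None:
                    starts.append((n, ent))
        for n in sorted(top):
            if usable((n, LEFT)) is None and usable((n, RIGHT)) is None:
                starts.append((n, LEFT))
        for n, ent in starts:
            if n in visited:
                continue
            # a free-entry side means the chain begins here; enter on the
            # side with no link so traversal leaves through the linked side
            items, circular = walk_chain(n, ent)
            rev = reverse_items(items)
            ids = [p[0] for k, p in items if k == "node"]
            rev_ids = [p[0] for k, p in rev if k == "node"]
            chosen = items if (ids, str(items)) <= (rev_ids, str(rev)) else rev
            chains.append(SnarlChain(chosen, parent_snarl=parent, circular=circular))
        for n in sorted(top):  # leftovers: cycles with no free side
            if n not in visited:
                items, circular = walk_chain(n, LEFT)
                chains.append(SnarlChain(items, parent_snarl=parent, circular=circular))

        chains.sort(key=lambda c: min(c.node_ids()))
        for chain in chains:
            for nid in chain.node_ids():
                tree.chain_of[nid] = chain
            for kind, payload in chain.items:
                if kind == "snarl":
                    payload.parent_chain = chain
        for s in level:
            idx = snarls.index(s)
            s.children = build_region(
                set(s.content_nodes), by_parent.get(idx, []), s
            )
        return chains

    for comp in graph.components():
        level_ids = [
            i
            for i, p in parent_of.items()
            if p is None and snarls[i].start_side[0] in comp
        ]
        tree.root_chains.extend(build_region(set(comp), level_ids, None))
    tree.root_chains.sort(key=lambda c: min(c.node_ids()))
    return tree


def _is_cyclic(
    graph: VariationGraph, sa, sb, contents: frozenset[int]
) -> bool:
    """True when the snarl interior admits a repeated node visit.

    Detected as a directed cycle in the traversal graph restricted to the
    snarl contents (a tandem-duplication back edge or a hairpin loop)."""
    span = set(contents)
    travs = [(n, o) for n in span for o in (FORWARD, REVERSE)]
    succ: dict[tuple[int, str], list] = {t: [] for t in travs}
    for (x, y) in graph.edges:
        for (exit_s, entry_s) in ((x, y), (y, x)):
            if exit_s[0] not in span or entry_s[0] not in span:
                continue
            out_trav = (exit_s[0], FORWARD if exit_s[1] == RIGHT else REVERSE)
            in_trav = (entry_s[0], FORWARD if entry_s[1] == LEFT else REVERSE)
            succ[out_trav].append(in_trav)
    state: dict[tuple[int, str], int] = {}

    def dfs(t) -> bool:
        state[t] = 1
        for nxt in succ[t]:
            if state.get(nxt) == 1:
                return True
            if nxt not in state and dfs(nxt):
                return True
        state[t] = 2
        return False

    return any(dfs(t) for t in travs if t not in state)
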