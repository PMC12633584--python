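"""Independent oracles used by the test suite.

Everything here is deliberately written against third-party primitives
(networkx connectivity, dense Gotoh DP, exhaustive enumeration) rather
than the package's own data structures, so agreement is evidence of
correctness rather than tautology.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from glite.graph import FORWARD, LEFT, REVERSE, RIGHT, VariationGraph


# ---------------------------------------------------------------------------
# snarl decomposition oracle


def _side_nodes(graph: VariationGraph):
    return [(n, s) for n in sorted(graph.nodes) for s in (LEFT, RIGHT)]


def _edge_list(graph: VariationGraph):
    return list(graph.edges)


def _trav_digraph(graph: VariationGraph) -> nx.DiGraph:
    G = nx.DiGraph()
    for n in graph.nodes:
        G.add_node((n, FORWARD))
        G.add_node((n, REVERSE))
    for (a, b) in graph.edges:
        for exit_s, entry_s in ((a, b), (b, a)):
            u = (exit_s[0], FORWARD if exit_s[1] == RIGHT else REVERSE)
            v = (entry_s[0], FORWARD if entry_s[1] == LEFT else REVERSE)
            G.add_edge(u, v)
    return G


def oracle_separable_pairs(graph: VariationGraph):
    """All strictly separable side pairs with their contents, via networkx.

    For each unordered node pair, the side-split graph (internal edges for
    every other node) is built and its connected components read off."""
    sides = _side_nodes(graph)
    edges = _edge_list(graph)
    nodes = sorted(graph.nodes)
    # MultiGraph: a node's internal side-to-side edge must stay distinct
    # from a real self edge (tandem-duplication back edge) between the
    # same two sides, so cutting a node removes only the internal edge.
    full = nx.MultiGraph()
    full.add_nodes_from(sides)
    for a, b in edges:
        full.add_edge(a, b, key="real")
    for n in nodes:
        full.add_edge((n, LEFT), (n, RIGHT), key="internal")
    found: dict[tuple, frozenset] = {}
    for u, v in itertools.combinations(nodes, 2):
        view = nx.restricted_view(
            full,
            [],
            [
                ((u, LEFT), (u, RIGHT), "internal"),
                ((v, LEFT), (v, RIGHT), "internal"),
            ],
        )
        comps = list(nx.connected_components(view))
        comp_of = {}
        for ci, comp in enumerate(comps):
            for s in comp:
                comp_of[s] = ci
        for sa in ((u, LEFT), (u, RIGHT)):
            for sb in ((v, LEFT), (v, RIGHT)):
                ca = comp_of[sa]
                if comp_of[sb] != ca:
                    continue
                opp_a = (sa[0], RIGHT if sa[1] == LEFT else LEFT)
                opp_b = (sb[0], RIGHT if sb[1] == LEFT else LEFT)
                if comp_of[opp_a] == ca or comp_of[opp_b] == ca:
                    continue
                contents = frozenset(n for n, _ in comps[ca] if n not in (u, v))
                found[(sa, sb)] = contents
    return found


def _oracle_traversable(graph, trav_g: nx.DiGraph, sa, sb, contents) -> bool:
    if graph.has_edge(sa, sb):
        return True
    allowed = {(n, o) for n in contents for o in (FORWARD, REVERSE)}
    sub = trav_g.subgraph(allowed)
    start_travs = [
        (t[0], FORWARD if t[1] == LEFT else REVERSE)
        for t in graph.side_neighbours(sa)
        if t[0] in contents
    ]
    goal_travs = set()
    for t in graph.side_neighbours(sb):
        if t[0] in contents:
            # traversal whose exit side connects to sb
            goal_travs.add((t[0], FORWARD if t[1] == RIGHT else REVERSE))
    for s in start_travs:
        if s in goal_travs:
            return True
        if any(g in nx.descendants(sub, s) for g in goal_travs):
            return True
    return False


def oracle_snarl_set(graph: VariationGraph):
    """The canonical accepted snarl set: separable, traversable, minimal,
    then smallest-first nesting-consistent acceptance."""
    sep = oracle_separable_pairs(graph)
    trav_g = _trav_digraph(graph)
    candidates = []
    for (sa, sb), contents in sep.items():
        if not contents:
            continue
        if not (
            _oracle_traversable(graph, trav_g, sa, sb, contents)
            or _oracle_traversable(graph, trav_g, sb, sa, contents)
        ):
            continue
        minimal = True
        for n in contents:
            for s in ((n, LEFT), (n, RIGHT)):
                for pair in ((sa, s), (s, sa), (s, sb), (sb, s)):
                    if pair in sep:
                        minimal = False
                        break
                if not minimal:
                    break
            if not minimal:
                break
        if minimal:
            a, b = (sa, sb) if (sa[0], sb[0]) <= (sb[0], sa[0]) else (sb, sa)
            candidates.append((a, b, contents))
    candidates.sort(key=lambda t: (len(t[2]), t[0][0], t[1][0], t[0][1], t[1][1]))
    accepted = []
    for sa, sb, contents in candidates:
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
    return sorted((a, b, tuple(sorted(c))) for a, b, c in accepted)


def snarl_set_of_tree(tree) -> list:
    return sorted(
        (s.start_side, s.end_side, tuple(sorted(s.content_nodes)))
        if (s.start_side[0], s.end_side[0]) <= (s.end_side[0], s.start_side[0])
        else (s.end_side, s.start_side, tuple(sorted(s.content_nodes)))
        for s in tree.all_snarls()
    )


# ---------------------------------------------------------------------------
# base-level distance oracle


def base_digraph(graph: VariationGraph) -> nx.DiGraph:
    """One vertex per base per orientation; unit-weight edges."""
    G = nx.DiGraph()
    for n, seq in graph.nodes.items():
        for o in (FORWARD, REVERSE):
            for i in range(len(seq) - 1):
                G.add_edge((n, o, i), (n, o, i + 1))
            G.add_node((n, o, len(seq) - 1))
            G.add_node((n, o, 0))
    for (a, b) in graph.edges:
        for exit_s, entry_s in ((a, b), (b, a)):
            u_node = exit_s[0]
            u_or = FORWARD if exit_s[1] == RIGHT else REVERSE
            v_node = entry_s[0]
            v_or = FORWARD if entry_s[1] == LEFT else REVERSE
            G.add_edge(
                (u_node, u_or, len(graph.nodes[u_node]) - 1), (v_node, v_or, 0)
            )
    return G


def bfs_distance(G: nx.DiGraph, a, b) -> int | None:
    try:
        return nx.shortest_path_length(G, a, b)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return None


# ---------------------------------------------------------------------------
# alignment oracles


def gotoh_global(q: str, t: str, match, mismatch, gap_open, gap_extend) -> int:
    n, m = len(q), len(t)
    NEG = -(10**9)
    H = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    H[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = gap_open + gap_extend * j
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = gap_open + gap_extend * i
        H[i, 0] = F[i, 0]
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open + gap_extend, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open + gap_extend, F[i - 1, j] + gap_extend)
            sub = match if q[i - 1] == t[j - 1] else mismatch
            H[i, j] = max(H[i - 1, j - 1] + sub, E[i, j], F[i, j])
    return int(H[n, m])


def enumerate_paths(graph: VariationGraph, start_key, end_key, max_len: int):
    """All base-level walks from start (inclusive) to end (exclusive)."""

    def succs(key):
        n, o, off = key
        if off + 1 < len(graph.nodes[n]):
            return [(n, o, off + 1)]
        out = []
        from glite.graph import exit_side

        for side in graph.side_neighbours(exit_side((n, o))):
            out.append((side[0], FORWARD if side[1] == LEFT else REVERSE, 0))
        return out

    results = []
    stack = [(start_key, [start_key])]
    while stack:
        key, path = stack.pop()
        if len(path) > max_len:
            continue
        for sk in succs(key):
            if sk == end_key:
                results.append(path)
            else:
                stack.append((sk, path + [sk]))
    return results


def path_spelling(graph: VariationGraph, path) -> str:
    return "".join(
        graph.oriented_sequence((n, o))[off : off + 1] for n, o, off in path
    )


def best_path_alignment(graph, query, start_key, end_key, scoring, max_len):
    """Exhaustive path enumeration + per-path dense DP; the graph-aligner oracle."""
    best = None
    for path in enumerate_paths(graph, start_key, end_key, max_len):
        sc = gotoh_global(
            query,
            path_spelling(graph, path),
            scoring.match,
            scoring.mismatch,
            scoring.gap_open,
            scoring.gap_extend,
        )
        if best is None or sc > best:
            best = sc
    return best


# ---------------------------------------------------------------------------
# chaining oracle


def best_chain_exhaustive(read_offsets, k, dist, params) -> float:
    """Best chain score over all ordered seed subsets (read-offset order)."""
    from glite.chaining import gap_cost

    n = len(read_offsets)
    best = 0.0
    for r in range(1, n + 1):
        for sub in itertools.combinations(range(n), r):
            ok = True
            sc = float(k)
            for a, b in zip(sub, sub[1:]):
                if read_offsets[b] <= read_offsets[a]:
                    ok = False
                    break
                c = gap_cost(read_offsets[b] - read_offsets[a], dist(a, b), params)
                if not math.isfinite(c):
                    ok = False
                    break
                sc += min(k, read_offsets[b] - read_offsets[a]) - c
            if ok and sc > best:
                best = sc
    return best


# ---------------------------------------------------------------------------
# minimizer selection oracle


def naive_minimizers(seq: str, k: int, w: int, order_key):
    """Per-window scan: smallest-key k-mer per window, leftmost on ties."""
    from glite.seeds import _kmer_codes

    entries = {off: canon for off, _, canon, _ in _kmer_codes(seq, k)}
    n_starts = len(seq) - k + 1
    if n_starts <= 0:
        return set()
    selected = set()
    windows = (
        range(n_starts - w + 1) if n_starts >= w else range(1)
    )
    for wstart in windows:
        wend = min(wstart + w, n_starts)
        best = None
        for off in range(wstart, wend):
            if off not in entries:
                continue
            key = order_key(entries[off])
            if best is None or key < best[0]:
                best = (key, off)
        if best is not None:
            selected.add(best[1])
    return selected


def gotoh_global_fast(q: str, t: str, match, mismatch, gap_open, gap_extend) -> int:
    """Row-vectorized Gotoh: identical recurrences to gotoh_global.

    The within-row gap state is solved exactly via a running-maximum
    transform: E[i,j] = ge*j + go + cummax_{j'<j}(G[i,j'] - ge*j')."""
    n, m = len(q), len(t)
    if n == 0 or m == 0:
        if n == m == 0:
            return 0
        return gap_open + gap_extend * max(n, m)
    NEG = -(10**9)
    qv = np.frombuffer(q.encode(), dtype=np.uint8)
    tv = np.frombuffer(t.encode(), dtype=np.uint8)
    j_idx = np.arange(m + 1, dtype=np.int64)
    H_prev = gap_open + gap_extend * j_idx
    H_prev[0] = 0
    F_prev = np.full(m + 1, NEG, dtype=np.int64)
    for i in range(1, n + 1):
        F = np.maximum(H_prev + gap_open + gap_extend, F_prev + gap_extend)
        sub = np.where(tv == qv[i - 1], match, mismatch)
        M = H_prev[:-1] + sub
        G = np.full(m + 1, NEG, dtype=np.int64)
        G[0] = gap_open + gap_extend * i  # leading gap in target
        G[1:] = np.maximum(M, F[1:])
        G[0] = max(G[0], F[0])
        shifted = G - gap_extend * j_idx
        run = np.maximum.accumulate(shifted)
        E = np.full(m + 1, NEG, dtype=np.int64)
        E[1:] = gap_extend * j_idx[1:] + gap_open + run[:-1]
        H = np.maximum(G, E)
        H_prev, F_prev = H, F
    return int(H_prev[m])
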