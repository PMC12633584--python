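"""Minimum-distance queries between oriented base positions in the graph.

Distances are counted in base steps along valid walks: consecutive bases of
a walk are at distance 1 and d(A, A) = 0.  A position is entered in its
orientation, so a reverse position continues leftward through the node.
Unreachable pairs are reported as ``None`` (an explicit sentinel, never a
large magic number).

Queries run on a weighted digraph over oriented node traversals (two
vertices per node); moving from traversal u to traversal v costs the length
of v's node.  Single-source distances are computed with Dijkstra (scipy
compiled sparse-graph routines) and cached, which also covers cycles from
tandem duplications: a minimum distance never benefits from looping twice.
The per-chain prefix sums and per-snarl boundary tables consumed by zip
codes are derived from the same machinery and cached on the index.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .graph import (
    FORWARD,
    LEFT,
    REVERSE,
    RIGHT,
    GraphPosition,
    VariationGraph,
)

__all__ = ["DistanceIndex", "build_distance_index"]

_PRECOMPUTE_TRAV_LIMIT = 6000


class DistanceIndex:
    def __init__(self, graph: VariationGraph, snarl_tree=None):
        self.graph = graph
        self.tree = snarl_tree
        self._nodes = sorted(graph.nodes)
        self._rank = {n: i for i, n in enumerate(self._nodes)}
        self._len = np.array([len(graph.nodes[n]) for n in self._nodes], dtype=np.int64)
        n_trav = 2 * len(self._nodes)
        pairs: set[tuple[int, int]] = set()
        for (a, b) in graph.edges:
            for exit_s, entry_s in ((a, b), (b, a)):
                u = self._trav_id(exit_s[0], FORWARD if exit_s[1] == RIGHT else REVERSE)
                v = self._trav_id(entry_s[0], FORWARD if entry_s[1] == LEFT else REVERSE)
                pairs.add((u, v))
        rows, cols, data = [], [], []
        self._succ: list[list[int]] = [[] for _ in range(n_trav)]
        for u, v in sorted(pairs):
            rows.append(u)
            cols.append(v)
            data.append(int(self._len[v >> 1]))
            self._succ[u].append(v)
        self._csr = csr_matrix(
            (data, (rows, cols)), shape=(n_trav, n_trav), dtype=np.float64
        )
        self._rows: dict[int, np.ndarray] = {}
        self._all: np.ndarray | None = None
        # caches filled lazily for the zip-code layer
        self._chain_prefix: dict[int, dict[int, int]] = {}

    # -- plumbing ------------------------------------------------------

    def _trav_id(self, node_id: int, orientation: str) -> int:
        return self._rank[node_id] * 2 + (0 if orientation == FORWARD else 1)

    def node_length(self, node_id: int) -> int:
        return int(self._len[self._rank[node_id]])

    def precompute_all(self) -> None:
        """All-pairs traversal distances; worthwhile when mapping many reads."""
        if self._all is None and self._csr.shape[0] <= _PRECOMPUTE_TRAV_LIMIT:
            self._all = dijkstra(self._csr, directed=True)

    def _row(self, u: int) -> np.ndarray:
        if self._all is not None:
            return self._all[u]
        row = self._rows.get(u)
        if row is None:
            row = dijkstra(self._csr, directed=True, indices=u)
            self._rows[u] = row
        return row

    # -- queries -------------------------------------------------------

    def min_distance(self, a: GraphPosition, b: GraphPosition) -> int | None:
        """Exact minimum base-step distance from position a to position b."""
        for p in (a, b):
            if p.node_id not in self._rank:
                raise KeyError(f"unknown node {p.node_id}")
            if not 0 <= p.offset < self.node_length(p.node_id):
                raise ValueError(f"offset out of range in {p}")
        ua = self._trav_id(a.node_id, a.orientation)
        ub = self._trav_id(b.node_id, b.orientation)
        len_a = self.node_length(a.node_id)
        len_b = self.node_length(b.node_id)
        best = np.inf
        if ua == ub:
            if b.offset >= a.offset:
                best = b.offset - a.offset
            # re-reaching the same traversal needs a loop through the graph
            loop = np.inf
            for v in self._succ[ua]:
                loop = min(loop, self._len[v >> 1] + self._row(v)[ua])
            best = min(best, (len_a - a.offset) + (loop - len_a) + b.offset)
        else:
            through = self._row(ua)[ub]
            best = min(best, (len_a - a.offset) + (through - len_b) + b.offset)
        return None if np.isinf(best) else int(best)

    def side_gap(self, from_side: tuple[int, str], to_side: tuple[int, str]) -> int | None:
        """Bases strictly between two facing node sides along a shortest walk."""
        d = self.min_distance(self.pos_leaving(from_side), self.pos_arriving(to_side))
        return None if d is None else d - 1

    def pos_leaving(self, side: tuple[int, str]) -> GraphPosition:
        """The last base of a traversal that exits through ``side``."""
        n, s = side
        ln = self.node_length(n)
        return GraphPosition(n, FORWARD if s == RIGHT else REVERSE, ln - 1)

    def pos_arriving(self, side: tuple[int, str]) -> GraphPosition:
        """The first base of a traversal that enters through ``side``."""
        n, s = side
        return GraphPosition(n, FORWARD if s == LEFT else REVERSE, 0)

    # -- snarl-tree derived tables ------------------------------------

    def chain_prefix(self, chain) -> dict[int, int]:
        """Node id -> offset of the node's first base from the chain start.

        Offsets are measured along the chain's canonical traversal
        direction and include minimum spans through intervening snarls, so
        they strictly increase along the chain (acyclic chains)."""
        key = id(chain)
        if key not in self._chain_prefix:
            node_items = chain.node_items()
            first, first_o = node_items[0]
            start = GraphPosition(first, first_o, 0)
            prefix: dict[int, int] = {}
            for n, o in node_items:
                d = self.min_distance(start, GraphPosition(n, o, 0))
                prefix[n] = -1 if d is None else d
            self._chain_prefix[key] = prefix
        return self._chain_prefix[key]


def build_distance_index(graph: VariationGraph, snarl_tree=None) -> DistanceIndex:
    return DistanceIndex(graph, snarl_tree)
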