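"""Zip codes and zip code trees: ordered seeds with traversal distances.

A *zip code* is the snarl-tree address of a graph position: its chain/snarl
ancestry from the root, annotated with prefix-sum offsets along chains and
distances from child chains to snarl boundaries.  Sorting seeds by zip code
lays them out along an unrolled, acyclic view of the graph.

A *zip code tree* arranges one read's seeds in that order, bracketing the
seeds contained in each snarl/chain, so that the minimum graph distance
between any two seeds can be accumulated in a single traversal: seed-to-seed
hops within a chain, and boundary-anchor hops across snarls.  Seeds on
sibling chains of one snarl (alternative alleles) are mutually unreachable
in the traversal.  On acyclic graphs with consistently oriented seeds the
traversal distances are exact; on cyclic or inverted regions they never
under-report the true minimum (each hop is itself a minimum distance, so
accumulated sums obey the triangle inequality).

Seeds whose global orientation conflicts with a tree's traversal direction,
or that lie on a different root chain, are split into separate trees of the
forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

from .graph import (
    GraphPosition,
    entry_side,
    exit_side,
    flip_oriented,
)
from .distance import DistanceIndex
from .seeds import SeedHit
from .snarls import Snarl, SnarlChain, SnarlTree

__all__ = [
    "ZipCode",
    "ZipCodeForest",
    "ZipTree",
    "compute_zipcode",
    "build_zip_forest",
    "iter_seed_distances",
]


@dataclass
class ChainLevel:
    chain: SnarlChain
    offset: int  # prefix-sum offset of the child's start within the chain
    rank: int  # child item rank in the chain


@dataclass
class SnarlLevel:
    snarl: Snarl
    chain_rank: int
    # gaps (intervening bases) from the child chain's two ends to the
    # snarl's two boundaries: (start->chain entry, chain exit->end,
    # start->reversed entry, reversed exit->end); None where unreachable
    boundary_distances: tuple


@dataclass
class LeafLevel:
    node_id: int
    length: int
    offset: int  # in the chain's canonical traversal direction
    forward: bool  # position orientation agrees with the chain direction


@dataclass
class ZipCode:
    levels: list  # root-first: ChainLevel / SnarlLevel alternating, LeafLevel last

    @property
    def leaf(self) -> LeafLevel:
        return self.levels[-1]


def _chain_orientation_of(chain: SnarlChain, node_id: int) -> str:
    for n, o in chain.node_items():
        if n == node_id:
            return o
    raise KeyError(node_id)


def _chain_rank_maps(chain: SnarlChain):
    node_rank: dict[int, int] = {}
    snarl_rank: dict[int, int] = {}
    for i, (kind, payload) in enumerate(chain.items):
        if kind == "node":
            node_rank[payload[0]] = i
        else:
            snarl_rank[id(payload)] = i
    return node_rank, snarl_rank


def _chain_alignment_in_snarl(graph, snarl: Snarl, chain: SnarlChain) -> bool:
    """True when the chain's canonical direction runs start->end boundary."""
    first = chain.node_items()[0]
    last = chain.node_items()[-1]
    if graph.has_edge(snarl.start_side, entry_side(first)):
        return True
    if graph.has_edge(snarl.start_side, entry_side(flip_oriented(last))):
        return False
    return True


def compute_zipcode(
    position: GraphPosition, tree: SnarlTree, dindex: DistanceIndex
) -> ZipCode:
    """Snarl-tree address of a position, root level first."""
    graph = tree.graph
    ancestry = tree.ancestry(position.node_id)  # innermost chain first
    levels: list = []
    # walk root-first; ancestry alternates chain, snarl, chain, ...
    path = list(reversed(ancestry))
    for i, element in enumerate(path):
        if isinstance(element, SnarlChain):
            chain = element
            node_rank, snarl_rank = _chain_rank_maps(chain)
            prefix = dindex.chain_prefix(chain)
            child = path[i + 1] if i + 1 < len(path) else None
            if child is None:  # leaf chain level: child is the node itself
                rank = node_rank[position.node_id]
                levels.append(ChainLevel(chain, prefix[position.node_id], rank))
            else:
                rank = snarl_rank[id(child)]
                prev_id = chain.items[rank - 1][1][0]
                offset = prefix[prev_id] + dindex.node_length(prev_id)
                levels.append(ChainLevel(chain, offset, rank))
        else:
            snarl = element
            child_chain = path[i + 1]
            chain_rank = next(
                j for j, c in enumerate(snarl.children) if c is child_chain
            )
            first = child_chain.node_items()[0]
            last = child_chain.node_items()[-1]
            bd = (
                dindex.side_gap(snarl.start_side, entry_side(first)),
                dindex.side_gap(exit_side(last), snarl.end_side),
                dindex.side_gap(snarl.start_side, entry_side(flip_oriented(last))),
                dindex.side_gap(exit_side(flip_oriented(first)), snarl.end_side),
            )
            levels.append(SnarlLevel(snarl, chain_rank, bd))
    chain = ancestry[0]
    o_c = _chain_orientation_of(chain, position.node_id)
    length = dindex.node_length(position.node_id)
    forward = position.orientation == o_c
    offset = position.offset if forward else length - 1 - position.offset
    levels.append(LeafLevel(position.node_id, length, offset, forward))
    return ZipCode(levels)


def _sort_key(zip_code: ZipCode) -> tuple:
    key: list[int] = []
    for lvl in zip_code.levels:
        if isinstance(lvl, ChainLevel):
            key.extend((lvl.offset, lvl.rank))
        elif isinstance(lvl, SnarlLevel):
            key.append(lvl.chain_rank)
        else:
            key.extend((lvl.offset, 0 if lvl.forward else 1))
    return tuple(key)


def _global_forward(zip_code: ZipCode, graph) -> bool:
    """Orientation of the seed's travel along the root chain."""
    fwd = zip_code.leaf.forward
    path = zip_code.levels
    for i, lvl in enumerate(path):
        if isinstance(lvl, SnarlLevel):
            snarl = lvl.snarl
            child_chain = snarl.children[lvl.chain_rank]
            if not _chain_alignment_in_snarl(graph, snarl, child_chain):
                fwd = not fwd
            # snarl orientation within its parent chain
            parent = path[i - 1]
            prev_trav = parent.chain.items[parent.rank - 1][1]
            if exit_side(prev_trav) != snarl.start_side:
                fwd = not fwd
    return fwd


# -- zip tree structure ------------------------------------------------


@dataclass
class ZSeed:
    seed: SeedHit
    pos: GraphPosition
    key: tuple = ()
    address: tuple = ()  # ((container, rank), ...) root-first


@dataclass
class ZSnarlBlock:
    snarl: Snarl
    entry_anchor: GraphPosition  # last base before entering, travel orientation
    exit_anchor: GraphPosition  # first base after leaving, travel orientation
    chains: list[list] = field(default_factory=list)  # per child chain, elements


class _ScanDone(Exception):
    pass


class ZipTree:
    """One tree of the forest: elements of the root chain in travel order."""

    def __init__(self, strand: str, elements: list, dindex: DistanceIndex):
        self.strand = strand
        self.elements = elements
        self.dindex = dindex
        self.seeds: list[ZSeed] = []
        self._index_of: dict[int, int] = {}
        self._collect(elements)
        self._fwd_cache: dict[int, dict[int, int | None]] = {}

    def _collect(self, elements: list) -> None:
        for e in elements:
            if isinstance(e, ZSeed):
                self._index_of[id(e)] = len(self.seeds)
                self.seeds.append(e)
            else:
                for chain_elems in e.chains:
                    self._collect(chain_elems)

    # -- traversal ------------------------------------------------------

    def _advance(self, cur: GraphPosition, dist: int | None, pos: GraphPosition):
        if dist is None:
            return None
        d = self.dindex.min_distance(cur, pos)
        return None if d is None else dist + d

    def _walk(self, elements: list, start: int, cur: GraphPosition, dist, out: list,
              limit: int | None):
        """Scan elements[start:] accumulating distances from the source seed."""
        for e in elements[start:]:
            if limit is not None and len(out) >= limit:
                raise _ScanDone
            if isinstance(e, ZSeed):
                d = self._advance(cur, dist, e.pos)
                out.append((e, d))
                if d is not None:
                    cur, dist = e.pos, d
            else:
                for chain_elems in e.chains:  # siblings isolated: same origin
                    self._walk(chain_elems, 0, cur, dist, out, limit)
                d = self._advance(cur, dist, e.exit_anchor)
                if d is not None:
                    cur, dist = e.exit_anchor, d
                else:
                    dist = None  # beyond an uncrossable snarl: unreachable
        return cur, dist

    def _locate(self, zseed: ZSeed):
        """Path of (elements_list, index, enclosing block or None) to the seed."""

        def rec(elements, trail):
            for i, e in enumerate(elements):
                if e is zseed:
                    return trail + [(elements, i, None)]
                if isinstance(e, ZSnarlBlock):
                    for ci, chain_elems in enumerate(e.chains):
                        r = rec(chain_elems, trail + [(elements, i, (e, ci))])
                        if r is not None:
                            return r
            return None

        path = rec(self.elements, [])
        if path is None:
            raise KeyError("seed not in this tree")
        return path

    def forward_distances(self, zseed: ZSeed, limit: int | None = None) -> dict[int, int | None]:
        """Tree-order scan: seed index -> distance from zseed (None = unreachable).

        With ``limit`` the scan stops after that many following seeds (seeds
        beyond it are simply absent from the result)."""
        key = self._index_of[id(zseed)]
        cached = self._fwd_cache.get(key)
        if cached is not None:
            full, result = cached
            if full or (limit is not None and len(result) >= limit):
                return result
        out: list[tuple[ZSeed, int | None]] = []
        path = self._locate(zseed)
        full = True
        try:
            # continue after the seed in its own list, then unwind through
            # enclosing snarl blocks; later sibling chains are unreachable
            elements, idx, _ = path[-1]
            cur, dist = self._walk(elements, idx + 1, zseed.pos, 0, out, limit)
            for depth in range(len(path) - 2, -1, -1):
                elements, idx, ctx = path[depth]
                block, chain_idx = ctx
                for later in block.chains[chain_idx + 1 :]:
                    for e in _iter_zseeds(later):
                        if limit is not None and len(out) >= limit:
                            raise _ScanDone
                        out.append((e, None))
                d = self._advance(cur, dist, block.exit_anchor)
                if d is not None:
                    cur, dist = block.exit_anchor, d
                else:
                    dist = None
                cur, dist = self._walk(elements, idx + 1, cur, dist, out, limit)
        except _ScanDone:
            full = False
        result = {self._index_of[id(e)]: d for e, d in out}
        self._fwd_cache[key] = (full, result)
        return result


def _iter_zseeds(elements: list):
    for e in elements:
        if isinstance(e, ZSeed):
            yield e
        else:
            for chain_elems in e.chains:
                yield from _iter_zseeds(chain_elems)


@dataclass
class ZipCodeForest:
    trees: list[ZipTree]

    def all_seeds(self) -> list[ZSeed]:
        return [z for t in self.trees for z in t.seeds]


def build_zip_forest(
    seeds: list[SeedHit], tree: SnarlTree, dindex: DistanceIndex
) -> ZipCodeForest:
    """Sort seeds by zip code and bracket them into per-strand zip trees."""
    if not seeds:
        return ZipCodeForest([])
    graph = tree.graph
    annotated: list[tuple] = []  # (root_chain, strand, key, zseed)
    for seed in seeds:
        zc = compute_zipcode(seed.position, tree, dindex)
        root_chain = zc.levels[0].chain
        strand = "+" if _global_forward(zc, graph) else "-"
        address = _address_of(zc)
        zs = ZSeed(seed, seed.position, _sort_key(zc) + (seed.read_offset,), address)
        annotated.append((root_chain, strand, zs))

    groups: dict[tuple[int, str], list[ZSeed]] = {}
    chain_obj: dict[int, SnarlChain] = {}
    for root_chain, strand, zs in annotated:
        chain_obj[id(root_chain)] = root_chain
        groups.setdefault((id(root_chain), strand), []).append(zs)

    trees = []
    for (chain_id, strand) in sorted(
        groups, key=lambda k: (min(chain_obj[k[0]].node_ids()), k[1])
    ):
        zseeds = sorted(groups[(chain_id, strand)], key=lambda z: z.key)
        root = chain_obj[chain_id]
        elements = _build_chain_elements(
            graph, dindex, root, zseeds, depth=0, reverse=(strand == "-")
        )
        trees.append(ZipTree(strand, elements, dindex))
    return ZipCodeForest(trees)


def _address_of(zc: ZipCode) -> tuple:
    addr = []
    for lvl in zc.levels:
        if isinstance(lvl, ChainLevel):
            addr.append(lvl.rank)
        elif isinstance(lvl, SnarlLevel):
            addr.append(lvl.chain_rank)
    return tuple(addr)


def _build_chain_elements(
    graph, dindex: DistanceIndex, chain: SnarlChain, zseeds: list[ZSeed], depth: int, reverse: bool
) -> list:
    """Group sorted seeds by chain item and recurse into snarl blocks."""
    grouped = [
        (rank, list(grp))
        for rank, grp in groupby(zseeds, key=lambda z: z.address[depth])
    ]
    if reverse:
        grouped = [(rank, list(reversed(grp))) for rank, grp in reversed(grouped)]
    elements: list = []
    for rank, grp in grouped:
        kind, payload = chain.items[rank]
        if kind == "node":
            elements.extend(grp)
            continue
        snarl: Snarl = payload
        trav_entry, trav_exit = _snarl_travel_sides(chain, rank, snarl, reverse)
        block = ZSnarlBlock(
            snarl,
            entry_anchor=dindex.pos_leaving(trav_entry),
            exit_anchor=dindex.pos_arriving(trav_exit),
        )
        for chain_rank, sub in groupby(grp, key=lambda z: z.address[depth + 1]):
            child = snarl.children[chain_rank]
            sub = list(sub)
            aligned = _chain_entry_alignment(graph, child, trav_entry)
            block.chains.append(
                _build_chain_elements(
                    graph, dindex, child, sub, depth + 2, reverse=not aligned
                )
            )
        elements.append(block)
    return elements


def _snarl_travel_sides(chain: SnarlChain, rank: int, snarl: Snarl, reverse: bool):
    if not reverse:
        prev_trav = chain.items[rank - 1][1]
        entry = exit_side(prev_trav)
    else:
        nxt_trav = chain.items[rank + 1][1]
        entry = entry_side(nxt_trav)
    exit_ = snarl.end_side if entry == snarl.start_side else snarl.start_side
    return entry, exit_


def _chain_entry_alignment(graph, chain: SnarlChain, travel_entry_side) -> bool:
    """True when the chain's canonical direction is entered from travel entry."""
    first = chain.node_items()[0]
    last = chain.node_items()[-1]
    if graph.has_edge(travel_entry_side, entry_side(first)):
        return True
    if graph.has_edge(travel_entry_side, entry_side(flip_oriented(last))):
        return False
    return True


def iter_seed_distances(tree: ZipTree, zseed: ZSeed, direction: str = "forward"):
    """Yield (other seed, minimum distance) in tree order from ``zseed``.

    Forward yields seeds after ``zseed``; backward yields seeds before it,
    with the distance measured from the earlier seed to ``zseed`` (the
    direction a chaining transition would take)."""
    my_idx = tree._index_of[id(zseed)]
    if direction == "forward":
        dists = tree.forward_distances(zseed)
        for j in range(my_idx + 1, len(tree.seeds)):
            yield tree.seeds[j], dists.get(j)
    elif direction == "backward":
        for i in range(my_idx - 1, -1, -1):
            other = tree.seeds[i]
            yield other, tree.forward_distances(other).get(my_idx)
    else:
        raise ValueError("direction must be 'forward' or 'backward'")


def dump_forest(forest: ZipCodeForest, stream) -> None:
    """Indented text rendering of each tree with element anchors."""

    def rec(elements, indent):
        for e in elements:
            if isinstance(e, ZSeed):
                p = e.pos
                stream.write(
                    f"{'  ' * indent}seed read@{e.seed.read_offset} "
                    f"({p.node_id}{p.orientation}{p.offset})\n"
                )
            else:
                s = e.snarl
                stream.write(
                    f"{'  ' * indent}snarl {s.start_side}->{s.end_side}\n"
                )
                for ci, chain_elems in enumerate(e.chains):
                    stream.write(f"{'  ' * (indent + 1)}chain #{ci}\n")
                    rec(chain_elems, indent + 2)

    for t in forest.trees:
        stream.write(f"tree strand={t.strand} n_seeds={len(t.seeds)}\n")
        rec(t.elements, 1)
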