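"""Co-linear chaining of seeds by dynamic programming.

A chain is an ordered subset of seeds that strictly increases in read
offset and is graph-reachable seed to seed (distances come from the zip
code tree traversal).  The objective is covered read bases minus gap costs,
where the gap of a transition is the absolute difference between its read
distance and its graph distance, priced like minimap2's gap penalty:
``a*g + b*log2(g)`` (zero when the two distances agree, infinite when the
graph distance is unreachable or the gap exceeds ``max_gap``).

The DP is exact over each zip tree's seed order: seed coverage is trimmed
by read overlap with the chosen predecessor, so the recurrence

    score(j) = max(k, max_i score(i) + min(k, r_j - r_i) - gap_cost(i, j))

maximizes covered bases minus gap cost over all admissible chains.  A
production-style fragment pre-pass is deliberately not used to prune the
DP: at the seed counts a single read produces it buys little and can break
optimality; instead, maximal zero-gap runs are reported as fragments of
the finished chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

__all__ = ["ChainingParams", "ChainResult", "Fragment", "gap_cost", "chain_seeds", "chain_forest"]


@dataclass
class ChainingParams:
    gap_scale: float = 0.19  # 'a': 0.01 x k for the default k of 19
    gap_log_scale: float = 0.5  # 'b'
    max_lookback: int = 64  # candidate predecessors per seed (tree order)
    max_gap: int = 10_000  # gap beyond which a transition is forbidden
    fragment_max_gap: int = 200  # read-step bound when reporting fragments
    top_chains: int = 4

    def validate(self) -> None:
        for name in ("gap_scale", "gap_log_scale", "max_lookback", "max_gap",
                     "fragment_max_gap", "top_chains"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def gap_cost(read_gap: int, graph_gap: int | None, params: ChainingParams) -> float:
    """Cost of transitioning between consecutive chained seeds."""
    if read_gap < 0:
        raise ValueError("read_gap must be non-negative")
    if graph_gap is None:
        return math.inf
    g = abs(read_gap - graph_gap)
    if g == 0:
        return 0.0
    if g > params.max_gap:
        return math.inf
    return params.gap_scale * g + params.gap_log_scale * math.log2(g)


@dataclass
class Fragment:
    indices: list[int]
    read_start: int
    read_end: int
    score: float


@dataclass
class ChainResult:
    indices: list[int]  # positions in the tree's seed order
    seeds: list  # the chained seed objects, in order
    score: float
    read_start: int
    read_end: int
    coverage: int  # covered read bases
    transitions: list[tuple[int, int | None]]  # (read_gap, graph_gap) per step
    tree: object = None

    def fragments(self, params: ChainingParams) -> list[Fragment]:
        """Maximal zero-gap runs of the chain (exact co-linear stretches)."""
        out: list[Fragment] = []
        run = [0]
        for t, (rg, gg) in enumerate(self.transitions):
            if gg is not None and rg == gg and rg <= params.fragment_max_gap:
                run.append(t + 1)
            else:
                out.append(run)
                run = [t + 1]
        out.append(run)
        frags = []
        for run_idx in out:
            sub = [self.seeds[i] for i in run_idx]
            frags.append(
                Fragment(
                    [self.indices[i] for i in run_idx],
                    sub[0].read_offset,
                    sub[-1].read_offset,
                    float(len(sub)),
                )
            )
        return frags


def chain_seeds(
    read_offsets: list[int],
    k: int,
    dist: Callable[[int, int], int | None],
    params: ChainingParams | None = None,
) -> tuple[list[tuple[float, list[int], list[tuple[int, int | None]]]], float]:
    """Exact chaining DP over seeds given in graph (tree) order.

    ``dist(i, j)`` is the minimum graph distance from seed i to seed j for
    i < j, or None when unreachable.  Returns ``(results, competitor)``:
    up to ``top_chains`` results as (score, indices, transitions), best
    first, whose read intervals overlap pairwise by at most 50% of the
    shorter interval; and the best score among chains that were suppressed
    by that overlap rule while sharing no seed with any accepted chain —
    genuine alternative placements of the same read stretch, which mapping
    quality must treat as competitors even though they are not reported.
    """
    params = params or ChainingParams()
    params.validate()
    n = len(read_offsets)
    if n == 0:
        return [], 0.0
    score = [float(k)] * n
    back: list[int | None] = [None] * n
    for j in range(n):
        r_j = read_offsets[j]
        lo = max(0, j - params.max_lookback)
        for i in range(lo, j):
            r_i = read_offsets[i]
            if r_j <= r_i:
                continue
            d = dist(i, j)
            cost = gap_cost(r_j - r_i, d, params)
            if not math.isfinite(cost):
                continue
            cand = score[i] + min(k, r_j - r_i) - cost
            if cand > score[j] or (
                cand == score[j] and back[j] is not None and i < back[j]
            ):
                score[j] = cand
                back[j] = i
    order = sorted(range(n), key=lambda j: (-score[j], read_offsets[j], j))
    results = []
    taken: list[tuple[int, int]] = []
    used_seeds: set[int] = set()
    competitor = 0.0
    for end in order:
        if len(results) >= params.top_chains:
            break
        idx = []
        j: int | None = end
        while j is not None:
            idx.append(j)
            j = back[j]
        idx.reverse()
        start_r, end_r = read_offsets[idx[0]], read_offsets[idx[-1]] + k
        span = end_r - start_r
        overlap_ok = True
        for s, e in taken:
            ov = min(e, end_r) - max(s, start_r)
            if ov > 0.5 * min(span, e - s):
                overlap_ok = False
                break
        if not overlap_ok:
            if not (set(idx) & used_seeds) and score[end] > competitor:
                competitor = score[end]
            continue
        transitions = [
            (read_offsets[b] - read_offsets[a], dist(a, b))
            for a, b in zip(idx, idx[1:])
        ]
        results.append((score[end], idx, transitions))
        taken.append((start_r, end_r))
        used_seeds.update(idx)
    return results, competitor


def chain_forest(
    forest, k: int, params: ChainingParams | None = None
) -> tuple[list[ChainResult], float]:
    """Chain every tree of a zip forest; rank results across trees.

    Returns (ranked chains, competitor score) where the competitor is the
    best suppressed alternative-placement chain across all trees."""
    params = params or ChainingParams()
    out: list[ChainResult] = []
    competitor = 0.0
    for tree in forest.trees:
        seeds = tree.seeds
        if not seeds:
            continue
        offsets = [z.seed.read_offset for z in seeds]

        def dist(i: int, j: int, _tree=tree, _seeds=seeds) -> int | None:
            return _tree.forward_distances(_seeds[i], limit=params.max_lookback).get(j)

        results, tree_comp = chain_seeds(offsets, k, dist, params)
        competitor = max(competitor, tree_comp)
        for sc, idx, transitions in results:
            chained = [seeds[i].seed for i in idx]
            coverage = k + sum(min(k, rg) for rg, _ in transitions)
            out.append(
                ChainResult(
                    indices=idx,
                    seeds=chained,
                    score=sc,
                    read_start=chained[0].read_offset,
                    read_end=chained[-1].read_offset + k,
                    coverage=coverage,
                    transitions=transitions,
                    tree=tree,
                )
            )
    out.sort(key=lambda c: (-c.score, c.read_start, -(c.read_end - c.read_start)))
    return out[: params.top_chains], competitor
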