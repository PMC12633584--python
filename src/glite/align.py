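"""Base-level alignment: wavefronts on haplotypes, banded DP on the graph.

A finished chain is turned into a full alignment in three kinds of pieces:

* between consecutive seeds, the read segment is aligned to the haplotype
  spellings consistent with both flanking seeds using a gap-affine
  wavefront algorithm (WFA) whose cost grows with the error of the
  alignment, not its length;
* when no haplotype spans a segment, or the wavefront declares failure or
  the problem is too large, a banded global aligner runs directly on the
  graph over a layer-unrolled subgraph between the two seed positions;
* the read tails beyond the first and last seed are aligned with anchored
  wavefronts against haplotype continuations, falling back to an X-drop
  extension over the graph, soft-clipping whatever does not extend.

Scoring is classic long-read practice: match +1, mismatch -4, gap open -6,
gap extend -1.  The WFA runs in cost space (mismatch 2(m-x)=10, gap open
-2*go=12, extend m-2*ge=3 for those defaults) and converts back via
score = (m*(|q|+|t|) - cost)/2, which is exact for gap-affine scores.

Edits use ops '=' (match), 'X' (mismatch), 'I' (read base absent from the
graph) and 'D' (graph base absent from the read), run-length merged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import (
    FORWARD,
    LEFT,
    REVERSE,
    GraphPosition,
    VariationGraph,
    entry_side,
    exit_side,
)

__all__ = [
    "ScoringParams",
    "WFAResult",
    "GraphAlignment",
    "wfa_align",
    "banded_graph_global",
    "xdrop_tail",
    "extend_chain",
    "score_edits",
]


@dataclass
class ScoringParams:
    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    xdrop: int = 20
    band_padding: int = 10
    wfa_max_len: int = 8192  # above this, go straight to the graph aligner
    wfa_max_cost: int = 6000  # wavefront-count proxy for memory; exceed = failure

    def validate(self) -> None:
        if self.match <= 0:
            raise ValueError("match must be positive")
        for name in ("mismatch", "gap_open", "gap_extend"):
            if getattr(self, name) > 0:
                raise ValueError(f"{name} must be <= 0")

    # cost-space constants (doubled to stay integral)
    @property
    def x2(self) -> int:
        return 2 * (self.match - self.mismatch)

    @property
    def o2(self) -> int:
        return -2 * self.gap_open

    @property
    def e2(self) -> int:
        return self.match - 2 * self.gap_extend


def merge_edits(edits: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, ln in edits:
        if ln == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def score_edits(edits: list[tuple[str, int]], scoring: ScoringParams) -> int:
    """Re-score an edit list from scratch (the invariant check used in tests)."""
    s = 0
    for op, ln in edits:
        if op == "=":
            s += scoring.match * ln
        elif op == "X":
            s += scoring.mismatch * ln
        elif op in "ID":
            s += scoring.gap_open + scoring.gap_extend * ln
        else:
            raise ValueError(f"unknown op {op!r}")
    return s


@dataclass
class WFAResult:
    ok: bool
    score: int
    edits: list[tuple[str, int]]
    query_end: int = 0  # query bases consumed (anchored mode)
    target_end: int = 0


def wfa_align(
    query: str,
    target: str,
    scoring: ScoringParams | None = None,
    mode: str = "global",
    max_cost: int | None = None,
) -> WFAResult:
    """Gap-affine wavefront alignment in cost space.

    ``global`` aligns both sequences end to end with the optimal gap-affine
    score.  ``anchored_prefix`` pins (0, 0) and returns the best-scoring
    partial alignment ending in a match/mismatch anywhere, for tails.
    Exceeding the cost budget is a declared failure (ok=False), the cue for
    the caller to fall back to the graph aligner.
    """
    scoring = scoring or ScoringParams()
    scoring.validate()
    if max_cost is None:
        max_cost = scoring.wfa_max_cost
    q, t = query, target
    n, m = len(q), len(t)
    x2, o2, e2 = scoring.x2, scoring.o2, scoring.e2
    ms = scoring.match

    if mode not in ("global", "anchored_prefix"):
        raise ValueError("mode must be 'global' or 'anchored_prefix'")
    if n == 0 or m == 0:
        if mode == "anchored_prefix":
            return WFAResult(True, 0, [], 0, 0)
        ln = max(n, m)
        edits = [("I" if n else "D", ln)] if ln else []
        return WFAResult(True, score_edits(edits, scoring) if edits else 0, edits, n, m)

    def extend(k: int, h: int) -> int:
        v = h - k
        while h < n and v < m and q[h] == t[v]:
            h += 1
            v += 1
        return h

    # wavefronts[s] = {'M': {k: h}, 'I': ..., 'D': ...}
    M: dict[int, dict[int, int]] = {}
    I: dict[int, dict[int, int]] = {}
    D: dict[int, dict[int, int]] = {}
    prov: dict[tuple[str, int, int], tuple] = {}  # (comp, s, k) -> (op, pre-ext h)

    h0 = extend(0, 0)
    M[0] = {0: h0}
    prov[("M", 0, 0)] = ("start", 0)
    k_goal = n - m

    best2 = None  # anchored: best doubled score and its cell
    best_cell = None

    def consider_best(s: int, k: int, h: int) -> None:
        nonlocal best2, best_cell
        v = h - k
        sc2 = ms * (h + v) - s
        if best2 is None or sc2 > best2:
            best2 = sc2
            best_cell = (s, k, h)

    if mode == "anchored_prefix":
        consider_best(0, 0, h0)
    if mode == "global" and k_goal in M[0] and M[0][k_goal] >= n:
        return _wfa_traceback(q, t, scoring, M, I, D, prov, 0, k_goal, mode="global")

    s = 0
    while True:
        s += 1
        if s > max_cost:
            if mode == "anchored_prefix" and best_cell is not None:
                return _wfa_traceback(q, t, scoring, M, I, D, prov, best_cell[0], best_cell[1], mode="anchored")
            return WFAResult(False, 0, [])
        new_M: dict[int, int] = {}
        new_I: dict[int, int] = {}
        new_D: dict[int, int] = {}
        src_open = M.get(s - o2 - e2, {})
        src_iext = I.get(s - e2, {})
        src_dext = D.get(s - e2, {})
        src_mm = M.get(s - x2, {})
        ks: set[int] = set()
        ks.update(k + 1 for k in src_open)
        ks.update(k + 1 for k in src_iext)
        ks.update(k - 1 for k in src_open)
        ks.update(k - 1 for k in src_dext)
        ks.update(src_mm)
        for k in ks:
            # insertion: consume query, k increases
            cand_i = None
            if (k - 1) in src_open:
                cand_i = (src_open[k - 1] + 1, ("I_open", src_open[k - 1]))
            if (k - 1) in src_iext:
                h = src_iext[k - 1] + 1
                if cand_i is None or h > cand_i[0]:
                    cand_i = (h, ("I_ext", src_iext[k - 1]))
            if cand_i is not None and 0 <= cand_i[0] <= n and 0 <= cand_i[0] - k <= m:
                new_I[k] = cand_i[0]
                prov[("I", s, k)] = cand_i[1]
            # deletion: consume target, k decreases
            cand_d = None
            if (k + 1) in src_open:
                cand_d = (src_open[k + 1], ("D_open", src_open[k + 1]))
            if (k + 1) in src_dext:
                h = src_dext[k + 1]
                if cand_d is None or h > cand_d[0]:
                    cand_d = (h, ("D_ext", src_dext[k + 1]))
            if cand_d is not None and 0 <= cand_d[0] <= n and 0 <= cand_d[0] - k <= m:
                new_D[k] = cand_d[0]
                prov[("D", s, k)] = cand_d[1]
            # match state: mismatch step or close a gap
            cand_m = None
            if k in src_mm and src_mm[k] + 1 <= n and src_mm[k] + 1 - k <= m:
                cand_m = (src_mm[k] + 1, ("X", src_mm[k]))
            if k in new_I and (cand_m is None or new_I[k] > cand_m[0]):
                cand_m = (new_I[k], ("from_I", new_I[k]))
            if k in new_D and (cand_m is None or new_D[k] > cand_m[0]):
                cand_m = (new_D[k], ("from_D", new_D[k]))
            if cand_m is not None:
                h_pre = cand_m[0]
                h_ext = extend(k, h_pre)
                new_M[k] = h_ext
                prov[("M", s, k)] = cand_m[1]
                if mode == "anchored_prefix":
                    consider_best(s, k, h_ext)
        if new_M:
            M[s] = new_M
        if new_I:
            I[s] = new_I
        if new_D:
            D[s] = new_D
        if mode == "global" and k_goal in new_M and new_M[k_goal] >= n:
            return _wfa_traceback(q, t, scoring, M, I, D, prov, s, k_goal, mode="global")
        if mode == "anchored_prefix":
            # optimistic bound: remaining bases could all match
            can_improve = False
            for k, h in new_M.items():
                v = h - k
                if ms * (h + v) - s + 2 * ms * min(n - h, m - v) > best2:
                    can_improve = True
                    break
            if not (can_improve or new_I or new_D) or (
                not new_M and not new_I and not new_D
            ):
                return _wfa_traceback(
                    q, t, scoring, M, I, D, prov, best_cell[0], best_cell[1], mode="anchored"
                )


def _wfa_traceback(q, t, scoring, M, I, D, prov, s_end, k_end, mode) -> WFAResult:
    n, m = len(q), len(t)
    x2, o2, e2 = scoring.x2, scoring.o2, scoring.e2
    edits_rev: list[tuple[str, int]] = []
    comp, s, k = "M", s_end, k_end
    h = M[s][k]
    while True:
        if comp == "M":
            op, h_pre = prov[("M", s, k)]
            run = h - (h_pre if op != "start" else h_pre)
            # extension matches between pre-op offset and current offset
            if op == "start":
                if h > 0:
                    edits_rev.append(("=", h))
                break
            if op == "X":
                if h - (h_pre + 1) > 0:
                    edits_rev.append(("=", h - (h_pre + 1)))
                edits_rev.append(("X", 1))
                s, k, h = s - x2, k, h_pre
            elif op == "from_I":
                if h - h_pre > 0:
                    edits_rev.append(("=", h - h_pre))
                comp, h = "I", h_pre
            elif op == "from_D":
                if h - h_pre > 0:
                    edits_rev.append(("=", h - h_pre))
                comp, h = "D", h_pre
        elif comp == "I":
            op, h_src = prov[("I", s, k)]
            edits_rev.append(("I", 1))
            if op == "I_open":
                comp, s, k, h = "M", s - o2 - e2, k - 1, h_src
            else:
                s, k, h = s - e2, k - 1, h_src
        else:
            op, h_src = prov[("D", s, k)]
            edits_rev.append(("D", 1))
            if op == "D_open":
                comp, s, k, h = "M", s - o2 - e2, k + 1, h_src
            else:
                s, k, h = s - e2, k + 1, h_src
    edits = merge_edits(list(reversed(edits_rev)))
    score = score_edits(edits, scoring)
    h_end = M[s_end][k_end]
    return WFAResult(True, score, edits, h_end, h_end - k_end)


# ---------------------------------------------------------------------------
# graph aligners


def _base_succ_fn(graph: VariationGraph):
    adj = graph.side_adjacency()
    lens = {n: graph.node_length(n) for n in graph.nodes}

    def succs(key: tuple[int, str, int]) -> list[tuple[int, str, int]]:
        node, orient, off = key
        if off + 1 < lens[node]:
            return [(node, orient, off + 1)]
        out = []
        for side in adj[exit_side((node, orient))]:
            out.append((side[0], FORWARD if side[1] == LEFT else REVERSE, 0))
        return out

    return succs


def _base_char(graph: VariationGraph, key: tuple[int, str, int]) -> str:
    return graph.oriented_sequence((key[0], key[1]))[key[2]]


_NEG = -(10**9)


def banded_graph_global(
    read_segment: str,
    graph: VariationGraph,
    start_pos: GraphPosition,
    end_pos: GraphPosition,
    scoring: ScoringParams | None = None,
    band: int | None = None,
) -> tuple[list[GraphPosition], list[tuple[str, int]], int]:
    """Globally align a read segment to graph walks from start to end.

    The graph side is the half-open base interval [start_pos, end_pos): the
    start base is aligned, the end base is not.  The subgraph is unrolled
    into layers by exact walk length from the start (cycles expand once per
    layer), and DP cells are restricted to |query_index - layer| <= band.
    Gap-affine scoring identical to the sequence aligners.  Returns
    (base-level path, edits, score).
    """
    scoring = scoring or ScoringParams()
    scoring.validate()
    m = len(read_segment)
    if band is None:
        band = scoring.band_padding + 1
    succs = _base_succ_fn(graph)
    start_key = (start_pos.node_id, start_pos.orientation, start_pos.offset)
    end_key = (end_pos.node_id, end_pos.orientation, end_pos.offset)
    if start_key == end_key:
        edits = [("I", m)] if m else []
        return [], edits, score_edits(edits, scoring) if edits else 0

    max_layers = m + band + 1
    # unrolled DAG: vertex = (layer, base key); edges from layer l to l+1
    vid_of: dict[tuple[int, tuple], int] = {}
    vkeys: list[tuple] = []
    vlayer: list[int] = []
    vpreds: list[list[int]] = []
    finals: list[int] = []  # vertices whose successor set contains end_key

    def add_vertex(layer: int, key: tuple, pred: int) -> int:
        vk = (layer, key)
        vid = vid_of.get(vk)
        if vid is None:
            vid = len(vkeys)
            vid_of[vk] = vid
            vkeys.append(key)
            vlayer.append(layer)
            vpreds.append([])
        if pred >= 0:
            vpreds[vid].append(pred)
        return vid

    frontier = [add_vertex(1, start_key, -1)]
    for layer in range(2, max_layers + 1):
        nxt = []
        for u in frontier:
            for sk in succs(vkeys[u]):
                if sk == end_key:
                    if u not in finals:
                        finals.append(u)
                    continue
                before = len(vkeys)
                v = add_vertex(layer, sk, u)
                if len(vkeys) > before:
                    nxt.append(v)
        frontier = nxt
        if not frontier:
            break
    # final vertices can also sit in the last expanded layer
    for u in range(len(vkeys)):
        if end_key in succs(vkeys[u]) and u not in finals:
            finals.append(u)
    if not finals:
        raise ValueError("end position unreachable from start position within the band")

    go, ge, ma, mi = scoring.gap_open, scoring.gap_extend, scoring.match, scoring.mismatch

    def src_h(i: int) -> int:  # leading insertions before any graph base
        return 0 if i == 0 else go + ge * i

    nv = len(vkeys)
    H = [None] * nv
    E = [None] * nv
    HC: list[list] = [None] * nv  # per-cell choice for traceback
    EC: list[list] = [None] * nv
    for v in range(nv):
        layer = vlayer[v]
        base = _base_char(graph, vkeys[v])
        h = [_NEG] * (m + 1)
        e = [_NEG] * (m + 1)
        hc: list = [None] * (m + 1)
        ec: list = [None] * (m + 1)
        lo = max(0, layer - band)
        hi = min(m, layer + band)
        preds = vpreds[v] if vpreds[v] else [-1]
        for i in range(lo, hi + 1):
            best_m, bm_src = _NEG, None
            best_e, be_src = _NEG, None
            for u in preds:
                hu_prev = src_h(i - 1) if u < 0 else (H[u][i - 1] if i >= 1 else _NEG)
                hu_here = src_h(i) if u < 0 else H[u][i]
                eu_here = _NEG if u < 0 else E[u][i]
                if i >= 1 and hu_prev > best_m:
                    best_m, bm_src = hu_prev, u
                cand_open = hu_here + go + ge
                cand_ext = eu_here + ge
                if cand_open > best_e:
                    best_e, be_src = cand_open, (u, "open")
                if cand_ext > best_e:
                    best_e, be_src = cand_ext, (u, "ext")
            if i >= 1 and best_m > _NEG // 2:
                best_m += ma if read_segment[i - 1] == base else mi
            else:
                best_m = _NEG
            e[i] = best_e
            ec[i] = be_src
            if best_m >= best_e:
                h[i], hc[i] = best_m, ("M", bm_src)
            else:
                h[i], hc[i] = best_e, ("E", None)
            if h[i] < _NEG // 2:
                hc[i] = None
        # insertions within the vertex column (consume query only)
        for i in range(lo + 1, hi + 1):
            prev_is_ins = hc[i - 1] is not None and hc[i - 1][0] == "I"
            cand = h[i - 1] + (ge if prev_is_ins else go + ge)
            if cand > h[i]:
                h[i], hc[i] = cand, ("I", None)
        H[v], E[v], HC[v], EC[v] = h, e, hc, ec
    best = None
    for u in finals:
        if H[u][m] > _NEG // 2 and (best is None or H[u][m] > best[0]):
            best = (H[u][m], u)
    if best is None:
        raise ValueError("no alignment within the band reaches the end position")

    score, v = best
    i = m
    state = "H"
    edits_rev: list[tuple[str, int]] = []
    path_rev: list[tuple] = []
    while v >= 0:
        if state == "H":
            choice = HC[v][i]
            if choice is None:
                break
            kind, src = choice
            if kind == "I":
                edits_rev.append(("I", 1))
                i -= 1
                continue
            if kind == "E":
                state = "E"
                continue
            # match/mismatch on this vertex
            base = _base_char(graph, vkeys[v])
            edits_rev.append(("=" if read_segment[i - 1] == base else "X", 1))
            path_rev.append(vkeys[v])
            i -= 1
            if src == -1:
                if i > 0:
                    edits_rev.append(("I", i))
                v = -1
            else:
                v = src
        else:  # E state: this vertex's base is deleted
            src = EC[v][i]
            edits_rev.append(("D", 1))
            path_rev.append(vkeys[v])
            u, how = src
            if u == -1:
                if i > 0:
                    edits_rev.append(("I", i))
                v = -1
            else:
                v = u
                state = "E" if how == "ext" else "H"
    edits = merge_edits(list(reversed(edits_rev)))
    path = [GraphPosition(*k) for k in reversed(path_rev)]
    return path, edits, score_edits(edits, scoring)


def xdrop_tail(
    read_tail: str,
    graph: VariationGraph,
    anchor_pos: GraphPosition,
    scoring: ScoringParams | None = None,
) -> tuple[list[GraphPosition], list[tuple[str, int]], int, int]:
    """Best local extension of a read tail outward from an anchor.

    The anchor is the last aligned base; extension consumes graph bases
    strictly after it.  Cells whose running score drops more than X below
    the best seen are pruned; extension may align zero bases, in which case
    the whole tail is left for the caller to soft-clip.  Returns
    (base path, edits, score, query bases consumed).
    """
    scoring = scoring or ScoringParams()
    scoring.validate()
    m = len(read_tail)
    if m == 0:
        return [], [], 0, 0
    succs = _base_succ_fn(graph)
    go, ge, ma, mi = scoring.gap_open, scoring.gap_extend, scoring.match, scoring.mismatch
    X = scoring.xdrop

    anchor_key = (anchor_pos.node_id, anchor_pos.orientation, anchor_pos.offset)
    # frontier of live cells: (key, i) -> (score, state) with back pointers
    # H cells only; affine gaps approximated per step kind
    start_cells: dict[tuple, tuple[int, str]] = {}
    back: dict[tuple, tuple] = {}
    best = (0, None)  # (score, cell); empty extension allowed
    frontier: dict[tuple, int] = {}
    for sk in succs(anchor_key):
        frontier[(sk, 0, "H")] = 0
    seen_scores: dict[tuple, int] = dict(frontier)
    live = list(frontier.items())
    best_score = 0
    while live:
        nxt: dict[tuple, tuple[int, tuple | None]] = {}

        def relax(cell, sc, src):
            cur = nxt.get(cell)
            if cur is None or sc > cur[0]:
                nxt[cell] = (sc, src)

        for (key, i, state), sc in live:
            base = _base_char(graph, key)
            # match/mismatch: consume this graph base and one query base
            if i < m:
                sub = ma if read_tail[i] == base else mi
                for sk in succs(key):
                    relax((sk, i + 1, "H"), sc + sub, ((key, i, state), "M"))
                # also allow the alignment to end on this consumed base
                end_sc = sc + sub
                if end_sc > best_score:
                    best_score = end_sc
                    best = (end_sc, ((key, i, state), "M_end"))
            # deletion: consume graph base only
            dcost = ge if state == "D" else go + ge
            for sk in succs(key):
                relax((sk, i, "D"), sc + dcost, ((key, i, state), "D"))
            # insertion: consume query base only
            if i < m:
                icost = ge if state == "I" else go + ge
                relax((key, i + 1, "I"), sc + icost, ((key, i, state), "I"))
        live = []
        for cell, (sc, src) in nxt.items():
            if sc < best_score - X:
                continue
            prev = seen_scores.get(cell)
            if prev is not None and prev >= sc:
                continue
            seen_scores[cell] = sc
            back[cell] = src
            live.append((cell, sc))
    if best[1] is None:
        return [], [], 0, 0
    # traceback from the best consumed base
    (cell, tag) = best[1]
    path_rev = []
    edits_rev = []
    key, i, state = cell
    base = _base_char(graph, key)
    edits_rev.append(("=" if read_tail[i] == base else "X", 1))
    path_rev.append(key)
    cur = cell
    while True:
        src = back.get(cur)
        if src is None:
            break
        (pkey, pi, pstate), op = src
        if op == "M":
            base = _base_char(graph, pkey)
            edits_rev.append(("=" if read_tail[pi] == base else "X", 1))
            path_rev.append(pkey)
        elif op == "D":
            edits_rev.append(("D", 1))
            path_rev.append(pkey)
        elif op == "I":
            edits_rev.append(("I", 1))
        cur = (pkey, pi, pstate)
    edits = merge_edits(list(reversed(edits_rev)))
    path = [GraphPosition(*k) for k in reversed(path_rev)]
    return path, edits, score_edits(edits, scoring), best[0] and (cell[1] + 1)


# ---------------------------------------------------------------------------
# chain extension


class HaplotypeCoords:
    """Occurrence index of graph positions on haplotype spellings.

    Both directions of every walk are indexed, so a position oriented along
    the read can always be located on some strand and its spelling sliced
    directly for wavefront alignment.
    """

    def __init__(self, graph: VariationGraph):
        self.graph = graph
        self.strands: list[dict] = []
        for walk in graph.walks:
            for steps, tag in ((walk.steps, "+"), (
                [(n, REVERSE if o == FORWARD else FORWARD) for n, o in reversed(walk.steps)],
                "-",
            )):
                seq = "".join(graph.oriented_sequence(s) for s in steps)
                starts = []
                occ: dict[tuple[int, str], list[tuple[int, int]]] = {}
                off = 0
                for si, (n, o) in enumerate(steps):
                    starts.append(off)
                    occ.setdefault((n, o), []).append((si, off))
                    off += graph.node_length(n)
                self.strands.append(
                    {"name": f"{walk.name}{tag}", "steps": steps, "seq": seq,
                     "starts": starts, "occ": occ, "len": off}
                )

    def locate(self, pos: GraphPosition) -> list[tuple[int, int]]:
        """(strand index, sequence offset) of every occurrence of a position."""
        out = []
        for si, st in enumerate(self.strands):
            for _, node_start in st["occ"].get((pos.node_id, pos.orientation), []):
                out.append((si, node_start + pos.offset))
        return out

    def slice_path(self, si: int, a: int, b: int) -> list[tuple[int, str, int, int]]:
        """Node runs (node, orient, off_start, off_end) covering seq[a:b)."""
        st = self.strands[si]
        runs = []
        from bisect import bisect_right

        i = bisect_right(st["starts"], a) - 1
        off = a
        while off < b:
            n, o = st["steps"][i]
            node_start = st["starts"][i]
            ln = self.graph.node_length(n)
            lo = off - node_start
            hi = min(ln, b - node_start)
            runs.append((n, o, lo, hi))
            off = node_start + hi
            i += 1
        return runs


class _PathBuilder:
    def __init__(self) -> None:
        self.runs: list[list] = []  # [node, orient, off_start, off_end)

    def add_run(self, node: int, orient: str, lo: int, hi: int) -> None:
        if hi <= lo:
            return
        if self.runs and self.runs[-1][0] == node and self.runs[-1][1] == orient \
                and self.runs[-1][3] == lo:
            self.runs[-1][3] = hi
        else:
            self.runs.append([node, orient, lo, hi])

    def add_base(self, pos: GraphPosition) -> None:
        self.add_run(pos.node_id, pos.orientation, pos.offset, pos.offset + 1)

    def add_runs(self, runs) -> None:
        for n, o, lo, hi in runs:
            self.add_run(n, o, lo, hi)


@dataclass
class GraphAlignment:
    read_name: str
    read_length: int
    read_start: int
    read_end: int  # half-open aligned interval of the read
    runs: list[list]  # [node, orient, off_start, off_end) along the walk
    edits: list[tuple[str, int]]
    score: int
    mapq: int = 0

    @property
    def path(self) -> list[tuple[int, str]]:
        return [(r[0], r[1]) for r in self.runs]

    def path_length(self, graph: VariationGraph) -> int:
        return sum(graph.node_length(n) for n, _ in self.path)

    def path_interval(self, graph: VariationGraph) -> tuple[int, int]:
        if not self.runs:
            return (0, 0)
        start = self.runs[0][2]
        end = self.path_length(graph) - (
            graph.node_length(self.runs[-1][0]) - self.runs[-1][3]
        )
        return (start, end)

    def residue_matches(self) -> int:
        return sum(ln for op, ln in self.edits if op == "=")

    def block_length(self) -> int:
        return sum(ln for op, ln in self.edits)

    def check_invariants(self, graph: VariationGraph) -> None:
        read_bases = sum(ln for op, ln in self.edits if op in "=XI")
        if read_bases != self.read_end - self.read_start:
            raise AssertionError("edits do not consume the aligned read interval")
        graph_bases = sum(ln for op, ln in self.edits if op in "=XD")
        span = sum(hi - lo for _, _, lo, hi in self.runs)
        if graph_bases != span:
            raise AssertionError("edits do not consume the walk span")
        for (a, b) in zip(self.runs, self.runs[1:]):
            if not graph.has_edge(exit_side((a[0], a[1])), entry_side((b[0], b[1]))):
                raise AssertionError(f"walk step {a}->{b} lacks edge support")


def _revcomp(s: str) -> str:
    from .graph import reverse_complement

    return reverse_complement(s)


def _align_segment(
    query: str,
    p_start: GraphPosition,
    p_end: GraphPosition,
    graph: VariationGraph,
    coords: HaplotypeCoords,
    scoring: ScoringParams,
    graph_dist: int | None,
) -> tuple[int, list[tuple[str, int]], list]:
    """Align query to the graph interval [p_start, p_end); returns
    (score, edits, runs).  Haplotype wavefronts first, graph DP fallback."""
    best: tuple[int, list, list] | None = None
    max_span = len(query) + 2 * scoring.band_padding + abs(
        (graph_dist or 0) - len(query)
    ) + 64
    seen_targets: set[tuple[int, str]] = set()
    starts = coords.locate(p_start)
    ends = {}
    for si, off in coords.locate(p_end):
        ends.setdefault(si, []).append(off)
    for si, a in starts:
        for b in ends.get(si, []):
            if b < a or b - a > max_span:
                continue
            target = coords.strands[si]["seq"][a:b]
            key = (len(target), target)
            if key in seen_targets:
                continue
            seen_targets.add(key)
            if target == query:
                cand = (scoring.match * len(query),
                        [("=", len(query))] if query else [],
                        coords.slice_path(si, a, b))
                if best is None or cand[0] > best[0]:
                    best = cand
                continue
            if max(len(query), len(target)) <= scoring.wfa_max_len:
                res = wfa_align(query, target, scoring, mode="global")
                if res.ok and (best is None or res.score > best[0]):
                    best = (res.score, res.edits, coords.slice_path(si, a, b))
    if best is not None:
        return best
    # no haplotype spans the segment (or wavefronts failed): graph DP
    band = abs(len(query) - (graph_dist or len(query))) + scoring.band_padding
    path, edits, score = banded_graph_global(
        query, graph, p_start, p_end, scoring, band=band
    )
    runs = [[p.node_id, p.orientation, p.offset, p.offset + 1] for p in path]
    return score, edits, runs


def _align_tail(
    tail: str,
    anchor: GraphPosition,
    graph: VariationGraph,
    coords: HaplotypeCoords,
    scoring: ScoringParams,
) -> tuple[int, list[tuple[str, int]], list, int]:
    """Anchored extension of a tail beyond the last aligned base.

    Returns (score, edits, runs, query consumed); haplotype continuations
    are tried with anchored wavefronts, then the graph X-drop extender."""
    if not tail:
        return 0, [], [], 0
    best: tuple[int, list, list, int] | None = None
    margin = min(len(tail) + 2 * scoring.band_padding + 32, len(tail) * 2 + 64)
    for si, off in coords.locate(anchor):
        a = off + 1
        b = min(a + margin, coords.strands[si]["len"])
        target = coords.strands[si]["seq"][a:b]
        lim = min(len(tail), len(target))
        if target[:lim] == tail[:lim]:
            res = WFAResult(True, scoring.match * lim, [("=", lim)] if lim else [], lim, lim)
        else:
            res = wfa_align(tail, target, scoring, mode="anchored_prefix")
        if res.ok and (best is None or res.score > best[0]):
            best = (res.score, res.edits, coords.slice_path(si, a, a + res.target_end),
                    res.query_end)
    if best is None or best[0] <= 0:
        path, edits, score, consumed = xdrop_tail(tail, graph, anchor, scoring)
        runs = [[p.node_id, p.orientation, p.offset, p.offset + 1] for p in path]
        cand = (score, edits, runs, consumed)
        if best is None or cand[0] > best[0]:
            best = cand
    return best


def extend_chain(
    chain,
    graph: VariationGraph,
    coords: HaplotypeCoords,
    scoring: ScoringParams | None = None,
    k: int | None = None,
    read: str = "",
    read_name: str = "read",
    dindex=None,
) -> GraphAlignment:
    """Turn a seed chain into a base-level alignment of the whole read.

    Alignment proceeds between consecutive seed start positions and outward
    from the first and last seeds; pieces are stitched into one walk whose
    edits, score and read accounting are mutually consistent."""
    scoring = scoring or ScoringParams()
    seeds = chain.seeds
    if not seeds:
        raise ValueError("cannot extend an empty chain")
    if k is None:
        k = len(read) - seeds[-1].read_offset if len(seeds) == 1 else 19
    builder = _PathBuilder()
    edits: list[tuple[str, int]] = []
    score = 0

    transitions = getattr(chain, "transitions", [None] * (len(seeds) - 1))
    for idx, (s_i, s_j) in enumerate(zip(seeds, seeds[1:])):
        query = read[s_i.read_offset : s_j.read_offset]
        gd = transitions[idx][1] if transitions[idx] is not None else None
        sc, ed, runs = _align_segment(
            query, s_i.position, s_j.position, graph, coords, scoring, gd
        )
        score += sc
        edits.extend(ed)
        builder.add_runs(runs)
    # final seed k-mer: an exact match on some indexed strand by construction
    last = seeds[-1]
    kmer = read[last.read_offset : last.read_offset + k]
    placed = False
    for si, a in coords.locate(last.position):
        if coords.strands[si]["seq"][a : a + k] == kmer:
            score += scoring.match * k
            edits.append(("=", k))
            builder.add_runs(coords.slice_path(si, a, a + k))
            placed = True
            break
    if not placed:  # degenerate (e.g. seed truncated at a walk end)
        sc, ed, runs = _align_segment(
            kmer, last.position, _advance_end(last, graph), graph, coords, scoring, k
        )
        score += sc
        edits.extend(ed)
        builder.add_runs(runs)

    # right tail
    right_tail = read[last.read_offset + k :]
    r_sc, r_ed, r_runs, r_used = _align_tail(
        right_tail, last.end_position, graph, coords, scoring
    )
    score += r_sc
    edits.extend(r_ed)
    builder.add_runs(r_runs)

    # left tail: flip into reverse orientation and extend forward
    first = seeds[0]
    left_read = read[: first.read_offset]
    anchor_rev = first.position.reverse(graph.node_length(first.position.node_id))
    l_sc, l_ed, l_runs, l_used = _align_tail(
        _revcomp(left_read), anchor_rev, graph, coords, scoring
    )
    score += l_sc
    left_edits = list(reversed(l_ed))
    left_runs = [
        [n, FORWARD if o == REVERSE else REVERSE,
         graph.node_length(n) - hi, graph.node_length(n) - lo]
        for n, o, lo, hi in reversed(l_runs)
    ]
    final_builder = _PathBuilder()
    final_builder.add_runs(left_runs)
    final_builder.add_runs([tuple(r) for r in builder.runs])
    aln = GraphAlignment(
        read_name=read_name,
        read_length=len(read),
        read_start=first.read_offset - l_used,
        read_end=last.read_offset + k + r_used,
        runs=final_builder.runs,
        edits=merge_edits(left_edits + edits),
        score=score,
    )
    return aln


def _advance_end(seed, graph: VariationGraph) -> GraphPosition:
    """Position one past the seed's final k-mer base (its exclusive end)."""
    end = seed.end_position
    ln = graph.node_length(end.node_id)
    if end.offset + 1 < ln:
        return GraphPosition(end.node_id, end.orientation, end.offset + 1)
    succ = _base_succ_fn(graph)((end.node_id, end.orientation, end.offset))
    if succ:
        return GraphPosition(*succ[0])
    return end  # dead end: final base handled by the degenerate interval
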