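"""Simulated-annealing search over walk assemblies.

Each iteration proposes a local change to the current set of walks (one of
six move types), scores the proposal incrementally, and accepts it by the
Metropolis rule: improvements always, a change of ``delta < 0`` with
probability ``exp(delta / T)`` under the cooling schedule
``T = T0 / ln(i + 1)``.  The best assembly ever visited is returned.

Moves (the contig at which a move applies is chosen at random):

* walk extension — random walk from the end of an existing walk; on meeting
  another walk's end, uniformly join / stop / continue;
* local improvement — re-route the connection between two adjacent long
  contigs through the best of several sampled paths (reachability-pruned),
  or greedy ~200 bp chunks when the gap is large;
* repeat optimization — add or remove one copy of a short loop (tandem
  repeat) in a walk;
* joining with advice — join two walks spanned by a read pair with a long
  insert (or a long read), filling the gap by path search or with Ns;
* disconnecting — split a walk at an unsupported bridge of short contigs;
* repeat interchange — re-pair the incoming and outgoing walk segments at a
  contig traversed several times, greedily while the score improves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .evaluation import EvalState, Evaluator
from .graph import (
    Assembly,
    AssemblyGraph,
    Walk,
    enumerate_short_loops,
    loops_by_node,
)

__all__ = [
    "AnnealConfig",
    "MoveProposal",
    "AnnealResult",
    "temperature",
    "accept",
    "anneal",
    "move_walk_extension",
    "move_local_improvement",
    "move_repeat_optimization",
    "move_joining_with_advice",
    "move_disconnecting",
    "move_repeat_interchange",
    "interchange_at_contig",
]

DEFAULT_MOVE_PROBABILITIES = {
    "extension": 0.25,
    "local": 0.20,
    "repeat_opt": 0.15,
    "advice": 0.15,
    "disconnect": 0.10,
    "interchange": 0.15,
}


@dataclass
class AnnealConfig:
    t0: float | None = None  # default: 0.01 * |LAP(initial)|
    move_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOVE_PROBABILITIES)
    )
    patience: int = 500
    max_iters: int = 5000
    rng_seed: int = 0
    greedy_chunk: int = 200
    big_gap: int = 5000
    long_threshold: int = 500
    local_samples: int = 10
    max_extension_steps: int = 20
    advice_min_insert: float = 0.0  # paired sets with at least this insert give advice
    paranoid: bool = False

    def validate(self) -> None:
        total = sum(self.move_probabilities.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"move probabilities must sum to 1 (got {total})")
        if self.patience < 1 or (self.t0 is not None and self.t0 <= 0):
            raise ValueError("invalid annealing configuration")


@dataclass
class MoveProposal:
    kind: str
    removed: list[int]
    added: list[Walk]


@dataclass
class AnnealResult:
    assembly: Assembly
    total: float
    state: EvalState
    trajectory: list[tuple]
    iterations: int


def temperature(iteration: int, t0: float) -> float:
    """Cooling schedule ``T0 / ln(i + 1)`` (shifted so i=1 is defined)."""
    if iteration < 1:
        raise ValueError("iteration must be >= 1")
    return t0 / math.log(iteration + 1)


def accept(delta_lap: float, T: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: always accept improvements, otherwise with
    probability ``exp(delta / T)``."""
    if delta_lap >= 0:
        return True
    if T <= 0:
        return False
    return bool(rng.random() < math.exp(delta_lap / T))


# ---------------------------------------------------------------------------
# move helpers
# ---------------------------------------------------------------------------


def _walk_end_map(assembly: Assembly, exclude: int) -> dict:
    """Map from oriented node to (walk id, how to join) for walk ends."""
    ends: dict = {}
    for wid, w in assembly.walks.items():
        if wid == exclude:
            continue
        nodes = w.nodes()
        if not nodes:
            continue
        ends.setdefault(nodes[0], []).append((wid, "forward"))
        rc_last = (nodes[-1][0], -nodes[-1][1])
        ends.setdefault(rc_last, []).append((wid, "reverse"))
    return ends


def _long_positions(walk: Walk, graph: AssemblyGraph, threshold: int) -> list[int]:
    out = []
    for i, e in enumerate(walk.elements):
        if e[0] == "node" and graph.node_len(e[1]) > threshold:
            out.append(i)
    return out


def move_walk_extension(
    assembly: Assembly,
    graph: AssemblyGraph,
    rng: np.random.Generator,
    config: AnnealConfig,
    state: EvalState | None = None,
    **_,
) -> MoveProposal | None:
    if not assembly.walks:
        return None
    wid = int(rng.choice(sorted(assembly.walks)))
    walk = assembly.walks[wid]
    if rng.random() < 0.5:
        walk = walk.reverse()
    nodes = walk.nodes()
    if not nodes:
        return None
    ends = _walk_end_map(assembly, wid)
    cur = nodes[-1]
    path: list[tuple] = []
    for _ in range(config.max_extension_steps):
        succs = graph.successors(cur)
        if not succs:
            break
        cur = succs[int(rng.integers(len(succs)))]
        path.append(("node", cur[0], cur[1]))
        if cur in ends:
            choice = int(rng.integers(3))  # join / stop / continue
            if choice == 0:
                wid2, how = ends[cur][int(rng.integers(len(ends[cur])))]
                other = assembly.walks[wid2]
                if how == "reverse":
                    other = other.reverse()
                joined = Walk(walk.elements + path[:-1] + list(other.elements))
                return MoveProposal("extension", [wid, wid2], [joined])
            if choice == 1:
                return MoveProposal("extension", [wid], [Walk(walk.elements + path)])
    # never met another walk's end: duplicating graph content is LAP-neutral
    # and would accumulate, so treat the wander as a no-op
    return None


def _reverse_reachable(graph: AssemblyGraph, target, max_nodes: int = 400) -> set:
    seen = {target}
    frontier = [target]
    while frontier and len(seen) < max_nodes:
        nxt = []
        for v in frontier:
            for u in graph.predecessors(v):
                if u not in seen:
                    seen.add(u)
                    nxt.append(u)
        frontier = nxt
    return seen


def _sample_path(
    graph: AssemblyGraph,
    src,
    dst,
    allowed: set,
    rng: np.random.Generator,
    max_len: int = 30,
) -> list | None:
    cur = src
    path = []
    for _ in range(max_len):
        succs = [v for v in graph.successors(cur) if v == dst or v in allowed]
        if not succs:
            return None
        cur = succs[int(rng.integers(len(succs)))]
        if cur == dst:
            return path
        path.append(cur)
    return None


def move_local_improvement(
    assembly: Assembly,
    graph: AssemblyGraph,
    rng: np.random.Generator,
    config: AnnealConfig,
    state: EvalState,
    evaluator: Evaluator,
    **_,
) -> MoveProposal | None:
    candidates = [
        wid
        for wid, w in sorted(assembly.walks.items())
        if len(_long_positions(w, graph, config.long_threshold)) >= 2
    ]
    if not candidates:
        return None
    wid = int(rng.choice(candidates))
    walk = assembly.walks[wid]
    longs = _long_positions(walk, graph, config.long_threshold)
    j = int(rng.integers(len(longs) - 1))
    i_s, i_t = longs[j], longs[j + 1]
    s_node = (walk.elements[i_s][1], walk.elements[i_s][2])
    t_node = (walk.elements[i_t][1], walk.elements[i_t][2])
    allowed = _reverse_reachable(graph, t_node)
    variants: dict[tuple, Walk] = {}
    for _ in range(config.local_samples):
        path = _sample_path(graph, s_node, t_node, allowed, rng)
        if path is None:
            continue
        elems = (
            walk.elements[: i_s + 1]
            + [("node", v[0], v[1]) for v in path]
            + walk.elements[i_t:]
        )
        variants[tuple(elems)] = Walk(list(elems))
    current_sig = tuple(walk.elements)
    variants.pop(current_sig, None)
    if not variants:
        return None
    best_walk, best_total = None, -math.inf
    for sig in sorted(variants):
        var = variants[sig]
        if not var.is_valid(graph):
            continue
        total = evaluator.propose(state, [wid], {-1: var}).total
        if total > best_total:
            best_walk, best_total = var, total
    if best_walk is None:
        return None
    return MoveProposal("local", [wid], [best_walk])


def move_repeat_optimization(
    assembly: Assembly,
    graph: AssemblyGraph,
    rng: np.random.Generator,
    config: AnnealConfig,
    loops: Sequence[Sequence] = (),
    loop_index: dict | None = None,
    **_,
) -> MoveProposal | None:
    if not assembly.walks:
        return None
    wid = int(rng.choice(sorted(assembly.walks)))
    walk = assembly.walks[wid]
    add_options: list[tuple[int, tuple]] = []
    if loop_index:
        for pos, e in enumerate(walk.elements):
            if e[0] != "node":
                continue
            node = (e[1], e[2])
            for li in loop_index.get(node, ()):
                loop = list(loops[li])
                k = loop.index(node)
                rotated = loop[k + 1 :] + loop[: k + 1]  # a, ..., z, v
                add_options.append((pos, tuple(rotated)))
    remove_options: list[tuple[int, int]] = []
    positions: dict = {}
    for pos, e in enumerate(walk.elements):
        if e[0] != "node":
            continue
        node = (e[1], e[2])
        for prev in positions.get(node, ()):
            if pos - prev <= 5:
                remove_options.append((prev, pos))
        positions.setdefault(node, []).append(pos)

    do_add = bool(add_options) and (not remove_options or rng.random() < 0.5)
    if do_add:
        pos, rotated = add_options[int(rng.integers(len(add_options)))]
        elems = (
            walk.elements[: pos + 1]
            + [("node", v[0], v[1]) for v in rotated]
            + walk.elements[pos + 1 :]
        )
        return MoveProposal("repeat_opt", [wid], [Walk(elems)])
    if remove_options:
        p, q = remove_options[int(rng.integers(len(remove_options)))]
        elems = walk.elements[: p + 1] + walk.elements[q + 1 :]
        return MoveProposal("repeat_opt", [wid], [Walk(elems)])
    return None


def _oriented_walk_position(state: EvalState, hit, assembly: Assembly):
    return hit


def move_joining_with_advice(
    assembly: Assembly,
    graph: AssemblyGraph,
    rng: np.random.Generator,
    config: AnnealConfig,
    state: EvalState,
    evaluator: Evaluator,
    readsets=None,
    **_,
) -> MoveProposal | None:
    readsets = readsets if readsets is not None else evaluator.readsets
    advice_sets = [
        si
        for si, rs in enumerate(readsets)
        if (rs.paired and (rs.params.insert_mean or 0) >= config.advice_min_insert)
        or rs.technology_class == "long-noisy"
    ]
    if not advice_sets or len(assembly.walks) < 2:
        return None
    si = int(rng.choice(advice_sets))
    rs = readsets[si]
    per_walk = state.per_set[si]
    # entries with alignments on two different walks
    entry_walks: dict[int, dict[int, list]] = {}
    for wid, data in per_walk.items():
        for entry, hits in data.hits.items():
            entry_walks.setdefault(entry[0], {}).setdefault(wid, []).append((entry[1], hits))
    spanning = []
    for ridx, by_walk in sorted(entry_walks.items()):
        if len(by_walk) >= 2:
            spanning.append((ridx, sorted(by_walk)))
    if not spanning:
        return None
    ridx, wids = spanning[int(rng.integers(len(spanning)))]
    w1, w2 = wids[0], wids[1]
    if len(wids) > 2:
        w1, w2 = sorted(rng.choice(wids, size=2, replace=False))
    hits1 = [h for _, hs in per_walk[w1].hits.items() for h in hs if h[0][0] == ridx]
    hits2 = [h for _, hs in per_walk[w2].hits.items() for h in hs if h[0][0] == ridx]
    if not hits1 or not hits2:
        return None
    h1 = hits1[int(rng.integers(len(hits1)))]
    h2 = hits2[int(rng.integers(len(hits2)))]

    A = assembly.walks[w1]
    B = assembly.walks[w2]
    lenA = state.walk_len[w1]
    lenB = state.walk_len[w2]
    # orient A so the anchoring alignment points toward A's right end,
    # B so its alignment points back toward B's left end
    p1, s1 = h1[1], h1[3]
    p2e, s2 = h2[2], h2[3]
    if rs.paired:
        # make the joined pair proper: left hit forward, right hit reverse
        # ("fr"), or the opposite for "rf" libraries
        want1, want2 = (1, -1) if rs.params.orientation == "fr" else (-1, 1)
    else:
        want1 = want2 = 1  # a long read crossing both walks left to right
    if s1 != want1:
        A = A.reverse()
        p1 = lenA - h1[2]
    if s2 != want2:
        B = B.reverse()
        p2e = lenB - h2[1]

    nodesA, nodesB = A.nodes(), B.nodes()
    if not nodesA or not nodesB:
        return None
    # candidate joins: sampled graph paths closing the gap, plus an N-gap
    # sized from the insert estimate; score them all and keep the best —
    # taking an arbitrary path lets unrelated graph content creep in
    candidates: list[Walk] = []
    seen: set = set()
    allowed = _reverse_reachable(graph, nodesB[0])
    for _ in range(config.local_samples):
        path = _sample_path(graph, nodesA[-1], nodesB[0], allowed, rng, max_len=15)
        if path is not None and tuple(path) not in seen:
            seen.add(tuple(path))
            elems = A.elements + [("node", v[0], v[1]) for v in path] + B.elements
            candidates.append(Walk(elems))
    if rs.paired:
        mu = rs.params.insert_mean
        gap = int(round(mu - (lenA - p1) - p2e))
    else:
        gap = 10  # a long read gives no insert estimate; use a token gap
    gap = max(1, gap)
    candidates.append(Walk(A.elements + [("gap", gap)] + B.elements))
    best, best_total = None, -math.inf
    for cand in candidates:
        if not cand.is_valid(graph):
            continue
        total = evaluator.propose(state, [w1, w2], {-1: cand}).total
        if total > best_total:
            best, best_total = cand, total
    if best is None:
        return None
    return MoveProposal("advice", [w1, w2], [best])


def _redundant_trim(walk, graph, usage, threshold, rng) -> Walk | None:
    """Trim a terminal run whose long contigs are all placed elsewhere.

    Extension and advice can replay another region's contigs at a walk end,
    leaving a duplicated head or tail that no other move removes whole.  The
    boundary is the outermost uniquely-placed long contig; everything beyond
    it on the chosen side is dropped."""
    longs = _long_positions(walk, graph, threshold)
    unique = [i for i in longs if usage[walk.elements[i][1]] < 2]
    if not unique or len(unique) == len(longs):
        return None
    cands = []
    if any(i > unique[-1] for i in longs):  # redundant tail
        cands.append(Walk(walk.elements[: unique[-1] + 1]))
    if any(i < unique[0] for i in longs):  # redundant head
        cands.append(Walk(walk.elements[unique[0]:]))
    if not cands:
        return None
    return cands[int(rng.integers(len(cands)))]


def move_disconnecting(
    assembly: Assembly,
    graph: AssemblyGraph,
    rng: np.random.Generator,
    config: AnnealConfig,
    **_,
) -> MoveProposal | None:
    if not assembly.walks:
        return None
    r = rng.random()
    # option A: drop a fully redundant walk (every contig also placed
    # elsewhere) — extension can duplicate content by walking through
    # another walk's body, and nothing else removes the leftover copy
    if len(assembly.walks) > 1 and r < 1 / 3:
        usage = assembly.placed_contigs()
        redundant = [
            wid
            for wid, w in sorted(assembly.walks.items())
            if w.contig_ids() and all(usage[c] >= 2 for c in w.contig_ids())
        ]
        if redundant:
            wid = int(rng.choice(redundant))
            return MoveProposal("disconnect", [wid], [])
    wid = int(rng.choice(sorted(assembly.walks)))
    walk = assembly.walks[wid]
    # option B: trim a redundant terminal run of the chosen walk
    if r < 2 / 3:
        trimmed = _redundant_trim(
            walk, graph, assembly.placed_contigs(), config.long_threshold, rng
        )
        if trimmed is not None:
            return MoveProposal("disconnect", [wid], [trimmed])
    # option C: split the walk between two adjacent long contigs
    longs = _long_positions(walk, graph, config.long_threshold)
    if len(longs) < 2:
        return None
    j = int(rng.integers(len(longs) - 1))
    i_a, i_b = longs[j], longs[j + 1]
    left = Walk(walk.elements[: i_a + 1])
    right = Walk(walk.elements[i_b:])
    return MoveProposal("disconnect", [wid], [left, right])


# ---------------------------------------------------------------------------
# repeat interchange
# ---------------------------------------------------------------------------


def _traversal_pieces(assembly: Assembly, cid: int):
    """Cut every walk at each traversal of ``cid``.

    Returns ``(pieces, traversals, wids)`` where each traversal is
    ``(in_piece_id, out_piece_id, strand_of_c)`` and pieces are element
    lists.  Walks whose traversals mix strands are rejected (None).
    """
    pieces: list[list] = []
    traversals: list[tuple[int, int, int]] = []
    wids: list[int] = []
    starts: list[int] = []  # piece ids that begin a walk
    for wid in sorted(assembly.walks):
        walk = assembly.walks[wid]
        pos = [i for i, e in enumerate(walk.elements) if e[0] == "node" and e[1] == cid]
        if not pos:
            continue
        strands = {walk.elements[i][2] for i in pos}
        if len(strands) > 1:
            return None
        if strands == {-1}:
            walk = walk.reverse()
            n = len(walk.elements)
            pos = sorted(n - 1 - i for i in pos)
        wids.append(wid)
        prev = 0
        piece_ids = []
        for p in pos:
            pieces.append(walk.elements[prev:p])
            piece_ids.append(len(pieces) - 1)
            prev = p + 1
        pieces.append(walk.elements[prev:])
        piece_ids.append(len(pieces) - 1)
        starts.append(piece_ids[0])
        for t in range(len(pos)):
            traversals.append((piece_ids[t], piece_ids[t + 1], 1))
    return pieces, traversals, wids, starts


def _reassemble(pieces, traversals, starts, sigma, cid: int) -> list[Walk] | None:
    """Walks resulting from pairing traversal j's in-piece with the out-piece
    of traversal ``sigma[j]``.  Pairings that close a cycle are linearized by
    cutting the cycle after its last traversal of ``cid``, so the repeat copy
    count is preserved and mis-phased repeats inside a single walk can still
    be re-paired."""
    out_of: dict[int, int] = {}  # in-piece id -> assigned out-piece id
    for j, (inp, _outp, _s) in enumerate(traversals):
        out_of[inp] = traversals[sigma[j]][1]
    assigned_outs = set(out_of.values())
    walks = []
    used = set()
    for start in starts:
        if start in assigned_outs:
            continue
        elems: list = []
        cur = start
        while cur is not None and cur not in used:
            used.add(cur)
            elems.extend(pieces[cur])
            nxt = out_of.get(cur)
            if nxt is not None:
                elems.append(("node", cid, 1))
            cur = nxt
        if elems:
            walks.append(Walk(elems))
    # leftover pieces form cycles: cut each after its final traversal
    for start in range(len(pieces)):
        if start in used:
            continue
        elems = []
        cur = start
        while cur not in used:
            used.add(cur)
            elems.extend(pieces[cur])
            elems.append(("node", cid, 1))
            cur = out_of[cur]
        if elems:
            walks.append(Walk(elems))
    return walks


def interchange_at_contig(
    assembly: Assembly,
    state: EvalState,
    evaluator: Evaluator,
    graph: AssemblyGraph,
    cid: int,
    max_traversals: int = 4,
):
    """All exchange variants at one multiply-traversed contig.

    Returns ``(baseline_total, variants)`` with each variant
    ``(total, removed_wids, new_walks)``, or None when the contig cannot be
    re-paired (single traversal, mixed strands, too many traversals).
    """
    from itertools import permutations

    cut = _traversal_pieces(assembly, cid)
    if cut is None:
        return None
    pieces, traversals, wids, starts = cut
    m = len(traversals)
    if m < 2 or m > max_traversals:
        return None
    baseline = state.total
    variants = []
    for sigma in permutations(range(m)):
        if list(sigma) == list(range(m)):
            continue
        walks = _reassemble(pieces, traversals, starts, list(sigma), cid)
        if walks is None or not all(w.is_valid(graph) for w in walks):
            continue
        added = {-(i + 1): w for i, w in enumerate(walks)}
        total = evaluator.propose(state, wids, added).total
        variants.append((total, wids, walks))
    return baseline, variants


def move_repeat_interchange(
    assembly: Assembly,
    graph: AssemblyGraph,
    rng: np.random.Generator,
    config: AnnealConfig,
    state: EvalState,
    evaluator: Evaluator,
    **_,
) -> MoveProposal | None:
    usage = assembly.placed_contigs()
    multi = sorted(cid for cid, n in usage.items() if n >= 2)
    if not multi:
        return None
    cid = int(rng.choice(multi))
    work_asm = assembly
    work_state = state
    improved = False
    for _ in range(4):  # repeat while the score improves at this contig
        res = interchange_at_contig(work_asm, work_state, evaluator, graph, cid)
        if not res:
            break
        baseline, variants = res
        if not variants:
            break
        best = max(variants, key=lambda v: v[0])
        if best[0] <= baseline + 1e-9:
            break
        improved = True
        _total, wids, walks = best
        if work_asm is assembly:
            work_asm = assembly.copy()
        new_ids = work_asm.apply(wids, walks)
        work_state = evaluator.propose(work_state, wids, dict(zip(new_ids, walks)))
    if not improved:
        return None
    # walks of the working assembly not present in the original are the additions
    orig_ids = set(assembly.walks)
    added = [w for wid, w in sorted(work_asm.walks.items()) if wid not in orig_ids]
    removed = sorted(orig_ids - set(work_asm.walks))
    return MoveProposal("interchange", removed, added)


# ---------------------------------------------------------------------------
# the annealing loop
# ---------------------------------------------------------------------------

_MOVES: dict[str, Callable] = {
    "extension": move_walk_extension,
    "local": move_local_improvement,
    "repeat_opt": move_repeat_optimization,
    "advice": move_joining_with_advice,
    "disconnect": move_disconnecting,
    "interchange": move_repeat_interchange,
}


def anneal(
    initial: Assembly,
    graph: AssemblyGraph,
    readsets,
    config: AnnealConfig,
    evaluator: Evaluator | None = None,
    trajectory_path=None,
) -> AnnealResult:
    """Run simulated annealing from ``initial`` and return the best-LAP
    assembly visited.  The trajectory logs
    (iteration, move, delta, accepted, T, current total, best total)."""
    config.validate()
    if evaluator is None:
        evaluator = Evaluator(graph, readsets, long_threshold=config.long_threshold)
    rng = np.random.default_rng(config.rng_seed)
    state = evaluator.evaluate(initial)
    cur = initial.copy()
    best = cur.copy()
    best_total = state.total
    t0 = config.t0 if config.t0 is not None else 0.01 * abs(state.total)
    if t0 <= 0:
        t0 = 1e-3
    loops = enumerate_short_loops(graph) if graph is not None else []
    loop_index = loops_by_node(loops)
    move_names = sorted(config.move_probabilities)
    move_p = np.array([config.move_probabilities[m] for m in move_names])
    move_p = move_p / move_p.sum()

    trajectory: list[tuple] = []
    no_improve = 0
    it = 0
    for it in range(1, config.max_iters + 1):
        T = temperature(it, t0)
        kind = move_names[int(rng.choice(len(move_names), p=move_p))]
        prop = _MOVES[kind](
            assembly=cur,
            graph=graph,
            rng=rng,
            config=config,
            state=state,
            evaluator=evaluator,
            readsets=readsets,
            loops=loops,
            loop_index=loop_index,
        )
        accepted = False
        delta = 0.0
        if prop is not None and all(w.is_valid(graph) for w in prop.added):
            new_asm = cur.copy()
            new_ids = new_asm.apply(prop.removed, prop.added)
            new_state = evaluator.propose(state, prop.removed, dict(zip(new_ids, prop.added)))
            delta = new_state.total - state.total
            if accept(delta, T, rng):
                accepted = True
                cur, state = new_asm, new_state
                if config.paranoid:
                    full = evaluator.full_recompute(cur)
                    if abs(full.total - state.total) > 1e-6:
                        raise AssertionError(
                            f"incremental {state.total} != full {full.total}"
                        )
        trajectory.append((it, kind, delta, accepted, T, state.total, best_total))
        if state.total > best_total + 1e-12:
            best_total = state.total
            best = cur.copy()
            no_improve = 0
        else:
            no_improve += 1
        if no_improve >= config.patience:
            break

    if trajectory_path is not None:
        with open(trajectory_path, "w") as fh:
            fh.write("iteration\tmove\tdelta\taccepted\tT\ttotal\tbest\n")
            for rec in trajectory:
                fh.write("\t".join(str(x) for x in rec) + "\n")
    return AnnealResult(best, best_total, state, trajectory, it)
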