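"""Postprocessing: break walks at ambiguously phased repeats.

A contig traversed several times by the final walks asserts a phasing: each
entry path into the repeat is paired with one exit path.  That pairing is
only trustworthy when read data can see across the repeat.  A traversal is
*spanned* when some alignment evidence (a proper read pair or a single long
alignment) anchors on both flanks of the repeat copy; otherwise the
assignment of exits to entries is arbitrary.  A repeat is also flagged when
an alternative exit pairing scores within tolerance of the current one —
the likelihood itself cannot tell the arrangements apart.

Flagged repeats are broken: each traversing walk is cut at the repeat, the
flanking pieces become walks of their own, and the repeat contig is emitted
exactly once as a standalone walk.  This trades contiguity for correctness;
every junction that survives is supported by data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annealing import _traversal_pieces, interchange_at_contig
from .evaluation import EvalState, Evaluator
from .graph import Assembly, AssemblyGraph, Walk

__all__ = ["BreakRecord", "BreakReport", "break_ambiguous"]


@dataclass
class BreakRecord:
    contig: int
    reason: str  # "unspanned", "score-tie" or "unsupported-junction"
    baseline: float
    alternative: float | None  # best alternative pairing's score, if scored


@dataclass
class BreakReport:
    records: list[BreakRecord] = field(default_factory=list)

    @property
    def broken_contigs(self) -> list[int]:
        return [r.contig for r in self.records]


def _copy_spans(evaluator: Evaluator, walk: Walk, cid: int, graph: AssemblyGraph):
    """Full walk-coordinate extent ``(a, b)`` of each traversal of ``cid``."""
    _, layout, _ = evaluator.render(walk)
    clen = graph.node_len(cid)
    spans = []
    for e, _s, t in layout:
        if e[0] == "node" and e[1] == cid:
            spans.append((max(0, t - clen), t))
    return spans


def _traversal_spanned(
    state: EvalState, evaluator: Evaluator, wid: int, a: int, b: int
) -> bool:
    """True when some alignment interval anchors on both flanks of [a, b)."""
    for si in range(len(evaluator.readsets)):
        data = state.per_set[si].get(wid)
        if data is None:
            continue
        for lo, hi in data.intervals:
            if lo < a and hi > b:
                return True
    return False


def _unsupported_junction(
    state: EvalState, evaluator: Evaluator, wid: int, walk: Walk, graph: AssemblyGraph
):
    """First junction between consecutive long contigs of ``walk`` that no
    alignment interval bridges, as ``(elem_idx_a, elem_idx_b, contig_a)``.

    A walk can splice two distant regions through a run of repeat-shared
    short contigs traversed only once, which the multiplicity scan above
    never examines.  Genuine joins are bridged by a read or proper pair
    anchored on both sides; the spliced join is not, because each mate that
    should span it has its true partner in content absent from the walk.

    Bridges must penetrate half a read length into each side: a read
    straddling a repeat boundary can align a few bases past the junction of
    the *wrong* copy (soaking up the flank mismatches as errors), and such
    near-zero-weight hits must not count as support.
    """
    margin = max(1, evaluator.lr // 2)
    _, layout, _ = evaluator.render(walk)
    longs = []  # (elem_idx, span_start, span_end, contig)
    for i, (e, _s, t) in enumerate(layout):
        if e[0] == "node" and graph.node_len(e[1]) > evaluator.long_threshold:
            longs.append((i, t - graph.node_len(e[1]), t, e[1]))
    for (ia, _aa, ba, ca), (ib, ab, _bb, _cb) in zip(longs, longs[1:]):
        bridged = False
        for si in range(len(evaluator.readsets)):
            data = state.per_set[si].get(wid)
            if data is None:
                continue
            for lo, hi in data.intervals:
                if lo < ba - margin and hi > ab + margin:
                    bridged = True
                    break
            if bridged:
                break
        if not bridged:
            return ia, ib, ca
    return None


def _trimmed(piece: list) -> list:
    """Piece without leading/trailing N-gaps (a walk must not start or end
    with a scaffold gap)."""
    i, j = 0, len(piece)
    while i < j and piece[i][0] == "gap":
        i += 1
    while j > i and piece[j - 1][0] == "gap":
        j -= 1
    return piece[i:j]


def break_ambiguous(
    assembly: Assembly,
    graph: AssemblyGraph,
    evaluator: Evaluator,
    tolerance: float = 1e-3,
) -> tuple[Assembly, BreakReport, EvalState]:
    """Break every ambiguously phased repeat of ``assembly``.

    ``tolerance`` is the relative LAP margin below which two exit pairings
    count as indistinguishable.  Returns the broken assembly, a report of
    the repeats broken, and the evaluation state of the result.
    """
    work = assembly.copy()
    state = evaluator.evaluate(work)
    report = BreakReport()

    while True:
        usage = work.placed_contigs()
        candidates = sorted(
            cid
            for cid, n in usage.items()
            if n >= 2 and cid not in report.broken_contigs
        )
        broke = False
        for cid in candidates:
            # evidence test: every traversal must be spanned
            spanned = True
            for wid in sorted(work.walks):
                walk = work.walks[wid]
                if cid not in walk.contig_ids():
                    continue
                for a, b in _copy_spans(evaluator, walk, cid, graph):
                    if not _traversal_spanned(state, evaluator, wid, a, b):
                        spanned = False
                        break
                if not spanned:
                    break
            # score test: an alternative pairing within tolerance
            alternative = None
            if spanned:
                res = interchange_at_contig(work, state, evaluator, graph, cid)
                if res:
                    baseline, variants = res
                    if variants:
                        alternative = max(v[0] for v in variants)
                        margin = tolerance * max(1.0, abs(baseline))
                        if alternative >= baseline - margin:
                            spanned = False
            if spanned:
                continue

            cut = _traversal_pieces(work, cid)
            if cut is None:
                continue  # mixed-strand traversals: leave untouched
            pre_break_total = state.total
            pieces, _traversals, wids, _starts = cut
            new_walks = [Walk(p) for p in map(_trimmed, pieces) if p]
            new_walks.append(Walk([("node", cid, 1)]))
            new_ids = work.apply(wids, new_walks)
            state = evaluator.propose(state, wids, dict(zip(new_ids, new_walks)))
            report.records.append(
                BreakRecord(
                    contig=cid,
                    reason="score-tie" if alternative is not None else "unspanned",
                    baseline=pre_break_total,
                    alternative=alternative,
                )
            )
            broke = True
            break  # walk set changed; restart the scan
        if broke:
            continue
        # junction pass: cut joins between long contigs that no alignment
        # interval bridges (catches repeat splices traversed only once)
        for wid in sorted(work.walks):
            walk = work.walks[wid]
            bad = _unsupported_junction(state, evaluator, wid, walk, graph)
            if bad is None:
                continue
            ia, ib, ca = bad
            pre_break_total = state.total
            pieces = [
                walk.elements[: ia + 1],
                walk.elements[ia + 1 : ib],  # intervening shorts/gaps
                walk.elements[ib:],
            ]
            new_walks = [Walk(p) for p in map(_trimmed, pieces) if p]
            new_ids = work.apply([wid], new_walks)
            state = evaluator.propose(state, [wid], dict(zip(new_ids, new_walks)))
            report.records.append(
                BreakRecord(
                    contig=ca,
                    reason="unsupported-junction",
                    baseline=pre_break_total,
                    alternative=None,
                )
            )
            broke = True
            break
        if not broke:
            break
    return work, report, state
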