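"""Assembly likelihood evaluation with incremental caching.

Evaluating LAP from scratch means aligning every read against every walk.
Because an annealing move touches only one or two walks, almost all of that
work can be reused.  Three optimizations, layered here, make evaluation
incremental:

1. *Windows* — each walk is split into overlapping windows (adjacent windows
   overlap by at least ``2*l_r`` bases, ``l_r`` the longest read length, so
   every alignment lies fully inside at least one window).  Alignments are
   stored per window, keyed by the window's sequence content, so windows
   untouched by a move are never realigned.
2. *Interior masking* — the interior of a long contig never changes; when a
   window begins or ends with a long contig, only the ``2*l_r`` margins of
   that contig (plus everything between them) are realigned, and interior
   alignments come from a per-contig store computed once.
3. *Candidate filtering* — only reads sharing indexed features (k-mers or
   min-hashes) with the realigned span are aligned; long noisy reads are
   restricted by contig-overlap candidates.

The combine step merges per-walk hit stores into per-read probabilities
(floors applied), per-set LAPs, connectivity penalties and the weighted
total.  Apart from the alignment stores the combine is recomputed exactly
from the stored hits, so an incremental total equals a from-scratch
recomputation whenever the stores are correct — the property the test suite
checks move by move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import model
from .aligner import (
    KmerIndex,
    MinHashIndex,
    align_long_read,
    align_short_read,
    build_seed_index,
    long_read_candidates,
)
from .graph import Assembly, AssemblyGraph, Walk, walk_layout, walk_sequence
from .model import LapBreakdown, ModelParams, ReadSet, log_alignment_weight

__all__ = ["Window", "Evaluator", "EvalState", "partition_windows", "masked_realign_span"]

NEG_INF = -math.inf

# hit tuple: (entry, start, end, strand, matches, errors, log_weight)
Hit = tuple


@dataclass
class Window:
    """A span of one walk together with the elements it covers.

    ``start``/``end`` are walk coordinates; ``elements`` lists
    ``(element, elem_start, elem_end)`` for every walk element whose
    contributed span intersects the window.
    """

    start: int
    end: int
    elements: list[tuple]

    @property
    def length(self) -> int:
        return self.end - self.start


def partition_windows(layout: Sequence[tuple], total_len: int, lr: int) -> list[Window]:
    """Greedy left-to-right window partition of a walk.

    The first window extends at least ``2*lr`` bases beyond the boundary of
    the first element; each next window starts at the latest element
    boundary that preserves a ``2*lr`` overlap and extends at least ``2*lr``
    bases beyond the previous window's end.  Boundaries snap to element
    boundaries where possible.
    """
    if total_len <= 0:
        return []
    boundaries = sorted({end for _, _, end in layout} | {0, total_len})

    def elements_in(ws: int, we: int) -> list[tuple]:
        return [(e, s, t) for e, s, t in layout if s < we and t > ws]

    def next_boundary(pos: int) -> int:
        for b in boundaries:
            if b >= pos:
                return b
        return total_len

    windows: list[Window] = []
    start = 0
    first_end = layout[0][2] if layout else total_len
    end = next_boundary(first_end + 2 * lr)
    while True:
        end = min(end, total_len)
        if total_len - end < 2 * lr:  # a stub window would be redundant
            end = total_len
        windows.append(Window(start, end, elements_in(start, end)))
        if end >= total_len:
            break
        cands = [b for b in boundaries if b <= end - 2 * lr and b > start]
        start = max(cands) if cands else max(start + 1, end - 2 * lr)
        end = next_boundary(end + 2 * lr)
    return windows


def masked_realign_span(
    window: Window, lr: int, long_threshold: int = 500
) -> tuple[int, int, list[tuple]]:
    """Sub-span of a window that actually needs realignment.

    Returns ``(span_start, span_end, interior_contigs)`` in walk
    coordinates.  If the window begins (ends) with a long contig, only its
    last (first) ``2*lr`` bases are included; ``interior_contigs`` lists the
    ``(element, elem_start, elem_end)`` entries whose stored alignments are
    substituted for the excluded interiors.
    """
    span_start, span_end = window.start, window.end
    interiors: list[tuple] = []
    if not window.elements:
        return span_start, span_end, interiors
    first = window.elements[0]
    last = window.elements[-1]

    def is_long_node(entry: tuple) -> bool:
        elem = entry[0]
        return elem[0] == "node" and (entry[2] - entry[1]) > long_threshold

    if is_long_node(first):
        span_start = max(window.start, min(first[2], window.end) - 2 * lr)
        interiors.append(first)
    if is_long_node(last) and last is not first:
        span_end = min(window.end, max(last[1], window.start) + 2 * lr)
        interiors.append(last)
    elif is_long_node(first) and last is first:
        # the window is a single long contig: margins may even cross
        span_end = min(window.end, max(first[1], window.start) + 2 * lr)
    if span_end < span_start:
        span_end = span_start
    return span_start, span_end, interiors


@dataclass
class EvalState:
    """Cached evaluation of one assembly: per-walk stores plus the combined
    score.  States are cheap to copy; per-walk data is immutable and
    shared between states."""

    walks: dict[int, Walk]
    walk_len: dict[int, int]
    per_set: list[dict[int, "WalkSetData"]]
    total_length: int = 0
    breakdown: LapBreakdown | None = None

    @property
    def total(self) -> float:
        return self.breakdown.total if self.breakdown else NEG_INF

    def shallow_copy(self) -> "EvalState":
        return EvalState(
            dict(self.walks),
            dict(self.walk_len),
            [dict(d) for d in self.per_set],
            self.total_length,
            None,
        )


@dataclass
class WalkSetData:
    """One read set's alignment summary on one walk (immutable once built)."""

    entry_idx: np.ndarray  # read or pair indices with hits on this walk
    lognum: np.ndarray  # log numerator contribution of this walk per entry
    hits: dict  # entry -> tuple of hit tuples (walk coordinates)
    intervals: list  # coverage intervals for the connectivity penalty
    disconnected: int = 0


def _lru_put(cache: dict, key, value, cap: int) -> None:
    if len(cache) >= cap:
        for k in list(cache.keys())[: cap // 2]:
            del cache[k]
    cache[key] = value


class Evaluator:
    """Aligns read sets to assemblies and combines the LAP score.

    ``filter_backend`` selects the candidate prefilter for short-accurate
    sets (``"kmer"`` or ``"minhash"``).  Set ``paranoid=True`` to force full
    recomputation on every call (debugging aid).
    """

    def __init__(
        self,
        graph: AssemblyGraph | None,
        readsets: Sequence[ReadSet],
        long_threshold: int = 500,
        filter_backend: str = "kmer",
        index_k: int = 13,
        num_hashes: int = 3,
        max_hits: int = 10,
        max_edit_fraction: float = 0.1,
        seed: int = 0,
        paranoid: bool = False,
        cache_cap: int = 512,
    ):
        self.graph = graph
        self.readsets = list(readsets)
        self.long_threshold = long_threshold
        self.max_hits = max_hits
        self.max_edit_fraction = max_edit_fraction
        self.paranoid = paranoid
        self.cache_cap = cache_cap
        self.lr = max((rs.max_read_length for rs in self.readsets), default=100)

        self._indexes: list = []
        self._floors: list[np.ndarray] = []
        self._n_entries: list[int] = []
        for si, rs in enumerate(self.readsets):
            n = len(rs)
            self._n_entries.append(n)
            floors = np.array(
                [model.log_no_alignment_floor(rs.fragment_length(i), rs.params) for i in range(n)]
            )
            self._floors.append(floors)
            if rs.technology_class == "long-noisy":
                self._indexes.append(None)
            elif filter_backend == "minhash":
                idx = MinHashIndex(
                    k=index_k, num_hashes=num_hashes, seed=seed + si, read_length=rs.max_read_length
                )
                for i, seq in enumerate(rs.reads):
                    idx.add((i, 0), seq)
                if rs.paired and rs.mates:
                    for i, seq in enumerate(rs.mates):
                        idx.add((i, 1), seq)
                self._indexes.append(idx)
            else:
                idx = KmerIndex(k=index_k)
                for i, seq in enumerate(rs.reads):
                    idx.add((i, 0), seq)
                if rs.paired and rs.mates:
                    for i, seq in enumerate(rs.mates):
                        idx.add((i, 1), seq)
                self._indexes.append(idx)

        self._render_cache: dict = {}
        self._window_cache: dict = {}
        self._walk_cache: dict = {}
        self._contig_store: dict = {}
        self._long_candidates: list = [None] * len(self.readsets)

    # ------------------------------------------------------------------
    # rendering and windows
    # ------------------------------------------------------------------
    @staticmethod
    def walk_signature(walk: Walk) -> tuple:
        return tuple(tuple(e) for e in walk.elements)

    def render(self, walk: Walk):
        sig = self.walk_signature(walk)
        cached = self._render_cache.get(sig)
        if cached is not None:
            return cached
        if self.graph is not None:
            seq = walk_sequence(walk, self.graph)
            layout = walk_layout(walk, self.graph)
        else:
            seq, layout = self._render_raw(walk)
        windows = partition_windows(layout, len(seq), self.lr)
        rec = (seq, layout, windows)
        _lru_put(self._render_cache, sig, rec, self.cache_cap)
        return rec

    @staticmethod
    def _render_raw(walk: Walk):
        parts, layout, pos = [], [], 0
        for e in walk.elements:
            if e[0] == "gap":
                parts.append("N" * e[1])
                layout.append((e, pos, pos + e[1]))
                pos += e[1]
            elif e[0] == "seq":
                parts.append(e[1])
                layout.append((e, pos, pos + len(e[1])))
                pos += len(e[1])
            else:
                raise RuntimeError("node elements require a graph")
        return "".join(parts), layout

    # ------------------------------------------------------------------
    # alignment stores
    # ------------------------------------------------------------------
    def _contig_hits(self, set_idx: int, cid: int) -> tuple:
        """Alignments of a read set to one contig's forward sequence."""
        key = (set_idx, cid)
        hits = self._contig_store.get(key)
        if hits is None:
            seq = self.graph.contigs[cid]
            hits = tuple(self._align_span(set_idx, seq))
            self._contig_store[key] = hits
        return hits

    def _candidates(self, set_idx: int, span_seq: str):
        rs = self.readsets[set_idx]
        index = self._indexes[set_idx]
        if index is None:
            return None
        return sorted(index.candidates(span_seq, rs.max_read_length))

    def _align_span(self, set_idx: int, span_seq: str) -> list[Hit]:
        """All hits of one read set inside a sequence span (local coords)."""
        rs = self.readsets[set_idx]
        out: list[Hit] = []
        if rs.technology_class == "long-noisy":
            cand = self._long_read_filter(set_idx, span_seq)
            tindex = build_seed_index(span_seq, 11)
            for i in cand:
                for h in align_long_read(
                    rs.reads[i],
                    span_seq,
                    error_rate=rs.params.error_rate,
                    target_index=tindex,
                ):
                    out.append(((i, 0), h.start, h.end, h.strand, h.matches, h.errors, h.log_weight))
            return out
        tindex = build_seed_index(span_seq, 13)
        eps = rs.params.error_rate
        for entry in self._candidates(set_idx, span_seq):
            i, mate = entry
            seq = rs.reads[i] if mate == 0 else rs.mates[i]
            for h in align_short_read(
                seq,
                span_seq,
                max_edit_fraction=self.max_edit_fraction,
                max_hits=self.max_hits,
                target_index=tindex,
            ):
                lw = log_alignment_weight(h.errors, h.matches, eps)
                if lw == NEG_INF:
                    continue
                out.append((entry, h.start, h.end, h.strand, h.matches, h.errors, lw))
        return out

    def _long_read_filter(self, set_idx: int, span_seq: str) -> list[int]:
        """Long reads worth aligning to a span: contig-overlap candidates
        against the span treated as a single contig."""
        rs = self.readsets[set_idx]
        pairs = long_read_candidates({0: span_seq}, rs.reads, min_contig=100)
        return sorted(i for _, i in pairs)

    def _window_hits(self, set_idx: int, walk: Walk, window: Window, seq: str) -> tuple:
        """Deduplicated hits inside one window, in walk coordinates."""
        wseq = seq[window.start : window.end]
        layout_sig = tuple(
            (e[0], e[1] if e[0] != "seq" else len(e[1]), e[2] if len(e) > 2 else 0, s - window.start, t - window.start)
            for e, s, t in window.elements
        )
        key = (set_idx, wseq, layout_sig)
        off = window.start
        cached = self._window_cache.get(key)
        if cached is not None and not self.paranoid:
            # cache stores window-relative coordinates; shift to walk coords
            return tuple(
                (h[0], h[1] + off, h[2] + off, h[3], h[4], h[5], h[6]) for h in cached
            )

        span_start, span_end, interiors = masked_realign_span(
            window, self.lr, self.long_threshold
        )
        if self.graph is None or self.readsets[set_idx].technology_class == "long-noisy":
            # no per-contig store for raw sequences or banded long-read hits
            span_start, span_end, interiors = window.start, window.end, []

        hits: dict[tuple, Hit] = {}

        def put(h: Hit) -> None:
            k = (h[0], h[1], h[3])
            old = hits.get(k)
            if old is None or h[6] > old[6]:
                hits[k] = h

        if span_end > span_start:
            for h in self._align_span(set_idx, seq[span_start:span_end]):
                put((h[0], h[1] + span_start, h[2] + span_start, h[3], h[4], h[5], h[6]))
        k = self.graph.k if self.graph else 0
        for elem, es, ee in interiors:
            _, cid, strand = elem
            clen = self.graph.node_len(cid)
            full_start = ee - clen  # start of the contig's full placement
            visible_lo, visible_hi = es, ee
            for h in self._contig_hits(set_idx, cid):
                entry, hs, he, hstrand, m, s, lw = h
                if strand == 1:
                    ws_, we_ = full_start + hs, full_start + he
                    st = hstrand
                else:
                    ws_, we_ = full_start + (clen - he), full_start + (clen - hs)
                    st = -hstrand
                if ws_ < visible_lo or we_ > visible_hi:
                    continue
                put((entry, ws_, we_, st, m, s, lw))

        result = tuple(sorted(hits.values(), key=lambda h: (h[0], h[1], h[3])))
        rel = tuple(
            (h[0], h[1] - off, h[2] - off, h[3], h[4], h[5], h[6]) for h in result
        )
        _lru_put(self._window_cache, key, rel, self.cache_cap * 4)
        return result

    # ------------------------------------------------------------------
    # per-walk data
    # ------------------------------------------------------------------
    def walk_set_data(self, set_idx: int, walk: Walk, use_cache: bool = True) -> WalkSetData:
        sig = (set_idx, self.walk_signature(walk))
        if use_cache and not self.paranoid:
            cached = self._walk_cache.get(sig)
            if cached is not None:
                return cached
        seq, layout, windows = self.render(walk)
        merged: dict[tuple, Hit] = {}
        for window in windows:
            for h in self._window_hits(set_idx, walk, window, seq):
                k = (h[0], h[1], h[3])
                old = merged.get(k)
                if old is None or h[6] > old[6]:
                    merged[k] = h
        by_entry: dict = {}
        for h in merged.values():
            by_entry.setdefault(h[0], []).append(h)
        data = self._summarise_walk(set_idx, layout, len(seq), by_entry)
        if use_cache and not self.paranoid:
            _lru_put(self._walk_cache, sig, data, self.cache_cap)
        return data

    def _summarise_walk(
        self, set_idx: int, layout, length: int, by_entry: dict
    ) -> WalkSetData:
        rs = self.readsets[set_idx]
        params = rs.params
        idx_list: list[int] = []
        num_list: list[float] = []
        intervals: list[tuple[int, int]] = []
        hits_out: dict = {}

        if rs.paired:
            pair_ids = sorted({e[0] for e in by_entry})
            for i in pair_ids:
                h1 = by_entry.get((i, 0), [])
                h2 = by_entry.get((i, 1), [])
                if h1:
                    hits_out[(i, 0)] = tuple(h1)
                if h2:
                    hits_out[(i, 1)] = tuple(h2)
                terms: list[float] = []
                proper: list[tuple[int, int]] = []
                for a in h1:
                    for b in h2:
                        d = _pair_distance(a, b, params.orientation)
                        if d is None:
                            continue
                        terms.append(
                            a[6] + b[6] + model.log_insert_density(d, params.insert_mean, params.insert_sd)
                        )
                        if abs(d - params.insert_mean) <= 4 * params.insert_sd:
                            proper.append((min(a[1], b[1]), max(a[2], b[2])))
                if terms:
                    idx_list.append(i)
                    num_list.append(_logsumexp(terms))
                if proper:
                    intervals.extend(proper)
                else:
                    intervals.extend((h[1], h[2]) for h in h1)
                    intervals.extend((h[1], h[2]) for h in h2)
        else:
            for entry in sorted(by_entry):
                hs = by_entry[entry]
                hits_out[entry] = tuple(hs)
                idx_list.append(entry[0])
                num_list.append(_logsumexp([h[6] for h in hs]))
                intervals.extend((h[1], h[2]) for h in hs)

        # N-gaps are deliberately NOT exempt: a scaffold join is only free of
        # penalty when proper pairs (or long reads) actually span the gap.
        d, _ = model.connectivity_penalty({0: length}, {0: intervals}, params)
        return WalkSetData(
            entry_idx=np.array(idx_list, dtype=np.int64),
            lognum=np.array(num_list, dtype=float),
            hits=hits_out,
            intervals=intervals,
            disconnected=d,
        )

    # ------------------------------------------------------------------
    # evaluation entry points
    # ------------------------------------------------------------------
    def evaluate(self, assembly: Assembly, use_cache: bool = True) -> EvalState:
        """Score a whole assembly (walk and window stores reused if warm)."""
        walks = {wid: w for wid, w in assembly.walks.items()}
        walk_len: dict[int, int] = {}
        per_set: list[dict[int, WalkSetData]] = [dict() for _ in self.readsets]
        for wid in sorted(walks):
            seq, _, _ = self.render(walks[wid])
            walk_len[wid] = len(seq)
            for si in range(len(self.readsets)):
                per_set[si][wid] = self.walk_set_data(si, walks[wid], use_cache)
        state = EvalState(walks, walk_len, per_set, sum(walk_len.values()))
        state.breakdown = self._combine(state)
        return state

    def full_recompute(self, assembly: Assembly) -> LapBreakdown:
        """From-scratch total (window/walk caches bypassed): the oracle the
        incremental path is checked against."""
        walk_cache, window_cache = self._walk_cache, self._window_cache
        render_cache = self._render_cache
        self._walk_cache, self._window_cache, self._render_cache = {}, {}, {}
        try:
            state = self.evaluate(assembly, use_cache=False)
        finally:
            self._walk_cache, self._window_cache, self._render_cache = (
                walk_cache,
                window_cache,
                render_cache,
            )
        return state.breakdown

    def propose(
        self, state: EvalState, removed: Sequence[int], added: dict[int, Walk]
    ) -> EvalState:
        """State for the assembly with ``removed`` walk ids dropped and
        ``added`` (id -> walk) evaluated; untouched walks are reused."""
        new = state.shallow_copy()
        for wid in removed:
            new.walks.pop(wid)
            new.total_length -= new.walk_len.pop(wid)
            for si in range(len(self.readsets)):
                new.per_set[si].pop(wid)
        for wid, walk in sorted(added.items()):
            seq, _, _ = self.render(walk)
            new.walks[wid] = walk
            new.walk_len[wid] = len(seq)
            new.total_length += len(seq)
            for si in range(len(self.readsets)):
                new.per_set[si][wid] = self.walk_set_data(si, walk)
        new.breakdown = self._combine(new)
        return new

    # ------------------------------------------------------------------
    def _combine(self, state: EvalState) -> LapBreakdown:
        """Merge per-walk stores into the weighted, penalized total."""
        L = max(state.total_length, 1)
        log2L = math.log(2.0 * L)
        laps: list[float] = []
        disconnected: list[int] = []
        params = [rs.params for rs in self.readsets]
        for si, rs in enumerate(self.readsets):
            n = self._n_entries[si]
            num = np.full(n, NEG_INF)
            d = 0
            for wid in sorted(state.per_set[si]):
                data = state.per_set[si][wid]
                d += data.disconnected
                if data.entry_idx.size:
                    num[data.entry_idx] = np.logaddexp(num[data.entry_idx], data.lognum)
            vals = np.maximum(num - log2L, self._floors[si])
            laps.append(float(vals.mean()))
            disconnected.append(d)
        return model.combined_lap(laps, disconnected, params)


def _pair_distance(a: Hit, b: Hit, orientation: str):
    if a[3] == b[3]:
        return None
    left, right = (a, b) if a[1] <= b[1] else (b, a)
    if orientation == "fr":
        if left[3] != 1 or right[3] != -1:
            return None
    else:
        if left[3] != -1 or right[3] != 1:
            return None
    return float(right[2] - left[1])


def _logsumexp(values: list[float]) -> float:
    m = max(values)
    if m == NEG_INF:
        return NEG_INF
    return m + math.log(sum(math.exp(v - m) for v in values))
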