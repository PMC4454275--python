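import numpy as np
import pytest

from lapasm import Assembly, Walk
from lapasm.evaluation import (
    Evaluator,
    masked_realign_span,
    partition_windows,
    Window,
)
from lapasm.graph import initial_assembly, map_external_assembly, walk_layout
from lapasm.sequtils import revcomp


class TestWindows:
    def _layout(self, lengths):
        layout, pos = [], 0
        for i, n in enumerate(lengths):
            layout.append((("node", i, 1), pos, pos + n))
            pos += n
        return layout, pos

    def test_single_window_for_short_walk(self):
        layout, total = self._layout([300])
        windows = partition_windows(layout, total, lr=100)
        assert len(windows) == 1
        assert (windows[0].start, windows[0].end) == (0, 300)

    def test_overlap_at_least_2lr(self):
        layout, total = self._layout([900, 40, 900, 40, 900, 40, 900])
        lr = 100
        windows = partition_windows(layout, total, lr)
        assert windows[0].start == 0 and windows[-1].end == total
        for a, b in zip(windows, windows[1:]):
            assert b.start < a.end
            assert a.end - b.start >= 2 * lr
        # every walk position is inside some window
        covered = np.zeros(total, dtype=bool)
        for w in windows:
            covered[w.start : w.end] = True
        assert covered.all()

    def test_masked_span_keeps_margins_of_long_contigs(self):
        layout, total = self._layout([2000, 50, 2000])
        windows = partition_windows(layout, total, lr=100)
        w = windows[0]
        span_start, span_end, interiors = masked_realign_span(w, lr=100, long_threshold=500)
        assert span_start == 2000 - 200  # last 2*lr bases of the leading long contig
        assert interiors and interiors[0][0][1] == 0

    def test_empty_layout(self):
        assert partition_windows([], 0, 100) == []


class TestEvaluator:
    def test_incremental_equals_full_on_initial(self, small_eval):
        ev, asm = small_eval["evaluator"], small_eval["assembly"]
        st = ev.evaluate(asm)
        assert ev.full_recompute(asm).total == pytest.approx(st.total, abs=1e-9)

    def test_propose_equals_fresh_evaluation(self, small_eval):
        ev, asm = small_eval["evaluator"], small_eval["assembly"]
        st = ev.evaluate(asm)
        wids = sorted(asm.walks)
        a, b = wids[0], wids[1]
        # join two walks with a scaffold gap and drop another
        joined = Walk(asm.walks[a].elements + [("gap", 200)] + asm.walks[b].elements)
        new_asm = asm.copy()
        new_ids = new_asm.apply([a, b], [joined])
        inc = ev.propose(st, [a, b], dict(zip(new_ids, [joined])))
        fresh = ev.full_recompute(new_asm)
        assert inc.total == pytest.approx(fresh.total, abs=1e-9)

    def test_reversed_walk_scores_identically(self, small_eval):
        ev, asm = small_eval["evaluator"], small_eval["assembly"]
        st = ev.evaluate(asm)
        wid = sorted(asm.walks)[0]
        rev = asm.walks[wid].reverse()
        inc = ev.propose(st, [wid], {wid: rev})
        assert inc.total == pytest.approx(st.total, abs=1e-6)

    def test_raw_sequence_matches_graph_walk(self, small_eval):
        """The same sequence scores the same whether rendered from graph
        nodes or given as a raw string."""
        ev, asm = small_eval["evaluator"], small_eval["assembly"]
        graph, rs = small_eval["graph"], small_eval["readset"]
        st = ev.evaluate(asm)
        seqs = list(asm.sequences(graph).values())
        ev_raw = Evaluator(None, [rs], seed=0)
        raw_asm = Assembly.from_walks(Walk([("seq", s)]) for s in seqs)
        st_raw = ev_raw.evaluate(raw_asm)
        assert st_raw.total == pytest.approx(st.total, abs=1e-6)

    def test_truth_beats_fragmented_assembly(self, small_eval):
        genome, rs = small_eval["genome"], small_eval["readset"]
        graph, asm = small_eval["graph"], small_eval["assembly"]
        ev = small_eval["evaluator"]
        ev_raw = Evaluator(None, [rs], seed=0)
        truth = ev_raw.evaluate(Assembly.from_walks([Walk([("seq", genome)])]))
        frag = ev.evaluate(asm)
        # compare the likelihood terms: the connectivity penalty exempts walk
        # starts, so raw totals are not comparable across walk counts
        assert truth.breakdown.per_set_lap[0] > frag.breakdown.per_set_lap[0] + 1.0

    def test_minhash_backend_agrees_with_kmer(self, small_world):
        graph, rs = small_world["graph"], small_world["readset"]
        asm = initial_assembly(graph)
        lap_k = Evaluator(graph, [rs], filter_backend="kmer", seed=1).evaluate(asm)
        lap_m = Evaluator(graph, [rs], filter_backend="minhash", seed=1).evaluate(asm)
        # min-hash is a probabilistic prefilter: a small sensitivity loss is
        # expected, but the totals must agree to within a percent
        assert lap_m.total == pytest.approx(lap_k.total, rel=1e-2)

    def test_true_join_beats_gap_disruption(self, small_eval):
        """On the truth walk, tearing a junction open with a large N-gap
        must lower the score: spanning pairs lose their insert term and the
        added length shrinks every read's probability."""
        ev = small_eval["evaluator"]
        genome, graph = small_eval["genome"], small_eval["graph"]
        truth = map_external_assembly([genome], graph)
        wid = next(iter(truth.walks))
        walk = truth.walks[wid]
        nodes = [i for i, e in enumerate(walk.elements) if e[0] == "node"]
        mid = nodes[len(nodes) // 2]
        disrupted = Walk(walk.elements[:mid] + [("gap", 5000)] + walk.elements[mid:])
        st = ev.evaluate(truth)
        alt = ev.propose(st, [wid], {-1: disrupted})
        assert alt.total < st.total - 1.0
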