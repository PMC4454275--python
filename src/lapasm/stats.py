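"""Assembly quality statistics against a known truth genome.

Contiguity (N50 over the truth length, so fragmentations are not rewarded)
and correctness (misjoins counted by anchoring contig substrings on the
truth and looking for breaks in colinearity).
"""

from __future__ import annotations

from typing import Sequence

from .sequtils import revcomp

__all__ = ["n50", "count_misjoins", "compute_stats"]


def n50(lengths: Sequence[int], reference_length: int | None = None) -> int:
    """Smallest length such that pieces at least that long cover half the
    reference (the assembly's own length when no reference is given)."""
    if not lengths:
        return 0
    total = reference_length if reference_length else sum(lengths)
    half = total / 2.0
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= half:
            return length
    return 0


def _anchor_positions(truth: str, anchor_len: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    rc = revcomp(truth)
    n = len(truth)
    for i in range(0, n - anchor_len + 1):
        index.setdefault(truth[i : i + anchor_len], []).append((i, 1))
    for i in range(0, n - anchor_len + 1):
        # position reported on the forward strand of the truth
        index.setdefault(rc[i : i + anchor_len], []).append((n - i - anchor_len, -1))
    return index


def count_misjoins(
    sequences: Sequence[str],
    truth: str,
    anchor_len: int = 100,
    step: int = 200,
    tolerance: int | None = None,
) -> int:
    """Breaks in colinearity of contig anchors on the truth genome.

    Every ``step`` bases an ``anchor_len``-mer of the contig is located
    exactly in the truth (either strand); anchors with no exact, unique hit
    (sequencing errors, Ns, repeat copies) are skipped.  Anchors are grouped
    into colinear runs (same strand, truth distance matching contig distance
    within ``tolerance``, default ``2 * step``); a break between two runs of
    at least two anchors each counts as one misjoin.  Single-anchor runs are
    discarded: a lone jumping anchor is far more likely a consensus base
    error inside a near-identical repeat copy (which makes the anchor match
    the *other* copy exactly) than a real structural break.
    """
    if tolerance is None:
        tolerance = 2 * step

    def colinear(a, b):
        (pa, ta, sa), (pb, tb, sb) = a, b
        return sa == sb and abs((tb - ta) * sa - (pb - pa)) <= tolerance

    index = _anchor_positions(truth, anchor_len)
    misjoins = 0
    for seq in sequences:
        blocks: list[list] = [[]]  # anchor chains between scaffold gaps
        for pos in range(0, max(1, len(seq) - anchor_len + 1), step):
            anchor = seq[pos : pos + anchor_len]
            if len(anchor) < anchor_len:
                continue
            if "N" in anchor:
                if blocks[-1]:
                    blocks.append([])  # a scaffold gap resets colinearity
                continue
            hits = index.get(anchor)
            if not hits or len(hits) > 1:
                continue  # ambiguous (repeat) or erroneous anchor
            blocks[-1].append((pos, hits[0][0], hits[0][1]))
        for anchors in blocks:
            runs: list[list] = []
            for a in anchors:
                if runs and colinear(runs[-1][-1], a):
                    runs[-1].append(a)
                else:
                    runs.append([a])
            merged: list[list] = []
            for r in runs:
                if len(r) < 2:
                    continue  # stray anchor, see docstring
                if merged and colinear(merged[-1][-1], r[0]):
                    merged[-1].extend(r)
                else:
                    merged.append(r)
            misjoins += max(0, len(merged) - 1)
    return misjoins


def compute_stats(
    sequences: Sequence[str],
    truth: str | None = None,
    anchor_len: int = 100,
    step: int = 200,
) -> dict:
    lengths = [len(s) for s in sequences]
    out = {
        "num_sequences": len(sequences),
        "total_length": sum(lengths),
        "largest": max(lengths, default=0),
        "n50": n50(lengths),
    }
    if truth is not None:
        out["truth_length"] = len(truth)
        out["n50_truth"] = n50(lengths, len(truth))
        out["misjoins"] = count_misjoins(sequences, truth, anchor_len, step)
    return out
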