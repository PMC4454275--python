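"""Probabilistic read–assembly likelihood model.

The assembly score is the log average probability (LAP) of a read: for a read
set ``R`` and assembly ``A``,

    LAP(A|R) = (1/|R|) * sum_r log Pr(r|A),

where ``Pr(r|A)`` is approximated from a set ``S_r`` of best alignments of the
read to the assembly.  Each alignment with ``m`` matching bases and ``s``
errors (substitutions and indels, sharing a single per-base error rate
``epsilon``) contributes ``R(s, m) = epsilon**s * (1-epsilon)**m``; a single
read's probability is ``sum_j R(s_j, m_j) / (2L)`` with ``L`` the total
assembly length (both strands combined give the ``2L`` normaliser).  Paired
reads additionally weight every consistent pair of placements by a normal
density on the observed insert size.  Reads with no good alignment receive a
length-dependent floor ``exp(c + k*l)`` approximating the cost of adding the
read as its own contig.  Scores of several read sets are combined linearly
with per-set weights, after subtracting a per-set penalty ``alpha * d`` for
``d`` bases not "connected" by any read (a guard against spuriously joined
contigs).

All probabilities are handled in natural-log space internally so that long,
noisy reads (whose linear-space weights underflow) are scored exactly like
short ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "AlignmentHit",
    "ReadSet",
    "LapBreakdown",
    "log_alignment_weight",
    "single_read_probability",
    "single_read_log_probability",
    "paired_read_probability",
    "paired_read_log_probability",
    "no_alignment_floor",
    "default_noalign_scale",
    "log_no_alignment_floor",
    "read_set_lap",
    "connectivity_penalty",
    "combined_lap",
]

LOG_2PI = math.log(2.0 * math.pi)


class ModelConfigError(ValueError):
    """Raised for invalid or missing model parameters."""


@dataclass
class ModelParams:
    """Per-read-set model parameters.

    Parameters
    ----------
    error_rate:
        Per-base sequencing error probability ``epsilon`` (substitutions and
        indels share it).
    insert_mean, insert_sd:
        Mean and standard deviation of the insert-size distribution, in bases
        (paired sets only).
    weight:
        Nonnegative weight of this set in the combined score.
    noalign_offset, noalign_scale:
        Constants ``c`` and ``k`` of the no-alignment floor ``exp(c + k*l)``;
        ``noalign_scale`` must be negative so longer reads get lower floors.
    conn_window:
        Connectivity window: base ``j`` counts as connected if some read
        covers it and starts at least ``conn_window`` bases before it.
    penalty_alpha:
        Penalty per disconnected base, subtracted from the set's LAP.
    orientation:
        Expected relative strand of mates: ``"fr"`` (innie, fragment
        libraries) or ``"rf"`` (outie, mate pairs).
    exempt_walk_starts:
        If true, the first and last ``conn_window`` bases of each walk are
        exempt from the disconnected count: at the start no placement can
        begin ``conn_window`` bases earlier, and the end is exempted
        symmetrically.  N-gaps are never exempt: a scaffold join escapes
        the penalty only when pairs or long reads truly span it.
    """

    error_rate: float = 0.01
    insert_mean: float | None = None
    insert_sd: float | None = None
    weight: float = 1.0
    noalign_offset: float = -15.0
    noalign_scale: float = -0.2
    conn_window: int = 50
    penalty_alpha: float = 3.0
    orientation: str = "fr"
    exempt_walk_starts: bool = True

    def validate(self, paired: bool = False) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ModelConfigError(f"error_rate must be in [0, 1): {self.error_rate}")
        if self.weight < 0:
            raise ModelConfigError("weight must be nonnegative")
        if self.penalty_alpha < 0:
            raise ModelConfigError("penalty_alpha must be nonnegative")
        if self.conn_window < 1:
            raise ModelConfigError("conn_window must be >= 1")
        if self.noalign_scale >= 0:
            raise ModelConfigError("noalign_scale must be negative")
        if paired:
            if self.insert_mean is None or self.insert_sd is None:
                raise ModelConfigError("paired read set requires insert_mean and insert_sd")
            if self.insert_sd <= 0:
                raise ModelConfigError("insert_sd must be positive")
        if self.orientation not in ("fr", "rf"):
            raise ModelConfigError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class AlignmentHit:
    """One candidate placement of a read on a walk.

    ``start``/``end`` are 0-based half-open coordinates on the walk's forward
    strand; ``strand`` is ``+1`` or ``-1``.  ``matches``/``errors`` are the
    match count ``m`` and edit-operation count ``s`` of the alignment.  For
    long noisy reads, ``log_weight`` may carry a precomputed log probability
    mass (from the banded forward algorithm) that replaces ``R(s, m)``.
    """

    walk_id: int
    start: int
    end: int
    strand: int
    matches: int
    errors: int
    log_weight: float | None = None

    def __post_init__(self) -> None:
        if self.matches + self.errors < 1:
            raise ValueError("alignment must contain at least one operation")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")


@dataclass
class ReadSet:
    """A collection of reads plus the parameters of its model term.

    ``reads`` (and ``mates`` when ``paired``) are uppercase DNA strings.
    ``technology_class`` selects the alignment backend: ``"short-accurate"``
    (seeded edit-distance alignment) or ``"long-noisy"`` (seed-chain guide
    plus banded forward).
    """

    reads: list[str]
    params: ModelParams
    paired: bool = False
    mates: list[str] | None = None
    technology_class: str = "short-accurate"
    name: str = "reads"
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.params.validate(paired=self.paired)
        if self.paired:
            if self.mates is None or len(self.mates) != len(self.reads):
                raise ModelConfigError("paired set must carry one mate per read")
        if any(len(r) < 1 for r in self.reads):
            raise ModelConfigError("read lengths must be >= 1")
        if self.mates and any(len(r) < 1 for r in self.mates):
            raise ModelConfigError("read lengths must be >= 1")

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def max_read_length(self) -> int:
        longest = max((len(r) for r in self.reads), default=0)
        if self.mates:
            longest = max(longest, max(len(r) for r in self.mates))
        return longest

    def fragment_length(self, i: int) -> int:
        """Total sequenced bases of read (pair) ``i``, used by the floor."""
        n = len(self.reads[i])
        if self.paired and self.mates is not None:
            n += len(self.mates[i])
        return n


@dataclass
class LapBreakdown:
    """Per-set LAP values, penalties and the combined weighted total."""

    per_set_lap: list[float] = field(default_factory=list)
    disconnected_bases: list[int] = field(default_factory=list)
    penalties: list[float] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)
    total: float = 0.0

    def copy(self) -> "LapBreakdown":
        return replace(
            self,
            per_set_lap=list(self.per_set_lap),
            disconnected_bases=list(self.disconnected_bases),
            penalties=list(self.penalties),
            weights=list(self.weights),
        )


def log_alignment_weight(errors: int, matches: int, error_rate: float) -> float:
    """log R(s, m) = s*log(eps) + m*log(1-eps), with the eps=0 limit."""
    if error_rate == 0.0:
        return 0.0 if errors == 0 else -math.inf
    return errors * math.log(error_rate) + matches * math.log1p(-error_rate)


def _hit_log_weight(hit: AlignmentHit, error_rate: float) -> float:
    if hit.log_weight is not None:
        return hit.log_weight
    return log_alignment_weight(hit.errors, hit.matches, error_rate)


def single_read_log_probability(
    hits: Iterable[AlignmentHit], genome_length: int, params: ModelParams
) -> float:
    """log of ``sum_j R(s_j, m_j) / (2L)``; ``-inf`` for an empty hit set."""
    if genome_length < 1:
        raise ValueError(f"genome length must be positive: {genome_length}")
    weights = [_hit_log_weight(h, params.error_rate) for h in hits]
    if not weights:
        return -math.inf
    m = max(weights)
    if m == -math.inf:
        return -math.inf
    total = m + math.log(sum(math.exp(w - m) for w in weights))
    return total - math.log(2.0 * genome_length)


def single_read_probability(
    hits: Iterable[AlignmentHit], genome_length: int, params: ModelParams
) -> float:
    """``Pr(r|A) ~= sum_j R(s_j, m_j) / (2L)``; 0 for an empty hit set.

    The caller substitutes the no-alignment floor whenever the returned
    probability falls below it.
    """
    lp = single_read_log_probability(hits, genome_length, params)
    return 0.0 if lp == -math.inf else math.exp(lp)


def log_insert_density(distance: float, mean: float, sd: float) -> float:
    """Normal log-density of an observed insert size."""
    z = (distance - mean) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * LOG_2PI


def pair_distance(h1: AlignmentHit, h2: AlignmentHit, orientation: str) -> float | None:
    """Observed insert size for a consistent placement of a mate pair.

    Returns ``None`` when the two placements are on different walks or on
    inconsistent strands.  For ``"fr"`` libraries the leftmost placement must
    be on the forward strand and the rightmost on the reverse strand (the
    opposite for ``"rf"``); the insert is measured between the outermost
    aligned bases.
    """
    if h1.walk_id != h2.walk_id or h1.strand == h2.strand:
        return None
    left, right = (h1, h2) if h1.start <= h2.start else (h2, h1)
    if orientation == "fr":
        if left.strand != 1 or right.strand != -1:
            return None
    else:  # rf
        if left.strand != -1 or right.strand != 1:
            return None
    return float(right.end - left.start)


def paired_read_log_probability(
    hits1: Iterable[AlignmentHit],
    hits2: Iterable[AlignmentHit],
    genome_length: int,
    params: ModelParams,
) -> float:
    """log of the double sum of Eq-style pair terms over consistent placements."""
    if genome_length < 1:
        raise ValueError(f"genome length must be positive: {genome_length}")
    if params.insert_mean is None or params.insert_sd is None:
        raise ModelConfigError("paired probability requires insert_mean and insert_sd")
    terms: list[float] = []
    hits2 = list(hits2)
    for h1 in hits1:
        w1 = _hit_log_weight(h1, params.error_rate)
        if w1 == -math.inf:
            continue
        for h2 in hits2:
            d = pair_distance(h1, h2, params.orientation)
            if d is None:
                continue
            w2 = _hit_log_weight(h2, params.error_rate)
            if w2 == -math.inf:
                continue
            terms.append(w1 + w2 + log_insert_density(d, params.insert_mean, params.insert_sd))
    if not terms:
        return -math.inf
    m = max(terms)
    total = m + math.log(sum(math.exp(t - m) for t in terms))
    return total - math.log(2.0 * genome_length)


def paired_read_probability(
    hits1: Iterable[AlignmentHit],
    hits2: Iterable[AlignmentHit],
    genome_length: int,
    params: ModelParams,
) -> float:
    lp = paired_read_log_probability(hits1, hits2, genome_length, params)
    return 0.0 if lp == -math.inf else math.exp(lp)


def log_no_alignment_floor(read_lengths: Sequence[int] | int, params: ModelParams) -> float:
    """``c + k * sum(l)``: log-space floor for a read (pair) with no alignment."""
    if isinstance(read_lengths, int):
        read_lengths = (read_lengths,)
    total = sum(read_lengths)
    if total < 1:
        raise ValueError("read length must be >= 1")
    return params.noalign_offset + params.noalign_scale * total


def no_alignment_floor(read_lengths: Sequence[int] | int, params: ModelParams) -> float:
    """``exp(c + k * sum(l))``, substituted whenever Pr(r|A) is lower."""
    return math.exp(log_no_alignment_floor(read_lengths, params))


def default_noalign_scale(error_rate: float, technology_class: str) -> float:
    """Per-base slope ``k`` of the no-alignment floor.

    The floor must lie below the weight of a typical genuine placement,
    whose per-base log-likelihood is ``eps*ln(eps) + (1-eps)*ln(1-eps)``.
    For accurate short reads (that value is above -0.2 for eps <= 2%) the
    conventional ``-0.2`` works; for noisy long reads the slope is set 50%
    below the typical placement so real alignments always clear the floor.
    """
    if technology_class == "short-accurate" or error_rate <= 0:
        return -0.2
    per_base = error_rate * math.log(error_rate) + (1 - error_rate) * math.log1p(-error_rate)
    return min(-0.2, 1.5 * per_base)


def read_set_lap(per_read_probabilities: Sequence[float]) -> float:
    """Log average probability: mean of natural logs (floors already applied)."""
    if len(per_read_probabilities) == 0:
        raise ModelConfigError("LAP of an empty read set is undefined")
    if any(p <= 0 for p in per_read_probabilities):
        raise RuntimeError("zero probability reached LAP; the floor was skipped")
    return float(np.mean(np.log(per_read_probabilities)))


def read_set_lap_from_logs(per_read_log_probabilities: Sequence[float]) -> float:
    """LAP from already-log per-read values (the internal fast path)."""
    arr = np.asarray(per_read_log_probabilities, dtype=float)
    if arr.size == 0:
        raise ModelConfigError("LAP of an empty read set is undefined")
    if not np.all(np.isfinite(arr)):
        raise RuntimeError("non-finite log probability reached LAP; the floor was skipped")
    return float(arr.mean())


def connected_mask(
    length: int,
    intervals: Iterable[tuple[int, int]],
    conn_window: int,
    exempt_intervals: Iterable[tuple[int, int]] = (),
) -> np.ndarray:
    """Boolean mask of bases that are connected (or exempt) on one walk.

    ``intervals`` are half-open spans of accepted read placements (a properly
    oriented pair contributes one interval over its whole insert).  Base ``j``
    is connected if some interval ``[s, e)`` has ``s <= j - conn_window`` and
    ``j < e``.  ``exempt_intervals`` mark bases excluded from the
    disconnected count (walk boundaries).
    """
    diff = np.zeros(length + 1, dtype=np.int64)
    for s, e in intervals:
        lo = s + conn_window
        if lo >= e or lo >= length:
            continue
        diff[max(lo, 0)] += 1
        diff[min(e, length)] -= 1
    mask = np.cumsum(diff[:-1]) > 0
    for s, e in exempt_intervals:
        s = max(s, 0)
        e = min(e, length)
        if s < e:
            mask[s:e] = True
    return mask


def connectivity_penalty(
    walk_lengths: Mapping[int, int],
    covering_alignments: Mapping[int, Iterable[tuple[int, int]]],
    params: ModelParams,
    exempt: Mapping[int, Iterable[tuple[int, int]]] | None = None,
) -> tuple[int, float]:
    """Count disconnected bases over all walks and the penalty ``alpha * d``.

    ``covering_alignments`` maps walk id to the accepted placement intervals
    of one read set (pairs merged into single spans).  ``exempt`` optionally
    maps walk id to intervals excluded from the count.
    """
    d = 0
    for wid, length in walk_lengths.items():
        intervals = list(covering_alignments.get(wid, ()))
        ex = list(exempt.get(wid, ())) if exempt else []
        if params.exempt_walk_starts:
            # symmetric boundary exemption: the first conn_window-1 bases can
            # never satisfy "starts conn_window before", and the last ones are
            # connectable only by an interval ending exactly at the walk end
            ex.append((0, params.conn_window))
            ex.append((length - params.conn_window, length))
        mask = connected_mask(length, intervals, params.conn_window, ex)
        d += int(length - mask.sum())
    return d, params.penalty_alpha * d


def combined_lap(
    per_set_laps: Sequence[float],
    disconnected: Sequence[int],
    params: Sequence[ModelParams],
) -> LapBreakdown:
    """Weighted combination ``sum_i w_i * (LAP_i - alpha_i * d_i)``.

    Each set's connectivity penalty is applied to its own LAP term before
    weighting, so a zero-weight set contributes nothing at all.
    """
    if not (len(per_set_laps) == len(disconnected) == len(params)):
        raise ModelConfigError("mismatched read set / weight counts")
    breakdown = LapBreakdown()
    total = 0.0
    for lap, d, p in zip(per_set_laps, disconnected, params):
        pen = p.penalty_alpha * d
        breakdown.per_set_lap.append(lap)
        breakdown.disconnected_bases.append(int(d))
        breakdown.penalties.append(pen)
        breakdown.weights.append(p.weight)
        total += p.weight * (lap - pen)
    breakdown.total = total
    return breakdown
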