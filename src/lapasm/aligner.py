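"""Read alignment and candidate filtering.

Produces the alignment sets that feed the likelihood model:

* ``KmerIndex`` / ``MinHashIndex`` — prefilters mapping a changed target
  sequence to the (hopefully small) set of reads that might align there.
  The min-hash index exploits ``Pr(m(A) = m(B)) = J(A, B)``: two sequences
  with similar k-mer content collide under a random hash function with
  probability equal to their Jaccard similarity, so storing each read once
  per hash function gives a compact, high-precision filter.
* ``align_short_read`` — seeded edit-distance alignment (shared k-mer
  diagonals, then banded alignment with edlib) returning the few best
  placements on both strands.
* ``banded_forward`` — sums alignment-path probabilities in a band around a
  guide alignment, for long reads whose error rate makes any single
  alignment a poor estimate of the read's probability mass.
* ``align_long_read`` / ``long_read_candidates`` — seed-and-extend guide
  alignments between long noisy reads and contigs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .sequtils import canonical, kmer_set, kmers, pack_kmer, pack_kmers_array, revcomp

__all__ = [
    "KmerIndex",
    "MinHashIndex",
    "GuideAlignment",
    "RawHit",
    "minhash",
    "hash_kmers",
    "align_short_read",
    "align_long_read",
    "banded_forward",
    "full_forward",
    "long_read_candidates",
]

_M1 = np.uint64(0xFF51AFD7ED558CCD)
_M2 = np.uint64(0xC4CEB9FE1A85EC53)
_S33 = np.uint64(33)


def _murmur_finalize(x: np.ndarray) -> np.ndarray:
    """64-bit Murmur3 finalizer (integer avalanche mixing)."""
    x = x.astype(np.uint64, copy=True)
    x ^= x >> _S33
    x *= _M1
    x ^= x >> _S33
    x *= _M2
    x ^= x >> _S33
    return x


def hash_kmers(packed: np.ndarray, seed: int) -> np.ndarray:
    """Hash 2-bit-packed k-mers: xor with a per-function seed, then mix."""
    return _murmur_finalize(packed ^ np.uint64(seed))


def minhash(kmer_collection: Iterable[str] | np.ndarray, seed: int) -> int:
    """Minimum hash value over a k-mer set; deterministic given ``seed``."""
    if isinstance(kmer_collection, np.ndarray):
        packed = kmer_collection
    else:
        packed = np.array([pack_kmer(km) for km in kmer_collection], dtype=np.uint64)
    if packed.size == 0:
        raise ValueError("minhash of an empty k-mer set is undefined")
    return int(hash_kmers(packed, seed).min())


@dataclass(frozen=True)
class RawHit:
    """An alignment hit in local target coordinates (no walk attached yet)."""

    start: int
    end: int
    strand: int
    matches: int
    errors: int
    log_weight: float | None = None


class KmerIndex:
    """Exact k-mer index over a read collection.

    Reads are indexed under every distinct canonical k-mer they contain;
    querying iterates over the target's k-mers, so every read sharing at
    least one k-mer with the target is returned (high recall, low precision).
    """

    def __init__(self, k: int = 13):
        self.k = k
        self._map: dict[str, set] = {}

    def add(self, read_id, seq: str) -> None:
        for km in set(kmers(seq, self.k)):
            self._map.setdefault(canonical(km), set()).add(read_id)

    def candidates(self, target: str, read_length: int | None = None) -> set:
        out: set = set()
        for km in set(kmers(target, self.k)):
            ids = self._map.get(canonical(km))
            if ids:
                out |= ids
        return out


class MinHashIndex:
    """Min-hash index: each read stored once per hash function.

    Querying computes, for every length-``read_length`` substring of the
    target, the min-hash of its canonical k-mer set under each hash function
    and retrieves reads stored under the same value.
    """

    def __init__(self, k: int = 13, num_hashes: int = 3, seed: int = 0, read_length: int = 100):
        self.k = k
        self.num_hashes = num_hashes
        self.read_length = read_length
        rng = np.random.default_rng(seed)
        self.seeds = [int(s) for s in rng.integers(0, 2**63, size=num_hashes, dtype=np.int64)]
        self._maps: list[dict[int, set]] = [dict() for _ in range(num_hashes)]

    def _packed_canonical(self, seq: str) -> np.ndarray:
        fwd = pack_kmers_array(seq, self.k)
        rev = pack_kmers_array(revcomp(seq), self.k)[::-1]
        good = (fwd >> np.uint64(63)) == 0
        return np.minimum(fwd, rev)[good], good

    def add(self, read_id, seq: str) -> None:
        packed, _ = self._packed_canonical(seq)
        if packed.size == 0:
            return
        for fn, seed in enumerate(self.seeds):
            mh = int(hash_kmers(packed, seed).min())
            self._maps[fn].setdefault(mh, set()).add(read_id)

    def candidates(self, target: str, read_length: int | None = None) -> set:
        lr = read_length or self.read_length
        packed, good = self._packed_canonical(target)
        n_all = len(target) - self.k + 1
        if n_all <= 0 or packed.size == 0:
            return set()
        width = max(1, lr - self.k + 1)
        out: set = set()
        for fn, seed in enumerate(self.seeds):
            hv_good = hash_kmers(packed, seed)
            hv = np.full(n_all, np.uint64(0xFFFFFFFFFFFFFFFF), dtype=np.uint64)
            hv[good] = hv_good
            if n_all <= width:
                minima = np.array([hv.min()], dtype=np.uint64)
            else:
                windows = np.lib.stride_tricks.sliding_window_view(hv, width)
                minima = windows.min(axis=1)
            table = self._maps[fn]
            for val in np.unique(minima):
                ids = table.get(int(val))
                if ids:
                    out |= ids
        return out


# ---------------------------------------------------------------------------
# Short-read alignment
# ---------------------------------------------------------------------------


def _parse_cigar(cigar: str) -> tuple[int, int]:
    """(matches, errors) from an extended edlib CIGAR (=, X, I, D)."""
    matches = errors = 0
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + int(ch)
        else:
            if ch == "=":
                matches += num
            else:
                errors += num
            num = 0
    return matches, errors


def _exhaustive_gapless(query: str, target: str, strand: int, max_errors: int) -> list[RawHit]:
    """All gapless placements of ``query`` with Hamming distance <= max_errors."""
    lq, lt = len(query), len(target)
    if lq > lt:
        return []
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, lq)
    mism = (windows != q).sum(axis=1)
    hits = []
    for off in np.nonzero(mism <= max_errors)[0]:
        s = int(mism[off])
        hits.append(RawHit(int(off), int(off) + lq, strand, lq - s, s))
    return hits


def _seed_diagonals(query: str, target_index: dict[str, list[int]], k: int) -> list[int]:
    diags = []
    for qpos in range(len(query) - k + 1):
        km = query[qpos : qpos + k]
        for tpos in target_index.get(km, ()):
            diags.append(tpos - qpos)
    return sorted(set(diags))


def _cluster(values: Sequence[int], gap: int) -> list[tuple[int, int]]:
    """Group sorted values into (min, max) runs separated by more than ``gap``."""
    clusters = []
    lo = hi = None
    for v in values:
        if lo is None:
            lo = hi = v
        elif v - hi <= gap:
            hi = v
        else:
            clusters.append((lo, hi))
            lo = hi = v
    if lo is not None:
        clusters.append((lo, hi))
    return clusters


def build_seed_index(target: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(target) - k + 1):
        index.setdefault(target[i : i + k], []).append(i)
    return index


def align_short_read(
    read: str,
    target: str,
    max_edit_fraction: float = 0.1,
    max_hits: int | None = 10,
    seed_k: int = 13,
    exhaustive: bool = False,
    target_index: dict[str, list[int]] | None = None,
) -> list[RawHit]:
    """Best placements of a short accurate read on both strands of ``target``.

    Seeded mode finds shared ``seed_k``-mer diagonals, then runs infix
    edit-distance alignment (edlib) in a window around each diagonal cluster.
    Exhaustive mode enumerates every gapless placement (used by tests and
    tiny instances).  Hits are deduplicated by (start, strand), ordered by
    (errors, start, strand) and truncated to ``max_hits``.
    """
    if not read or not target:
        return []
    lq = len(read)
    kmax = math.ceil(max_edit_fraction * lq)
    best: dict[tuple[int, int], RawHit] = {}

    for strand in (1, -1):
        query = read if strand == 1 else revcomp(read)
        if exhaustive or lq <= seed_k:
            for h in _exhaustive_gapless(query, target, strand, kmax):
                key = (h.start, h.strand)
                if key not in best or h.errors < best[key].errors:
                    best[key] = h
            continue
        if target_index is None:
            target_index = build_seed_index(target, seed_k)
        diags = _seed_diagonals(query, target_index, seed_k)
        for dlo, dhi in _cluster(diags, max(kmax, 1)):
            ws = max(0, dlo - kmax)
            we = min(len(target), dhi + lq + kmax)
            res = edlib.align(query, target[ws:we], mode="HW", task="path", k=kmax)
            if res["editDistance"] < 0:
                continue
            loc = res["locations"][0]
            matches, errors = _parse_cigar(res["cigar"])
            h = RawHit(ws + loc[0], ws + loc[1] + 1, strand, matches, errors)
            key = (h.start, h.strand)
            if key not in best or h.errors < best[key].errors:
                best[key] = h

    hits = sorted(best.values(), key=lambda h: (h.errors, h.start, -h.strand))
    if max_hits is not None:
        hits = hits[:max_hits]
    return hits


# ---------------------------------------------------------------------------
# Long-read alignment: guide alignments and the banded forward algorithm
# ---------------------------------------------------------------------------


@dataclass
class GuideAlignment:
    """A seed-and-extend alignment used as the center of the forward band.

    ``path`` lists lattice nodes ``(i, j)`` meaning "the first ``i`` read
    bases are aligned to target bases up to ``j``", monotone from
    ``(read_start, target_start)`` to ``(read_end, target_end)``.
    """

    read_start: int
    read_end: int
    target_start: int
    target_end: int
    path: list[tuple[int, int]]
    strand: int = 1
    errors: int = 0
    matches: int = 0

    def target_at(self) -> np.ndarray:
        """Guide target position g(i) for each read position on the path."""
        n = self.read_end - self.read_start + 1
        g = np.full(n, -1, dtype=np.int64)
        for i, j in self.path:
            idx = i - self.read_start
            if g[idx] < 0:
                g[idx] = j
        # fill any read positions skipped by deletions-only runs
        for idx in range(1, n):
            if g[idx] < 0:
                g[idx] = g[idx - 1]
        return g


def guide_from_cigar(cigar: str, read_start: int, target_start: int, strand: int = 1) -> GuideAlignment:
    i, j = read_start, target_start
    path = [(i, j)]
    matches = errors = 0
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + int(ch)
            continue
        for _ in range(num):
            if ch in "=X":
                i += 1
                j += 1
                if ch == "=":
                    matches += 1
                else:
                    errors += 1
            elif ch == "I":  # read base consumed, no target base
                i += 1
                errors += 1
            elif ch == "D":
                j += 1
                errors += 1
            path.append((i, j))
        num = 0
    return GuideAlignment(read_start, i, target_start, j, path, strand, errors, matches)


def banded_forward(
    read: str,
    target: str,
    guide: GuideAlignment,
    band: int = 3,
    error_rate: float = 0.1,
) -> float:
    """Log probability mass of all alignment paths within ``band`` diagonals
    of the guide alignment.

    Each path is weighted ``eps**s * (1-eps)**m`` exactly as a single
    alignment would be; the returned mass is therefore at least the guide
    alignment's own ``log R(s, m)`` and grows monotonically with the band,
    converging to the full forward value.  Band cells outside the target are
    clipped.
    """
    if error_rate <= 0.0:
        error_rate = 1e-12
    log_e = math.log(error_rate)
    log_m = math.log1p(-error_rate)
    query = read if guide.strand == 1 else revcomp(read)
    g = guide.target_at()
    r0, r1 = guide.read_start, guide.read_end
    n_t = len(target)

    prev: dict[int, float] = {}
    lo0 = max(0, g[0] - band)
    hi0 = min(n_t, g[0] + band)
    for j in range(lo0, hi0 + 1):
        prev[j] = 0.0
    for i in range(r0 + 1, r1 + 1):
        gi = g[i - r0]
        lo = max(0, gi - band)
        hi = min(n_t, gi + band)
        cur: dict[int, float] = {}
        base = query[i - 1]
        for j in range(lo, hi + 1):
            acc = -math.inf
            diag = prev.get(j - 1)
            if diag is not None:
                w = log_m if (j >= 1 and target[j - 1] == base) else log_e
                acc = diag + w
            up = prev.get(j)  # read base inserted relative to target
            if up is not None:
                acc = np.logaddexp(acc, up + log_e)
            left = cur.get(j - 1)  # target base deleted
            if left is not None:
                acc = np.logaddexp(acc, left + log_e)
            if acc > -math.inf:
                cur[j] = float(acc)
        prev = cur
        if not prev:
            return -math.inf
    glast = g[r1 - r0]
    finals = [v for j, v in prev.items() if abs(j - glast) <= band]
    if not finals:
        return -math.inf
    return float(np.logaddexp.reduce(np.array(finals)))


def full_forward(read: str, target: str, error_rate: float) -> float:
    """Unbanded forward value: log sum of ``R(s, m)`` over all semi-global
    alignments of the full read anywhere inside the target (test oracle)."""
    if error_rate <= 0.0:
        error_rate = 1e-12
    log_e = math.log(error_rate)
    log_m = math.log1p(-error_rate)
    lq, lt = len(read), len(target)
    prev = np.zeros(lt + 1)  # free start anywhere in target
    for i in range(1, lq + 1):
        cur = np.full(lt + 1, -math.inf)
        base = read[i - 1]
        sub = np.array([log_m if target[j - 1] == base else log_e for j in range(1, lt + 1)])
        cur[1:] = np.logaddexp(prev[:-1] + sub, prev[1:] + log_e)
        cur[0] = prev[0] + log_e
        for j in range(1, lt + 1):
            cur[j] = np.logaddexp(cur[j], cur[j - 1] + log_e)
        prev = cur
    return float(np.logaddexp.reduce(prev))  # free end anywhere in target


def align_long_read(
    read: str,
    target: str,
    error_rate: float = 0.15,
    seed_k: int = 11,
    band: int = 3,
    min_seeds: int = 3,
    max_hits: int = 4,
    target_index: dict[str, list[int]] | None = None,
) -> list[RawHit]:
    """Seed-chain guide alignments of a long noisy read, scored by the
    banded forward algorithm.

    Returns hits whose ``log_weight`` is the banded forward mass around each
    guide; ``errors``/``matches`` come from the guide alignment itself.
    """
    if target_index is None:
        target_index = build_seed_index(target, seed_k)
    lq = len(read)
    kmax = max(1, math.ceil(min(0.45, 3.2 * error_rate) * lq))
    hits: list[RawHit] = []
    for strand in (1, -1):
        query = read if strand == 1 else revcomp(read)
        matches = []
        for qpos in range(0, lq - seed_k + 1):
            km = query[qpos : qpos + seed_k]
            for tpos in target_index.get(km, ()):
                matches.append((tpos - qpos, tpos))
        if len(matches) < min_seeds:
            continue
        diags = sorted(d for d, _ in matches)
        for dlo, dhi in _cluster(diags, max(30, int(0.25 * lq))):
            cluster_t = [t for d, t in matches if dlo <= d <= dhi]
            if len(cluster_t) < min_seeds:
                continue
            pad = kmax + seed_k
            ws = max(0, min(dlo, min(cluster_t)) - pad)
            we = min(len(target), max(dhi + lq, max(cluster_t) + seed_k) + pad)
            res = edlib.align(query, target[ws:we], mode="HW", task="path", k=kmax)
            if res["editDistance"] < 0:
                continue
            loc = res["locations"][0]
            guide = guide_from_cigar(res["cigar"], 0, ws + loc[0], strand)
            # forward mass computed on the full target coordinates
            lw = banded_forward(read, target, guide, band=band, error_rate=error_rate)
            hits.append(
                RawHit(guide.target_start, guide.target_end, strand, guide.matches, guide.errors, lw)
            )
    hits.sort(key=lambda h: (-(h.log_weight if h.log_weight is not None else 0.0), h.start))
    # dedupe near-identical placements
    out: list[RawHit] = []
    for h in hits:
        if any(o.strand == h.strand and abs(o.start - h.start) < lq // 4 for o in out):
            continue
        out.append(h)
    return out[:max_hits]


def long_read_candidates(
    contigs: dict[int, str],
    long_reads: Sequence[str],
    min_contig: int = 100,
    seed_k: int = 11,
    min_seeds: int = 3,
) -> set[tuple[int, int]]:
    """(contig id, read index) pairs with seed-supported overlap.

    Only contigs of at least ``min_contig`` bases seed the filter; a pair is
    reported when read and contig share ``min_seeds`` k-mers on a consistent
    diagonal band (either strand), the desk-scale analogue of using coarse
    contig-to-read alignments as a prefilter.
    """
    read_index: dict[str, list[tuple[int, int]]] = {}
    for ridx, read in enumerate(long_reads):
        for pos in range(len(read) - seed_k + 1):
            read_index.setdefault(read[pos : pos + seed_k], []).append((ridx, pos))
    pairs: set[tuple[int, int]] = set()
    for cid, seq in sorted(contigs.items()):
        if len(seq) < min_contig:
            continue
        for strand_seq in (seq, revcomp(seq)):
            per_read: dict[int, list[int]] = {}
            for cpos in range(len(strand_seq) - seed_k + 1):
                for ridx, rpos in read_index.get(strand_seq[cpos : cpos + seed_k], ()):
                    per_read.setdefault(ridx, []).append(rpos - cpos)
            for ridx, diags in per_read.items():
                if (cid, ridx) in pairs or len(diags) < min_seeds:
                    continue
                diags.sort()
                span = max(30, int(0.25 * len(long_reads[ridx])))
                for lo, hi in _cluster(diags, span):
                    count = sum(1 for d in diags if lo <= d <= hi)
                    if count >= min_seeds:
                        pairs.add((cid, ridx))
                        break
    return pairs
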