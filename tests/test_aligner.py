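import math

import numpy as np
import pytest

from lapasm.aligner import (
    KmerIndex,
    MinHashIndex,
    align_long_read,
    align_short_read,
    banded_forward,
    full_forward,
    guide_from_cigar,
    hash_kmers,
    long_read_candidates,
    minhash,
)
from lapasm.sequtils import (
    canonical,
    kmer_set,
    pack_kmer,
    pack_kmers_array,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_seq(rng, n):
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate(rng, seq, n_subs):
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        out[pos] = "ACGT"[(("ACGT".index(out[pos])) + 1 + int(rng.integers(3))) % 4]
    return "".join(out)


class TestSequtils:
    def test_revcomp(self):
        assert revcomp("ACGTN") == "NACGT"
        assert revcomp(revcomp("GATTACA")) == "GATTACA"

    def test_canonical_is_min(self):
        assert canonical("TTTT") == "AAAA"
        assert canonical("ACGT") == "ACGT"  # palindrome

    def test_pack_kmers_array_matches_scalar(self):
        rng = np.random.default_rng(0)
        seq = _rand_seq(rng, 40)
        arr = pack_kmers_array(seq, 13)
        for i in range(len(seq) - 12):
            assert int(arr[i]) == pack_kmer(seq[i : i + 13])

    def test_pack_flags_n_windows(self):
        arr = pack_kmers_array("ACGTNACGTACGTA", 5)
        sentinel = np.uint64(1) << np.uint64(63)
        assert (arr[:5] == sentinel).all()  # windows touching the N
        assert (arr[5:] != sentinel).all()


class TestMinHash:
    def test_deterministic_and_seed_dependent(self):
        kms = kmer_set("ACGTACGTACGTACGTACGT", 7)
        assert minhash(kms, 5) == minhash(kms, 5)
        vals = {minhash(kms, s) for s in range(20)}
        assert len(vals) > 10

    def test_identical_sets_always_collide(self):
        a = kmer_set("ACGTACGTACGTACGTACGT", 7)
        assert all(minhash(a, s) == minhash(set(a), s) for s in range(50))

    def test_hash_kmers_avalanche(self):
        packed = np.arange(16, dtype=np.uint64)
        h = hash_kmers(packed, 1)
        assert len(set(h.tolist())) == 16  # injective on small inputs


class TestShortRead:
    def test_exact_read_found_both_strands(self):
        rng = np.random.default_rng(1)
        target = _rand_seq(rng, 500)
        read = target[200:250]
        hits = align_short_read(read, target)
        assert hits and hits[0].start == 200 and hits[0].strand == 1 and hits[0].errors == 0
        hits_rc = align_short_read(revcomp(read), target)
        assert hits_rc and hits_rc[0].start == 200 and hits_rc[0].strand == -1

    def test_seeded_equals_exhaustive_on_substitutions(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            target = _rand_seq(rng, 800)
            pos = int(rng.integers(0, 750))
            read = _mutate(rng, target[pos : pos + 50], int(rng.integers(0, 3)))
            if rng.random() < 0.5:
                read = revcomp(read)
            seeded = align_short_read(read, target, max_hits=None)
            exhaust = align_short_read(read, target, exhaustive=True, max_hits=None)
            ex_best = {(h.start, h.strand): h.errors for h in exhaust}
            # every exhaustive placement is found with no worse an error count
            se = {(h.start, h.strand): h.errors for h in seeded}
            for key, errs in ex_best.items():
                assert key in se and se[key] <= errs

    def test_max_hits_and_ordering(self):
        rng = np.random.default_rng(11)
        read = _rand_seq(rng, 40)
        filler = [_rand_seq(rng, 60) for _ in range(7)]
        target = "".join(f + read for f in filler)
        hits = align_short_read(read, target, max_hits=5)
        assert len(hits) == 5
        assert [h.errors for h in hits] == sorted(h.errors for h in hits)
        all_hits = align_short_read(read, target, max_hits=None)
        assert sum(1 for h in all_hits if h.errors == 0 and h.strand == 1) == 7


class TestKmerIndexes:
    def test_kmer_index_full_recall_for_exact_reads(self):
        rng = np.random.default_rng(3)
        target = _rand_seq(rng, 1000)
        idx = KmerIndex(k=13)
        for i in range(0, 900, 50):
            idx.add(i, target[i : i + 100])
        cands = idx.candidates(target)
        assert cands == set(range(0, 900, 50))

    def test_minhash_index_recall_for_exact_reads(self):
        rng = np.random.default_rng(4)
        target = _rand_seq(rng, 1000)
        idx = MinHashIndex(k=13, num_hashes=3, seed=7, read_length=100)
        for i in range(0, 900, 50):
            idx.add(i, target[i : i + 100])
        cands = idx.candidates(target, 100)
        # an exact substring shares its whole k-mer set with some window
        assert set(range(0, 900, 50)) <= cands


class TestBandedForward:
    def _setup(self, rng, n_target=300, n_read=80, pos=100):
        target = _rand_seq(rng, n_target)
        read = target[pos : pos + n_read]
        assert len(read) == n_read
        guide = guide_from_cigar(f"{n_read}=", 0, pos, 1)
        return read, target, guide

    def test_band_contains_guide_weight(self):
        rng = np.random.default_rng(5)
        read, target, guide = self._setup(rng)
        lw0 = banded_forward(read, target, guide, band=0, error_rate=0.1)
        single = guide.matches * math.log(0.9)  # exact guide: no errors
        assert lw0 >= single - 1e-9

    def test_monotone_in_band_and_bounded_by_full(self):
        rng = np.random.default_rng(6)
        read, target, guide = self._setup(rng)
        prev = -math.inf
        full = full_forward(read, target, 0.1)
        for band in (0, 1, 3, 8):
            lw = banded_forward(read, target, guide, band=band, error_rate=0.1)
            assert lw >= prev - 1e-12
            assert lw <= full + 1e-9
            prev = lw

    def test_huge_band_equals_full_forward(self):
        rng = np.random.default_rng(7)
        read, target, guide = self._setup(rng, n_target=120, n_read=40, pos=40)
        lw = banded_forward(read, target, guide, band=len(target), error_rate=0.08)
        assert lw == pytest.approx(full_forward(read, target, 0.08), abs=1e-9)


class TestLongRead:
    def test_planted_noisy_read_found(self):
        from lapasm.simulate import _apply_errors

        rng = np.random.default_rng(8)
        target = _rand_seq(rng, 3000)
        frag = target[1000:2200]
        read = _apply_errors(rng, frag, 0.1, 1 / 3)
        hits = align_long_read(read, target, error_rate=0.1)
        assert hits
        best = hits[0]
        assert best.strand == 1
        assert abs(best.start - 1000) < 50
        assert best.log_weight is not None and best.log_weight > -0.45 * len(read)

    def test_reverse_strand(self):
        from lapasm.simulate import _apply_errors

        rng = np.random.default_rng(9)
        target = _rand_seq(rng, 2000)
        read = _apply_errors(rng, revcomp(target[500:1400]), 0.08, 1 / 3)
        hits = align_long_read(read, target, error_rate=0.08)
        assert hits and hits[0].strand == -1 and abs(hits[0].start - 500) < 50

    def test_candidate_filter_finds_true_pairs(self):
        from lapasm.simulate import _apply_errors

        rng = np.random.default_rng(10)
        contigs = {0: _rand_seq(rng, 1500), 1: _rand_seq(rng, 1500)}
        reads = [
            _apply_errors(rng, contigs[0][200:1000], 0.1, 1 / 3),
            _apply_errors(rng, revcomp(contigs[1][300:1200]), 0.1, 1 / 3),
        ]
        pairs = long_read_candidates(contigs, reads)
        assert (0, 0) in pairs and (1, 1) in pairs
        assert (0, 1) not in pairs and (1, 0) not in pairs
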