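import numpy as np
import pytest

from lapasm.aligner import align_short_read
from lapasm.model import pair_distance, AlignmentHit
from lapasm.simulate import (
    GenomeSpec,
    LibrarySpec,
    RepeatSpec,
    invert_segment,
    random_genome,
    simulate_reads,
    spurious_join,
    swap_repeat_copies,
)
from lapasm.sequtils import revcomp


class TestGenome:
    def test_deterministic(self):
        spec = GenomeSpec(length=5000, repeats=[RepeatSpec(500, 2)], seed=5)
        g1, a1 = random_genome(spec)
        g2, a2 = random_genome(spec)
        assert g1 == g2 and a1 == a2

    def test_planted_repeat_is_exact_copy(self):
        genome, ann = random_genome(
            GenomeSpec(length=8000, repeats=[RepeatSpec(600, 2, divergence=0.0)], seed=6)
        )
        (s1, e1, _), (s2, e2, _) = ann
        assert genome[s1:e1] == genome[s2:e2]

    def test_divergence_approximate(self):
        genome, ann = random_genome(
            GenomeSpec(length=20000, repeats=[RepeatSpec(2000, 2, divergence=0.05)], seed=7)
        )
        (s1, e1, _), (s2, e2, _) = ann
        diff = sum(a != b for a, b in zip(genome[s1:e1], genome[s2:e2]))
        assert 0.02 < diff / 2000 < 0.09

    def test_base_composition(self):
        genome, _ = random_genome(GenomeSpec(length=40000, seed=8))
        freqs = {b: genome.count(b) / len(genome) for b in "ACGT"}
        assert all(abs(f - 0.25) < 0.02 for f in freqs.values())


class TestLibraries:
    def test_paired_reads_map_properly(self):
        genome, _ = random_genome(GenomeSpec(length=4000, seed=9))
        rs = simulate_reads(
            genome,
            LibrarySpec(coverage=2, read_length=80, error_rate=0.0, paired=True,
                        insert_mean=400, insert_sd=30, seed=10),
        )
        assert rs.paired and len(rs.mates) == len(rs)
        inserts = []
        for r, m in zip(rs.reads[:40], rs.mates[:40]):
            h1 = align_short_read(r, genome)[0]
            h2 = align_short_read(m, genome)[0]
            a = AlignmentHit(0, h1.start, h1.end, h1.strand, h1.matches, h1.errors)
            b = AlignmentHit(0, h2.start, h2.end, h2.strand, h2.matches, h2.errors)
            d = pair_distance(a, b, "fr")
            assert d is not None, "simulated pair must be properly oriented"
            inserts.append(d)
        assert 350 < np.mean(inserts) < 450

    def test_error_rate_realised(self):
        genome, _ = random_genome(GenomeSpec(length=6000, seed=11))
        rs = simulate_reads(
            genome, LibrarySpec(coverage=5, read_length=100, error_rate=0.02, seed=12)
        )
        mismatches = bases = 0
        for read in rs.reads[:200]:
            hits = align_short_read(read, genome, max_edit_fraction=0.2)
            if hits:
                mismatches += hits[0].errors
                bases += len(read)
        assert bases > 0
        assert 0.01 < mismatches / bases < 0.03

    def test_long_reads_lognormal_and_coverage(self):
        genome, _ = random_genome(GenomeSpec(length=10000, seed=13))
        rs = simulate_reads(
            genome,
            LibrarySpec(technology_class="long-noisy", coverage=8, error_rate=0.1,
                        long_read_median=1500, seed=14),
        )
        total = sum(len(r) for r in rs.reads)
        assert total >= 8 * len(genome)
        med = np.median([len(r) for r in rs.reads])
        assert 1000 < med < 2300
        assert rs.params.noalign_scale < -0.2  # long-noisy floor slope

    def test_determinism(self):
        genome, _ = random_genome(GenomeSpec(length=3000, seed=15))
        spec = LibrarySpec(coverage=3, read_length=50, error_rate=0.01, seed=16)
        r1 = simulate_reads(genome, spec)
        r2 = simulate_reads(genome, spec)
        assert r1.reads == r2.reads


class TestMisassemblies:
    def test_inversion_preserves_length_and_content(self):
        genome, _ = random_genome(GenomeSpec(length=2000, seed=17))
        bad = invert_segment(genome, 500, 900)
        assert len(bad) == len(genome)
        assert bad[500:900] == revcomp(genome[500:900])
        assert bad[:500] == genome[:500] and bad[900:] == genome[900:]

    def test_swap_copies_with_divergence_changes_sequence(self):
        genome, ann = random_genome(
            GenomeSpec(length=9000, repeats=[RepeatSpec(700, 2, divergence=0.05)], seed=18)
        )
        swapped = swap_repeat_copies(genome, ann)
        assert len(swapped) == len(genome)
        assert swapped != genome
        assert sorted(swapped) == sorted(genome)  # content-preserving

    def test_swap_exact_copies_is_noop(self):
        genome, ann = random_genome(
            GenomeSpec(length=9000, repeats=[RepeatSpec(700, 2, divergence=0.0)], seed=19)
        )
        assert swap_repeat_copies(genome, ann) == genome

    def test_spurious_join_is_rotation(self):
        genome, _ = random_genome(GenomeSpec(length=2000, seed=20))
        bad = spurious_join(genome, 700)
        assert bad == genome[700:] + genome[:700]
        assert spurious_join(bad, len(genome) - 700) == genome
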