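import numpy as np
import pytest

from lapasm.graph import (
    Assembly,
    AssemblyGraph,
    GraphBuildError,
    Walk,
    build_conservative_graph,
    enumerate_short_loops,
    graph_from_contigs,
    initial_assembly,
    loops_by_node,
    map_external_assembly,
    walk_layout,
    walk_sequence,
)
from lapasm.sequtils import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_seq(rng, n):
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


@pytest.fixture(scope="module")
def linear_graph():
    """Graph built from perfect reads of a repeat-free 3 kb genome."""
    rng = np.random.default_rng(20)
    genome = _rand_seq(rng, 3000)
    reads = [genome[i : i + 100] for i in range(0, 2901, 10)]
    graph = build_conservative_graph(reads, kmer_size=21, min_count=1)
    return genome, graph


class TestConstruction:
    def test_perfect_coverage_gives_single_contig(self, linear_graph):
        genome, graph = linear_graph
        assert len(graph.contigs) == 1
        seq = graph.contigs[0]
        assert seq in (genome, revcomp(genome))

    def test_repeat_collapses_into_branching_node(self):
        rng = np.random.default_rng(21)
        u1, r, u2, u3 = (_rand_seq(rng, n) for n in (600, 400, 600, 600))
        genome = u1 + r + u2 + r + u3
        reads = [genome[i : i + 80] for i in range(0, len(genome) - 80 + 1, 5)]
        graph = build_conservative_graph(reads, kmer_size=21, min_count=1)
        lens = sorted(len(s) for s in graph.contigs.values())
        # unique stretches plus one copy of the repeat (k-1 branch overlaps)
        assert len(graph.contigs) == 4
        assert len(genome) - 400 <= sum(lens) <= len(genome) - 400 + 4 * 20

    def test_low_coverage_raises(self):
        with pytest.raises(GraphBuildError):
            build_conservative_graph(["ACGTACGTACGTACGTACGTACGTA"], kmer_size=21, min_count=5)

    def test_strand_symmetry(self, linear_graph):
        _, graph = linear_graph
        for u, targets in graph.out.items():
            for v in targets:
                assert graph.has_edge(graph.rc(v), graph.rc(u))


@pytest.fixture(scope="module")
def repeat_graph():
    rng = np.random.default_rng(22)
    u1, r, u2, u3 = (_rand_seq(rng, n) for n in (600, 400, 600, 600))
    genome = u1 + r + u2 + r + u3
    reads = [genome[i : i + 80] for i in range(0, len(genome) - 80 + 1, 5)]
    graph = build_conservative_graph(reads, kmer_size=21, min_count=1)
    return genome, graph


class TestWalks:
    def test_mapped_walk_reproduces_genome(self, repeat_graph):
        genome, graph = repeat_graph
        asm = map_external_assembly([genome], graph)
        assert len(asm.walks) == 1
        walk = next(iter(asm.walks.values()))
        assert walk_sequence(walk, graph) == genome
        # the repeat contig is traversed twice
        from collections import Counter

        usage = Counter(walk.contig_ids())
        assert max(usage.values()) == 2

    def test_layout_spans_are_contiguous(self, repeat_graph):
        genome, graph = repeat_graph
        walk = next(iter(map_external_assembly([genome], graph).walks.values()))
        layout = walk_layout(walk, graph)
        pos = 0
        for _e, s, t in layout:
            assert s == pos and t > s
            pos = t
        assert pos == len(genome)

    def test_reverse_roundtrip(self, repeat_graph):
        genome, graph = repeat_graph
        walk = next(iter(map_external_assembly([genome], graph).walks.values()))
        assert walk_sequence(walk.reverse(), graph) == revcomp(genome)
        assert walk.reverse().reverse().elements == walk.elements

    def test_gap_and_seq_elements(self, repeat_graph):
        _, graph = repeat_graph
        cid = max(graph.contigs, key=lambda c: len(graph.contigs[c]))
        walk = Walk([("node", cid, 1), ("gap", 5), ("seq", "ACGTACGT")])
        assert walk.is_valid(graph)
        seq = walk_sequence(walk, graph)
        assert seq == graph.contigs[cid] + "N" * 5 + "ACGTACGT"

    def test_invalid_walks_rejected(self, repeat_graph):
        _, graph = repeat_graph
        cids = sorted(graph.contigs)
        assert not Walk([]).is_valid(graph)
        assert not Walk([("gap", 0)]).is_valid(graph)
        assert not Walk([("node", 9999, 1)]).is_valid(graph)
        # two nodes with no connecting edge
        w = Walk([("node", cids[0], 1), ("node", cids[0], 1)])
        if not graph.has_edge((cids[0], 1), (cids[0], 1)):
            assert not w.is_valid(graph)


class TestAssembly:
    def test_apply_and_copy_independent(self, linear_graph):
        _, graph = linear_graph
        asm = initial_assembly(graph, long_threshold=500)
        asm2 = asm.copy()
        wid = sorted(asm2.walks)[0]
        new = asm2.apply([wid], [Walk([("node", 0, -1)])])
        assert wid in asm.walks and wid not in asm2.walks
        assert all(n >= asm.next_id for n in new)

    def test_initial_assembly_requires_long_contig(self, linear_graph):
        _, graph = linear_graph
        with pytest.raises(GraphBuildError):
            initial_assembly(graph, long_threshold=10**9)


class TestLoops:
    def test_self_loop_detected(self):
        # a genome with a perfect tandem repeat gives a contig looping on itself
        rng = np.random.default_rng(23)
        u1, r, u2 = _rand_seq(rng, 300), _rand_seq(rng, 60), _rand_seq(rng, 300)
        genome = u1 + r * 3 + u2
        reads = [genome[i : i + 80] for i in range(0, len(genome) - 80 + 1, 4)]
        graph = build_conservative_graph(reads, kmer_size=21, min_count=1)
        loops = enumerate_short_loops(graph)
        assert loops, "tandem repeat should create a short cycle"
        index = loops_by_node(loops)
        assert all(isinstance(k, tuple) for k in index)


class TestExternalMapping:
    def test_gap_emitted_for_unmappable_span(self, repeat_graph):
        genome, graph = repeat_graph
        rng = np.random.default_rng(24)
        foreign = _rand_seq(rng, 300)
        # replace the span between the first flank and the middle stretch
        chimera = genome[:650] + foreign + genome[950:]
        asm = map_external_assembly([chimera], graph)
        walk = next(iter(asm.walks.values()))
        kinds = [e[0] for e in walk.elements]
        assert "gap" in kinds, "foreign sequence should be bridged by an N-gap"

    def test_graph_from_contigs_roundtrip(self):
        rng = np.random.default_rng(25)
        genome = _rand_seq(rng, 2000)
        graph = graph_from_contigs([genome], kmer_size=21)
        assert len(graph.contigs) == 1
        assert graph.contigs[0] in (genome, revcomp(genome))

    def test_gfa_output(self, linear_graph):
        _, graph = linear_graph
        gfa = graph.to_gfa()
        assert gfa.startswith("H\t")
        assert sum(1 for line in gfa.splitlines() if line.startswith("S\t")) == len(graph.contigs)
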