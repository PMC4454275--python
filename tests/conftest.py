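import pytest

from lapasm import (
    GenomeSpec,
    LibrarySpec,
    RepeatSpec,
    build_conservative_graph,
    initial_assembly,
    random_genome,
    simulate_reads,
)
from lapasm.evaluation import Evaluator


@pytest.fixture(scope="session")
def small_world():
    """A 10 kb repeat-free genome with one paired library and its graph."""
    genome, _ = random_genome(GenomeSpec(length=10000, repeats=[], seed=101))
    rs = simulate_reads(
        genome,
        LibrarySpec(
            coverage=30,
            read_length=100,
            error_rate=0.005,
            paired=True,
            insert_mean=500,
            insert_sd=50,
            seed=102,
            name="frag",
        ),
    )
    graph = build_conservative_graph(rs.reads + rs.mates, kmer_size=21)
    return {"genome": genome, "readset": rs, "graph": graph}


@pytest.fixture(scope="session")
def small_eval(small_world):
    graph, rs = small_world["graph"], small_world["readset"]
    evaluator = Evaluator(graph, [rs], seed=0)
    assembly = initial_assembly(graph)
    return {"evaluator": evaluator, "assembly": assembly, **small_world}


@pytest.fixture(scope="session")
def fixture20k():
    """The 20 kb acceptance fixture: one mate-spanned exact 1 kb two-copy
    repeat, 40x paired 100 bp reads with a 2 kb insert."""
    spec = GenomeSpec(
        length=20000, repeats=[RepeatSpec(unit_length=1000, copies=2)], seed=42
    )
    genome, annotation = random_genome(spec)
    rs = simulate_reads(
        genome,
        LibrarySpec(
            coverage=40,
            read_length=100,
            error_rate=0.005,
            paired=True,
            insert_mean=2000,
            insert_sd=200,
            seed=43,
            name="frag",
        ),
    )
    graph = build_conservative_graph(rs.reads + rs.mates, kmer_size=21)
    return {"genome": genome, "annotation": annotation, "readset": rs, "graph": graph}
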