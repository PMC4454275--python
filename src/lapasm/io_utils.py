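"""File formats: FASTA/FASTQ reads, assemblies, GFA graphs, reports.

Sequence I/O goes through Biopython.  Assemblies round-trip through FASTA
(scaffold gaps become runs of N) together with a JSON sidecar that preserves
the walk structure (contig ids, strands and gap lengths) exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .graph import Assembly, AssemblyGraph, Walk, walk_sequence

__all__ = [
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "write_paired_fastq",
    "assembly_records",
    "write_assembly",
    "write_walks_json",
    "read_walks_json",
    "write_gfa",
    "write_bed",
    "write_json",
]


def read_sequences(path: str | Path) -> tuple[list[str], list[str]]:
    """Read FASTA or FASTQ (by extension); returns (names, sequences)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), fmt):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return names, seqs


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def _fastq_records(names: Sequence[str], seqs: Sequence[str]):
    for name, seq in zip(names, seqs):
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        yield rec


def write_fastq(path: str | Path, names: Sequence[str], seqs: Sequence[str]) -> None:
    SeqIO.write(_fastq_records(names, seqs), str(path), "fastq")


def write_paired_fastq(
    prefix: str | Path, names: Sequence[str], reads: Sequence[str], mates: Sequence[str]
) -> tuple[Path, Path]:
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_1.fastq")
    p2 = prefix.with_name(prefix.name + "_2.fastq")
    write_fastq(p1, [n + "/1" for n in names], reads)
    write_fastq(p2, [n + "/2" for n in names], mates)
    return p1, p2


def assembly_records(
    assembly: Assembly, graph: AssemblyGraph, prefix: str = "walk"
) -> list[tuple[str, str]]:
    return [
        (f"{prefix}_{wid}", walk_sequence(w, graph))
        for wid, w in sorted(assembly.walks.items())
    ]


def write_assembly(
    path: str | Path, assembly: Assembly, graph: AssemblyGraph, prefix: str = "walk"
) -> None:
    write_fasta(path, assembly_records(assembly, graph, prefix))


def write_walks_json(path: str | Path, assembly: Assembly) -> None:
    data = {
        str(wid): [list(e) for e in w.elements]
        for wid, w in sorted(assembly.walks.items())
    }
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def read_walks_json(path: str | Path) -> Assembly:
    data = json.loads(Path(path).read_text())
    asm = Assembly()
    for wid in sorted(data, key=int):
        asm.add(Walk([tuple(e) for e in data[wid]]))
    return asm


def write_gfa(path: str | Path, graph: AssemblyGraph) -> None:
    Path(path).write_text(graph.to_gfa())


def write_bed(
    path: str | Path, intervals: Iterable[tuple[str, int, int, str]]
) -> None:
    """(chrom, start, end, name) rows in BED format."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_json(path: str | Path, data: Mapping) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
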