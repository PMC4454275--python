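"""Synthetic genomes and sequencing libraries.

Generates the test conditions every stage of the pipeline runs under: random
genomes with planted repeat families (the features that make assembly hard),
paired short reads with normally distributed insert sizes and per-base
substitution/indel errors, and long reads with log-normal lengths and a high
error rate.  Also provides constructors for controlled misassemblies
(inversion, repeat-copy swap, spurious join) used to probe whether the
likelihood prefers the true sequence.

Identical seeds reproduce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelParams, ReadSet, default_noalign_scale
from .sequtils import BASES, revcomp

__all__ = [
    "RepeatSpec",
    "GenomeSpec",
    "LibrarySpec",
    "random_genome",
    "simulate_reads",
    "invert_segment",
    "swap_repeat_copies",
    "spurious_join",
]

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class RepeatSpec:
    """One planted repeat family: ``copies`` copies of a ``unit_length`` unit
    at the given divergence (per-base substitution rate between copies)."""

    unit_length: int
    copies: int = 2
    divergence: float = 0.0
    placements: list[int] | None = None  # start positions; evenly spaced if None

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")
        if self.copies < 1 or self.unit_length < 1:
            raise ValueError("invalid repeat spec")


@dataclass
class GenomeSpec:
    length: int
    repeats: list[RepeatSpec] = field(default_factory=list)
    seed: int = 0


@dataclass
class LibrarySpec:
    """Parameters of one simulated sequencing library.

    ``technology_class`` is ``"short-accurate"`` (fixed-length, optionally
    paired) or ``"long-noisy"`` (single-end, log-normal lengths, errors split
    1/3 substitutions and 2/3 indels).
    """

    technology_class: str = "short-accurate"
    coverage: float = 40.0
    read_length: int = 100
    error_rate: float = 0.01
    paired: bool = False
    insert_mean: float | None = None
    insert_sd: float | None = None
    orientation: str = "fr"
    weight: float = 1.0
    long_read_median: int = 2000
    long_read_sigma: float = 0.3
    substitution_fraction: float | None = None  # default: 1.0 short, 1/3 long
    seed: int = 0
    name: str = "lib"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASE_ARR[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate_subs(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASE_ARR[_BASE_ARR != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def random_genome(spec: GenomeSpec) -> tuple[str, list[tuple[int, int, int]]]:
    """Uniform-random genome with planted repeats.

    Returns ``(sequence, annotation)`` where the annotation lists
    ``(start, end, family)`` intervals of the planted repeat copies.
    """
    rng = np.random.default_rng(spec.seed)
    seq = list(_random_seq(rng, spec.length))
    annotation: list[tuple[int, int, int]] = []
    for fam, rep in enumerate(spec.repeats):
        placements = rep.placements
        if placements is None:
            margin = max(200, spec.length // 20)
            usable = spec.length - 2 * margin - rep.unit_length
            if usable < 0 or rep.copies < 1:
                raise ValueError("repeat does not fit in the genome")
            step = usable // max(1, rep.copies - 1) if rep.copies > 1 else 0
            placements = [margin + i * step for i in range(rep.copies)]
        unit = "".join(seq[placements[0] : placements[0] + rep.unit_length])
        if len(unit) != rep.unit_length:
            raise ValueError("repeat placement out of bounds")
        for start in placements:
            if start < 0 or start + rep.unit_length > spec.length:
                raise ValueError("repeat placement out of bounds")
            copy = _mutate_subs(rng, unit, rep.divergence) if start != placements[0] else unit
            seq[start : start + rep.unit_length] = list(copy)
            annotation.append((start, start + rep.unit_length, fam))
    return "".join(seq), annotation


def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float, sub_fraction: float
) -> str:
    """Per-base errors: substitutions with probability ``error_rate *
    sub_fraction``, insertions/deletions sharing the remainder equally."""
    if error_rate <= 0:
        return seq
    out: list[str] = []
    p_sub = error_rate * sub_fraction
    p_ins = error_rate * (1.0 - sub_fraction) / 2.0
    p_del = p_ins
    for ch in seq:
        r = rng.random()
        if r < p_sub:
            out.append(str(rng.choice([b for b in BASES if b != ch])))
        elif r < p_sub + p_del:
            continue
        elif r < p_sub + p_del + p_ins:
            out.append(str(rng.choice(list(BASES))))
            out.append(ch)
        else:
            out.append(ch)
    if not out:
        out.append(seq[0])
    return "".join(out)


def simulate_reads(genome: str, spec: LibrarySpec) -> ReadSet:
    """Draw a read set from ``genome`` under the library's model.

    Reads are sampled uniformly from both strands; paired reads come from
    inserts of length ``Normal(insert_mean, insert_sd)`` in the requested
    orientation; long-read lengths are log-normal around
    ``long_read_median``.
    """
    rng = np.random.default_rng(spec.seed)
    n_g = len(genome)
    sub_frac = spec.substitution_fraction
    if sub_frac is None:
        sub_frac = 1.0 if spec.technology_class == "short-accurate" else 1.0 / 3.0

    reads: list[str] = []
    mates: list[str] | None = [] if spec.paired else None
    names: list[str] = []

    if spec.paired:
        if spec.insert_mean is None or spec.insert_sd is None:
            raise ValueError("paired library needs insert_mean and insert_sd")
        if n_g <= spec.insert_mean + 6 * spec.insert_sd:
            raise ValueError("genome too short for the requested insert size")
        n_pairs = int(round(spec.coverage * n_g / (2 * spec.read_length)))
        made = 0
        while made < n_pairs:
            insert = int(round(rng.normal(spec.insert_mean, spec.insert_sd)))
            if insert < 2 * spec.read_length or insert > n_g:
                continue
            start = int(rng.integers(0, n_g - insert + 1))
            fragment = genome[start : start + insert]
            if rng.random() < 0.5:
                fragment = revcomp(fragment)
            left = fragment[: spec.read_length]
            right = revcomp(fragment[-spec.read_length :])
            if spec.orientation == "rf":
                left, right = revcomp(left), revcomp(right)
            reads.append(_apply_errors(rng, left, spec.error_rate, sub_frac))
            mates.append(_apply_errors(rng, right, spec.error_rate, sub_frac))
            names.append(f"{spec.name}_{made}")
            made += 1
    elif spec.technology_class == "long-noisy":
        total_target = spec.coverage * n_g
        total = 0
        i = 0
        mu_log = np.log(spec.long_read_median)
        while total < total_target:
            length = int(round(np.exp(rng.normal(mu_log, spec.long_read_sigma))))
            length = max(200, min(length, n_g))
            start = int(rng.integers(0, n_g - length + 1))
            frag = genome[start : start + length]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            reads.append(_apply_errors(rng, frag, spec.error_rate, sub_frac))
            names.append(f"{spec.name}_{i}")
            total += length
            i += 1
    else:
        n_reads = int(round(spec.coverage * n_g / spec.read_length))
        for i in range(n_reads):
            start = int(rng.integers(0, n_g - spec.read_length + 1))
            frag = genome[start : start + spec.read_length]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            reads.append(_apply_errors(rng, frag, spec.error_rate, sub_frac))
            names.append(f"{spec.name}_{i}")

    lr = spec.read_length if spec.technology_class == "short-accurate" else spec.long_read_median
    params = ModelParams(
        error_rate=spec.error_rate,
        insert_mean=spec.insert_mean if spec.paired else None,
        insert_sd=spec.insert_sd if spec.paired else None,
        weight=spec.weight,
        orientation=spec.orientation,
        # half the read length: a window as large as the read would leave
        # single-read placements unable to connect any base at all
        conn_window=max(1, lr // 2),
        noalign_scale=default_noalign_scale(spec.error_rate, spec.technology_class),
    )
    return ReadSet(
        reads=reads,
        mates=mates,
        paired=spec.paired,
        params=params,
        technology_class=spec.technology_class,
        name=spec.name,
        names=names,
    )


# ---------------------------------------------------------------------------
# Controlled misassemblies
# ---------------------------------------------------------------------------


def invert_segment(genome: str, start: int, end: int) -> str:
    """Reverse-complement an internal segment (an inversion misassembly)."""
    return genome[:start] + revcomp(genome[start:end]) + genome[end:]


def swap_repeat_copies(
    genome: str, annotation: list[tuple[int, int, int]], family: int = 0
) -> str:
    """Exchange the sequence of the first two copies of a repeat family.

    A no-op for exact repeats; with diverged copies it mimics assigning the
    wrong copy to each locus.
    """
    copies = [(s, e) for s, e, fam in annotation if fam == family]
    if len(copies) < 2:
        raise ValueError("need at least two copies to swap")
    (s1, e1), (s2, e2) = copies[0], copies[1]
    a, b = genome[s1:e1], genome[s2:e2]
    return genome[:s1] + b + genome[e1:s2] + a + genome[e2:]


def spurious_join(genome: str, breakpoint: int | None = None) -> str:
    """Rotate the genome at an arbitrary breakpoint: the two halves are
    rejoined in the wrong order, creating one junction unsupported by reads."""
    if breakpoint is None:
        breakpoint = len(genome) // 2
    return genome[breakpoint:] + genome[:breakpoint]
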