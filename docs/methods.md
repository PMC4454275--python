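# Methods

This document describes the probabilistic model, the search procedure, the
default parameters, and the numerical choices made in `lapasm`, together
with the limitations we know about.

## 1. The likelihood model

An assembly is scored by how well it explains the reads that were used to
build it, not by intrinsic contiguity metrics.  For a read set *R* and an
assembly *A* (a set of scaffold sequences), the per-read average
log-probability is

```
LAP(A | R) = (1/|R|) * sum_r log Pr(r | A)
```

`Pr(r | A)` is a sum over all places the read (or read pair) could have
been sampled from:

- **Single reads.**  Each alignment of read *r* with *s* mismatches and
  *m* matching bases contributes `eps^s * (1-eps)^m / (2 * L_A)`, where
  `eps` is the per-base error rate of the library and `L_A` the total
  assembly length.  The factor `2 * L_A` is the uniform prior over start
  positions on both strands.
- **Read pairs.**  A pair contributes, for every combination of an
  alignment of each mate on the same scaffold with correct relative
  orientation, the product of the two alignment terms times a Normal
  density `N(d; insert_mean, insert_sd)` of the observed distance *d*
  (outer distance, 5' end to 5' end), again divided by `2 * L_A`.
- **No-alignment floor.**  A read with no alignment (or a pair with no
  compatible placement) would make the log undefined, so every read
  probability is floored at `exp(c + k * len)` with `c = -15` and
  `k = -0.2` for short accurate reads.  For long noisy reads, `k` is
  `min(-0.2, 1.5 * (eps*ln(eps) + (1-eps)*ln(1-eps)))`, i.e. 1.5 times the
  expected per-base log-likelihood of a *genuine* placement, so genuine
  placements always clear the floor.

Multiple libraries are combined as a weighted sum.

### Connectivity penalty

The likelihood alone barely distinguishes a correct join from two separate
scaffolds, so each library also contributes a *connectivity* term.  A base
*j* of a scaffold counts as **connected** for a library when some
placement interval `[s, e)` of that library (a read span, or the outer
span of a properly oriented pair) satisfies `s <= j - conn_window` and
`j < e` — i.e. the evidence reaches *j* from at least `conn_window` bases
upstream.  The first and last `conn_window` bases of each scaffold are
exempt (they can never, or only with probability zero, be connected).
Bases inside `N`-gaps are **not** exempt: a scaffold gap escapes the
penalty only when properly oriented pairs genuinely span it.  The combined
objective is

```
score(A) = sum_i w_i * ( LAP_i(A) - alpha_i * D_i(A) )
```

where `D_i` is the number of disconnected bases for library *i* and
`alpha_i = 3` by default.  The penalty is deliberately large: an
unsupported join must always score worse than leaving the pieces apart.

### Alignment

Short reads are aligned with a seed-and-extend scheme: exact k-mer seeds
(default seed length 13) are located via a hash index, extended with
banded edit-distance alignment (`edlib`), and deduplicated by end
position.  Alignments with an edit fraction above 0.3 are discarded.  An
exhaustive mode (used by the oracle tests) scores every ungapped placement
on both strands.  Long-read support uses the same machinery with
MinHash-based candidate filtering: the Jaccard similarity of k-mer sets is
estimated from 2000 seeded hash minima.

## 2. Incremental evaluation

Annealing needs thousands of score evaluations, so scores are computed
per *window*: each walk is cut at long-contig boundaries into overlapping
windows (overlap = one read length for single reads, insert mean plus six
standard deviations for pairs), and alignment hits are cached per window
keyed by window *content*.  Hits are stored window-relative and shifted to
walk coordinates on retrieval, so identical content recurring at a
different offset (or in a different walk) reuses the cache safely.  A move
that touches only some walks re-scores only the windows whose content
changed; per-read probability tallies are updated by subtracting the old
windows' contributions and adding the new ones.  The invariant
`|incremental - full recompute| <= 1e-6` is enforced in tests and
(optionally) after every accepted move via the `paranoid` flag.

## 3. The assembly graph and search

A conservative de Bruijn graph (default `k = 21`) is built from the reads:
k-mers occurring fewer than `min_count` times (default 2) are dropped,
unbranched paths are compacted into contigs.  Contigs longer than
`long_threshold` (default 500 bp) seed the initial assembly, one walk
each; short contigs are placed only as connective tissue inside walks.

Simulated annealing perturbs the walk set with six move families:

1. **extension** — extend a walk end through the graph;
2. **local improvement** — re-sample the path between two long contigs;
3. **repeat optimization** — add/remove a traversal of a short repeat
   contig;
4. **joining with advice** — join two walks whose reads pair across them,
   through sampled graph paths *or* an insert-estimated `N`-gap; all
   candidate paths are scored and only the best is proposed;
5. **disconnecting** — split a walk between long contigs, delete a fully
   redundant walk, or trim a terminal run whose long contigs are all
   placed elsewhere;
6. **repeat interchange** — re-pair the entries and exits of a
   multiply-traversed contig; cyclic re-pairings are linearized by cutting
   after the last repeat traversal.

Proposals are accepted with the Metropolis rule
`min(1, exp(delta / T))`; the temperature follows `T = t0 / ln(2 + it)`
with `t0` defaulting to 1% of the initial score magnitude.  The best
assembly ever visited is returned.

## 4. Postprocessing

The final assembly is made conservative by breaking ambiguous repeats:

- a multiply-traversed contig is broken unless **every** traversal is
  spanned by an alignment interval anchored on both flanks, and no
  alternative entry/exit pairing scores within tolerance (default relative
  `1e-3`) of the current one;
- every junction between consecutive long contigs must be bridged by an
  alignment interval penetrating at least half a read length into each
  side; otherwise the walk is cut there.  The margin matters: a read from
  the wrong copy of a repeat can align a few bases past the copy boundary
  by absorbing flank mismatches as errors, and such near-zero-weight hits
  must not count as support.

Broken repeats are emitted once as standalone scaffolds.  The result
trades contiguity for correctness: every surviving junction is supported
by data.

## 5. The simulator

`lapasm simulate` generates test instances: a uniform-random genome with
optional planted repeats (length, copy number, per-copy divergence are
configurable; placements are recorded in a BED file), then reads per
library: uniform start positions, per-base errors at the library rate,
paired reads from a Normal insert distribution, orientations `fr`, `rf`
or long single reads.  The simulator writes a ready-to-run config
(`run.yaml`) pointing at the generated FASTQ files.  It exists to make
every experiment in this repository reproducible from a seed; it is not a
general-purpose read simulator (no quality-score models, no indels in
short reads, no coverage biases).

## 6. Parameter defaults

| parameter | default | rationale |
|---|---|---|
| `error_rate` | required | library property; no safe default |
| `insert_mean`, `insert_sd` | required for paired | library property |
| `orientation` | `fr` | standard paired-end chemistry |
| `weight` | 1.0 | equal library weighting |
| `penalty_alpha` | 3.0 | unsupported joins must dominate any LAP gain |
| `conn_window` | read_length // 2 | a window as large as the read would leave single placements unable to connect anything |
| `noalign_offset` / `noalign_scale` | −15 / −0.2 | floor well below any genuine placement |
| graph `kmer_size` | 21 | longer than log4(genome) for the sizes used here, short enough for 100 bp reads |
| graph `min_count` | 2 | drops singleton error k-mers at ≥20× coverage |
| `long_threshold` | 500 | contigs above this are unambiguous anchors |
| annealing `t0` | 1% of initial score magnitude | scales acceptance to the problem |
| `max_iters` / `patience` | 5000 / 500 | converges on the 20 kb instances used in the tests |
| break `tolerance` | 1e-3 relative | score ties below measurement noise are ambiguous |

Problem sizes in the tests (genomes of 5–20 kb, reads of 20–100 bp,
coverage 20–40×) are our own choices: large enough to contain repeats
longer than a read and mate-pair-resolvable structure, small enough that
the whole suite runs in minutes.

## 7. Numerical choices

- All probability arithmetic is done in natural-log space; per-read sums
  over placements exponentiate alignment log-weights relative to their
  maximum.
- LAP values are means of logs; two assemblies are compared by score
  difference only, absolute values depend on |R| and L.
- The incremental evaluator is validated against full recomputation to
  `1e-6`; residual differences come from floating-point summation order.
- Random behavior (simulation, annealing, hashing) is seeded everywhere;
  identical seeds give identical trajectories.

## 8. Known limitations

- Search is stochastic: on adversarial instances (repeat flanked by
  content reachable only through short contigs) the annealer can converge
  to a local optimum with a mis-phased repeat; postprocessing then breaks
  the unsupported junction, sacrificing contiguity rather than emitting a
  misjoin.
- Short-read alignment models substitutions only (indels enter via the
  banded extension but are scored as mismatches).
- The insert-size model is a single Normal per library; bimodal or
  heavy-tailed libraries are not modeled.
- Coverage is assumed approximately uniform; GC bias and other coverage
  models are out of scope.
- The assembler targets small (kilobase-to-megabase) haploid genomes;
  there is no ploidy model.
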