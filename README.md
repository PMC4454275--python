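# lapasm

Likelihood-guided genome assembly: score whole assemblies by the
probability of the reads that produced them, and search for the
maximum-likelihood assembly by simulated annealing over a conservative
de Bruijn graph.

## The idea

Conventional assembly metrics (N50, contig counts) reward contiguity even
when it is wrong.  `lapasm` instead treats an assembly *A* as a hypothesis
about the genome and scores it by the average log-probability of the read
data *R*:

```
LAP(A | R) = (1/|R|) * sum over reads r of log Pr(r | A)
```

`Pr(r | A)` sums over every alignment of the read (error model:
per-base substitution rate) and, for paired libraries, over every properly
oriented placement of the pair weighted by a Normal insert-size density.
Reads that do not fit anywhere are floored at a small probability rather
than vetoing the assembly.  A connectivity penalty is subtracted for bases
not genuinely covered by spanning evidence, so unsupported joins always
lose to honest fragmentation.  Higher LAP = better assembly; misjoins,
collapsed repeats, spurious duplications and missing sequence all lower
the score.

The search builds a conservative de Bruijn graph from the reads, seeds one
walk per long contig, and perturbs the walk set with six annealing moves
(extension, local re-routing, repeat copy-number changes, pair-advised
joining, splitting/trimming, and repeat entry/exit interchange), accepting
proposals by the Metropolis rule.  A final postprocessing pass breaks
every junction that the data does not unambiguously support.

See [docs/methods.md](docs/methods.md) for the full model, parameter
defaults and limitations.

## Worked example

Simulate a 20 kb genome containing a 1 kb repeat in two 2%-divergent
copies, sequenced with 40× paired-end 100 bp reads (0.5% error,
2000 ± 200 bp inserts) — the repeat is longer than a read, so only insert
spans can phase it.  Save as `sim.yaml`:

```yaml
simulate:
  genome_length: 20000
  seed: 1
  repeats:
    - {unit_length: 1000, copies: 2, divergence: 0.02}
  libraries:
    - {name: pe, coverage: 40, read_length: 100, error_rate: 0.005,
       paired: true, insert_mean: 2000, insert_sd: 200, seed: 2}
graph: {kmer_size: 21, min_count: 3}
annealing: {max_iters: 2000, patience: 600, seed: 3}
```

Then run the pipeline:

```console
$ lapasm simulate --config sim.yaml --out-dir data
genome of 20000 bp and 1 libraries in data

$ lapasm assemble --config data/run.yaml --out-dir asm
1 walks, 19977 bp, score -23.6078 -> asm/assembly.fasta

$ lapasm stats --assembly asm/assembly.fasta --truth data/genome.fasta --out stats.json
largest	19977
misjoins	0
n50	19977
n50_truth	19977
num_sequences	1
total_length	19977
truth_length	20000
```

The assembler recovers the genome as a single scaffold with zero
misjoins (the ~23 bp shortfall is the genome ends, where coverage decays
to zero).  `asm/` also contains the walks (`walks.json`), the assembly
graph (`graph.gfa`), the annealing trajectory (`trajectory.tsv`) and a
score breakdown (`summary.json`):

```json
{
  "total": -23.60779019502738,
  "per_set_lap": [-23.60779019502738],
  "disconnected_bases": [0],
  "penalties": [0.0],
  "num_walks": 1,
  "total_length": 19977,
  "n50": 19977
}
```

Other commands:

- `lapasm improve --config run.yaml --assembly draft.fasta --out-dir out`
  — map an existing assembly onto the graph and anneal from there;
  breaks unsupported joins and makes supported ones.
- `lapasm score --config run.yaml --assembly any.fasta --out score.json`
  — score any FASTA under the model without searching.

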