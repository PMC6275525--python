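# damkit

DamID-seq analysis toolkit. From per-sample aligned-read positions (or
precomputed fragment-count tables) damkit builds GATC-fragment occupancy
tracks, calls gene-level RNA-polymerase-II "expression" with a permutation
FDR, classifies genes by cell-type specificity, calls TF-binding peaks with
gene-body target assignment, and integrates the resulting gene sets into
candidate-regulator reports. A synthetic-data generator with planted truth
makes every stage testable offline.

## How it works

- **Fragment map** — the genome is cut at every `GA^TC` (DpnI cleavage
  point, motif start + 2) on the forward strand; the intervals between cuts
  are the native resolution unit of all signal. Terminal fragments (touching
  chromosome ends) are flagged and excluded from scoring by default.
- **Occupancy track** — per fragment, `r_i = log2(F_i / D_i)` where `F`
  and `D` are pseudocount-smoothed, library-size-normalized frequencies of
  the Dam-fusion and Dam-only samples, median-centered over internal
  fragments.
- **Gene calls** — a gene's score `g` is the length-weighted mean of `r`
  over its overlapping internal fragments. The null resamples the same
  number of internal fragments genome-wide; `p = (1 + #{null >= g})/(M+1)`,
  Benjamini–Hochberg across genes, and `expressed = (q < θ) and (g > 0)`.
- **Specificity** — genes are A-specific (`q_A < θ`, `q_B >= θ`),
  B-specific, shared, or neither; shared genes with fold
  `F = 2^(g_A - g_B) >= fold_min` are sub-labelled enriched.
- **Peaks** — candidate peaks are runs of ≥ 2 consecutive internal
  fragments above the track's 95th percentile, scored as mean × length;
  significance comes from within-chromosome permutations of fragment values
  (empirical null-to-observed count ratio, monotonized). Target genes are
  those whose bodies overlap a retained peak by ≥ 1 bp.

## CLI

`damkit` exposes each stage as a subcommand plus a `run` driver over a
fixed output layout:

```sh
# full synthetic run: simulate -> fragments -> track -> genecall ->
# peakcall -> integrate -> report
damkit run --config config.yaml --out outdir --seed 1

# individual stages on arbitrary inputs
damkit fragments --genome genome.fa --out outdir
damkit count --fragments outdir/fragments.bed --reads reads.bed \
    --sample-id fusion_A --out outdir
damkit genecall --out outdir --fdr 0.01 --permutations 1000 --seed 1
damkit peakcall --out outdir --fdr 0.01 --shuffles 100 --seed 1
```

A YAML config provides defaults (`seed`, `fdr`, `pseudocount`,
`permutations`, `shuffles`, `fold_min`, and a `simulation:` block);
command-line flags override it. Every stage writes a JSON manifest with
parameters, seed, and SHA-256 checksums of its outputs; runs with the same
config and seed are byte-identical.

## Layout

```
src/damkit/
  reference.py    genome/GFF3 ingestion, GATC fragment map, gene assignment
  signal.py       read counting, occupancy tracks, bedGraph/TSV I/O
  expression.py   gene scoring, permutation FDR calls, specificity classes
  binding.py      peak calling, target-gene assignment
  integration.py  Venn regions, TF ranking, enrichment, chi-square
  simulate.py     synthetic genomes/annotations/counts with planted truth
  cli.py          subcommands, config handling, manifests
tests/            unit + property tests and tests/test_acceptance.py
scripts/acceptance.py
```
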