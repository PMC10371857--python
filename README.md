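# poolscan

Selection scans for pooled population sequencing (pool-seq). `poolscan`
takes per-site nucleotide counts for several pooled populations (the
PoPoolation2 "sync" format), computes windowed differentiation statistics,
flags genomic regions where one focal population has diverged far beyond
background drift, and screens the non-synonymous variants inside those
regions for large, significant allele-frequency shifts with predicted
functional impact.

The package also ships a calibrated simulator of the whole setting —
drifted allele frequencies, pooled sampling, read depth — so every
statistic can be validated against planted truth, plus small utilities for
pooled nucleotide diversity and best-hit gene-family summaries.

## The method in brief

**Differentiation.** For two pools with allele frequencies `p1, p2`
estimated from `C1, C2` reads, the per-site Hudson FST components are

```
num = (p1 - p2)^2 - p1(1-p1)/(C1-1) - p2(1-p2)/(C2-1)
den = p1(1-p2) + p2(1-p1)
```

and a window's FST is the ratio of summed numerators to summed
denominators ("ratio of averages"), clamped to `[0, 1 - 1e-6]`.

**PBS.** FST converts to a branch length `T = -log(1 - FST)`. For a
population triplet (A, B, C) the population branch statistic of A is

```
PBS_A = (T_AB + T_AC - T_BC) / 2
```

— the frequency change along A's own branch since its split from B and C.
Large PBS in a focal population, not mirrored in the others, marks a
candidate selective sweep.

**Consensus outliers.** With one focal population and `k` others, every
pair of others forms a triplet. Each triplet's windowed PBS track gets its
own empirical top-0.1% nearest-rank threshold; windows strictly above it
in at least `min_support` triplets are outliers, and overlapping or
book-ended outlier windows merge into selection loci. Genes within ±50 kb
of a locus are reported as associated.

**Variant screen.** Inside the loci, non-synonymous variants are kept when
the focal-vs-others allele-frequency contrast is large (`|dAF| >= 0.5`)
and significant (two-sided Fisher's exact test on pooled read counts,
Benjamini–Hochberg adjusted `p < 0.05`). A substitution is called
deleterious when `PROVEAN < -2.5` or `SIFT < 0.05`; a missing score simply
drops its disjunct.

**Simulator.** Ancestral frequencies are uniform; each population drifts
under the Balding–Nichols model, `p_i ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`,
with variance `F·p(1-p)`. Inside planted sweep intervals the focal
population redraws with a much larger `F`. Reads arrive by two-stage
sampling: binomial draw of the pool's `2N` chromosomes, negative-binomial
depth, binomial read counts given the pool frequency.

See [docs/methods.md](docs/methods.md) for parameter defaults, numerical
conventions and limitations.

## Worked example

The repository ships a small synthetic world
([examples/demo_config.yaml](examples/demo_config.yaml)): four pools of 8
diploids, a 2 × 2 Mb genome with 20,000 SNPs, baseline drift F = 0.05 and
one planted 25-kb sweep at chr1:600,000–625,000 with sweep F = 0.6.

```console
$ poolscan run --config examples/demo_config.yaml --out-dir demo --verbose
[poolscan] simulated 20000 sites, 60 genes
[poolscan] scanning 3 triplets, window 5000, step 4000, coverage [4, 40], top 0.01
[poolscan] 1 loci, 3 associated genes
[poolscan] 1 candidate substitutions
done in 1.2 s; 8 artifacts in demo
```

The scan recovers exactly the planted sweep (`demo/loci.tsv`, 1-based
inclusive coordinates):

```
chrom  start   end     n_windows  support  supporting_triplets                              peak_pbs            genes
chr1   600001  625000  6          3        focal-east-west;focal-east-south;focal-west-south  0.5534413509510843  g00003;g00004;g00005
```

and the variant screen flags one deleterious substitution inside it
(`demo/candidates.tsv`, abridged):

```
chrom  pos     gene_id  position  af_focal  d_af                p_adjusted              provean  sift  deleterious
chr1   612575  g00003   359       1.0       0.8492259552042161  1.1821933929788877e-08  -2.76    NA    True
```

Each run also writes the simulated sync table, the gene annotation, the
per-triplet PBS tracks, the true simulated frequencies (`truth.tsv`) and a
`manifest.json` with the config snapshot, the derived stage seeds and a
SHA-256 digest of every artifact; re-running with the same config is
byte-identical.

The individual stages are available as subcommands
(`poolscan simulate | pi | fst | pbs | scan | variants | families`) for
real data; run any of them with `--help`.

## Using the library

```python
from poolscan import read_sync, pbs_scan, ScanConfig, consensus_loci, triplet_combinations

table = read_sync("pools.sync")
genome = [("chr1", 50_000_000)]
triplets = triplet_combinations("alpine", ["east", "west", "south"])
tracks = [pbs_scan(table, t, genome, window=5000, step=4000,
                   min_cov=4, max_cov=40, min_sites=5) for t in triplets]
loci = consensus_loci(tracks, ScanConfig(triplets, top_fraction=0.001, min_support=2))
```

Internally all coordinates are 0-based half-open; sync and result files
are read and written 1-based, matching the conventions of the formats.

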