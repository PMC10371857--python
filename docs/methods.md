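# Methods

This note records the statistical model, the parameter defaults and the
numerical conventions implemented in `poolscan`, together with the design
decisions behind them and the limitations of the simulator.

## 1. Data model and coordinates

Input is the PoPoolation2 *sync* format: one row per site with chromosome,
1-based position, reference base, and an `A:T:C:G:N:del` count sextet per
pool. Internally every coordinate is 0-based half-open; positions are
shifted down by one on read and up by one on write, and all result tables
(windows, loci) are emitted 1-based inclusive. Gene annotations are
accepted as BED (0-based half-open, passed through) or GFF3 `gene` records
(1-based inclusive, converted on read).

## 2. Allele reduction

A site enters differentiation statistics only if, pooling reads over all
involved pools, exactly two of A/T/C/G have at least `min_minor_count`
(default 2) reads; `N` and `del` columns never count as alleles. Sites
with three or more well-supported alleles, or with no alternate reads at
all, are skipped. The minor-read floor reflects that a single supporting
read at pool-seq depths is more often sequencing error than polymorphism.

## 3. Hudson FST, ratio of averages

Per site, with read frequencies `p1, p2` at nucleotide depths `C1, C2`:

```
num = (p1 - p2)^2 - p1(1-p1)/(C1-1) - p2(1-p2)/(C2-1)
den = p1(1-p2) + p2(1-p1)
```

Both pools must have depth within `[max(min_cov, 2), max_cov]` for the
site to be *usable*. A window's FST is `sum(num) / sum(den)` over its
usable sites (ratio of averages — more robust at low depth than averaging
per-site ratios), clamped to `[0, FST_CAP]` with `FST_CAP = 1 - 1e-6`.
Windows with no usable sites, with `den <= 0`, or with fewer than
`min_sites` usable sites are reported as missing (NaN), never as zero.
`min_sites` defaults to 1 in the library; the benchmark uses 5 (§8).

## 4. PBS

`T = -log(1 - FST)` converts FST to a branch length; the cap above keeps
it finite. For a triplet (A, B, C),
`PBS_A = (T_AB + T_AC - T_BC) / 2`. The implementation preserves the
algebraic identity `PBS_A + PBS_B + PBS_C = (T_AB + T_AC + T_BC) / 2`
exactly (it is part of the acceptance suite), and missingness propagates:
a window missing any pairwise FST has missing PBS.

## 5. Outlier windows, consensus loci, gene association

Windows are 5 kb advancing by 4 kb by default (1 kb overlap); only full
windows are formed, except that a chromosome shorter than one window gets
a single truncated window.

The outlier threshold is the empirical `1 - top_fraction` quantile by the
nearest-rank rule, `h = ceil((1 - f) * n)` (computed with a `1e-9` slack
to avoid float-representation overshoot at exact products), over the
finite PBS values of each triplet track separately; a window is an outlier
iff its PBS is **strictly greater** than the threshold. On 1..10000 with
`f = 0.001` the threshold is 9990 and exactly 10 values exceed it. A
warning is emitted when fewer than `1/f` finite values are available, in
which case the quantile is poorly resolved.

A window becomes part of a selection locus when it is an outlier in at
least `min_support` (default 2) of the triplets sharing the focal
population. Overlapping **and book-ended** (abutting) outlier windows on
the same chromosome merge into a single locus; the locus records its
supporting triplets and peak PBS. Genes associate with a locus when their
interval intersects the locus extended by `flank_bp = 50 kb` on each side
(half-open intersection, so a gene starting exactly at the flank boundary
does not associate); a gene can associate with several loci but is counted
once in the genome-wide selected-gene set.

## 6. Variant screen

For each candidate non-synonymous variant inside a locus:

* per-pool allele frequencies come from the biallelic reduction (§2);
* `dAF = af_focal - mean(af_others)`; the screen keeps `|dAF| >= daf_floor`
  (default 0.5);
* significance is a two-sided Fisher's exact test on the 2×2 table of
  focal alt/ref reads versus the *pooled* alt/ref reads of the other
  populations, Benjamini–Hochberg adjusted across the whole screened set;
  keep `p_adjusted < alpha` (default 0.05);
* a substitution is deleterious iff `PROVEAN < -2.5` **or** `SIFT < 0.05`
  (strict inequalities). A missing score drops its disjunct; a variant
  with both scores missing gets a missing call rather than an error at
  screening time (calling `classify_deleterious` directly with two missing
  scores raises).

## 7. Diversity

Per-pool coverage is bounded before any diversity estimate: sites below
`min_cov = 4` or above a ceiling are dropped. The default ceiling is
"mode plus half": `floor(1.5 × modal depth)` computed from the pool's own
depth distribution, ties between modes broken toward the smaller (the
conservative choice for repeat-inflated depth); a fixed ceiling is
available. Sites can be drawn down to a uniform target depth by
hypergeometric subsampling of the A/T/C/G reads.

Per-site diversity is `pi = C/(C-1) * (1 - sum_a p_a^2)`; a site whose
minor-read count is below `min_minor_count` counts as monomorphic
(`pi = 0`). Window pi is the sum of per-site values divided by the number
of *covered* sites in the window, so masked stretches do not deflate the
estimate; windows with no covered site are missing.

## 8. Simulator and benchmark

Frequencies: ancestral `p ~ Uniform(0.05, 0.95)` (range configurable);
each population independently draws
`p_i ~ Beta(p(1-F)/F, (1-p)(1-F)/F)` (Balding–Nichols; mean `p`, variance
`F p (1-p)`). Within each planted sweep interval the focal population
redraws with that sweep's larger `F`, pushing its frequencies toward
fixation. Reads: per site a uniform reference base and a distinct
alternate; the pool's `2N` chromosomes are a binomial draw from `p_i`,
depth is negative-binomial (`mean`, `shape`; variance `m + m²/shape`),
and alternate reads are binomial given the pool's chromosome frequency —
so the pooled-sampling noise of small pools is explicitly modelled.
SNP positions are distinct and uniform (rejection sampling, so large
genomes are never materialised). One master seed fans out to independent
per-stage streams via `numpy.random.SeedSequence.spawn`; all derived seeds
are reduced below 2³¹.

The recovery benchmark plants ten 25-kb sweeps (`sweep_F = 0.6`) at fixed
positions in a 4 × 50.001-Mb genome — exactly 50,000 analysis windows —
with four pools of 8 diploids, `baseline_F = 0.05`, one million SNPs and
mean depth 20 (shape 5), and scores the scan's merged loci against the
planted intervals over 20 replicate worlds: *recall* is the fraction of
sweeps overlapping a reported locus, the *false-locus fraction* is the
fraction of loci overlapping no sweep.

Benchmark parameter choices, fixed at design time from a power analysis
of the window statistics:

* **SNP density 5/kb** (one million SNPs): at 5-kb windows this yields
  ~25 usable SNPs per window; sparser panels leave windows with a handful
  of sites, where the ratio-of-averages estimator is noise-dominated.
* **`min_sites = 5`**: suppresses exactly those noise-dominated windows;
  kept as a library parameter (default 1) since thin windows can carry
  signal in real sparse data.
* **`max_cov = 40`** (twice the mean depth): the repeat-masking upper
  bound scaled to the simulated depth distribution.
* **sweep length 25 kb**: several windows wide, so recovery tests the
  window consensus rather than single-window luck.
* **depth shape 5**: strong overdispersion, the pessimistic end of real
  pooled libraries.

## 9. Gene families

Genes cluster by their best hit against a reference proteome: top
bit-score, ties broken by longer reference, then lexicographic reference
id for determinism. The duplicated-gene proportion is
`P_D = (genes in families of size >= 2) / (clustered genes)`; no-hit genes
are excluded from the denominator by default (flag to include — they can
never appear duplicated under best-hit clustering, so including them only
lowers `P_D`). Family-size matrices across two or more species are
written in the CAFE input layout (`Desc`, `Family ID`, one column per
species).

## 10. Limitations

The simulator draws sites independently: no linkage, so no LD-based
statistics can be validated against it, and sweep signals have no hitchhiking
shoulder. There is no sequencing error, no reference bias, no indels, and
no mapping artefacts beyond what the coverage bounds emulate. The
Balding–Nichols model has no explicit demography (no migration,
bottlenecks or shared branches); `F` summarises all drift. The variant
annotations in the pipeline's synthetic mode (residue index, amino acids,
effect scores) are placeholders with realistic marginals, not the output
of a real annotator — on real data, supply annotator output via the
`variants` and `effects` inputs instead.
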