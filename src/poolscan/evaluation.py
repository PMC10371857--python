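"""Parameter-recovery benchmark for the selection scan.

The benchmark plants sweeps of known location in a synthetic genome and asks
two questions of the full scan pipeline (simulate -> PBS per triplet ->
empirical threshold -> triplet consensus -> merged loci):

* **recall** — what fraction of planted sweep intervals overlap a reported
  selection locus;
* **false-locus fraction** — what fraction of reported loci overlap no
  planted sweep.

The standard conditions are four pooled populations of 8 diploids each, a
200 Mb genome yielding 50,000 analysis windows (5 kb advancing by 4 kb),
one million SNPs (about 5 per kb, the density of a diverse pooled sample),
baseline drift F = 0.05, ten planted 25-kb sweeps at sweep F = 0.6 in the
focal population, and mean pool depth 20x (negative-binomial, shape 5).
The three triplets pair the focal population with every pair of the
remaining three; windows with at least five informative sites whose PBS
lies above the triplet's own top-0.1% quantile, in at least two triplets,
form the reported loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .differentiation import pbs_scan
from .scan import ScanConfig, SelectionLocus, consensus_loci, triplet_combinations
from .simulate import SimConfig, Sweep, simulate_frequency_landscape, simulate_pool_counts

#: window geometry and filters of the standard benchmark scan
BENCH_WINDOW = 5_000
BENCH_STEP = 4_000
BENCH_MIN_COV = 4
BENCH_MAX_COV = 40        # twice the mean simulated depth
BENCH_TOP_FRACTION = 0.001
BENCH_MIN_SUPPORT = 2
BENCH_MIN_SITES = 5       # informative sites a window needs for a usable FST

_SWEEP_LEN = 25_000
_SWEEP_POSITIONS = [
    ("chr1", 5_000_000), ("chr1", 20_000_000), ("chr1", 35_000_000),
    ("chr2", 8_000_000), ("chr2", 24_000_000), ("chr2", 40_000_000),
    ("chr3", 12_000_000), ("chr3", 30_000_000),
    ("chr4", 16_000_000), ("chr4", 44_000_000),
]


def benchmark_config(seed: int, scale: float = 1.0) -> SimConfig:
    """The standard benchmark world, optionally scaled down.

    ``scale`` < 1 shrinks the genome, SNP count and sweep count together
    (used for quick smoke runs); the per-window SNP density, depths and
    drift parameters are untouched.
    """
    chrom_len = 50_001_000          # 12,500 windows of 5 kb at 4 kb step
    n_chroms = 4
    sweeps = [Sweep(c, p, p + _SWEEP_LEN, 0.6) for c, p in _SWEEP_POSITIONS]
    n_snps = 1_000_000
    if scale < 1.0:
        chrom_len = max(int(chrom_len * scale), 200 * BENCH_STEP)
        n_snps = max(int(n_snps * scale), 5000)
        sweeps = [s for s in sweeps if s.end <= chrom_len]
    genome = [(f"chr{i + 1}", chrom_len) for i in range(n_chroms)]
    return SimConfig(
        pop_names=("focal", "east", "west", "south"),
        focal_pop="focal",
        genome=genome,
        n_snps=n_snps,
        baseline_F=0.05,
        sweeps=sweeps,
        pool_diploids=8,
        depth_mean=20.0,
        depth_shape=5.0,
        seed=seed,
    )


@dataclass
class ReplicateResult:
    seed: int
    n_sweeps: int
    n_recovered: int
    n_loci: int
    n_false_loci: int
    loci: list[SelectionLocus] = field(repr=False, default_factory=list)


def _overlaps(locus: SelectionLocus, sweep) -> bool:
    return locus.chrom == sweep.chrom and locus.start < sweep.end \
        and sweep.start < locus.end


def run_replicate(seed: int, scale: float = 1.0) -> ReplicateResult:
    """One full simulate-and-scan cycle scored against the planted truth."""
    cfg = benchmark_config(seed, scale=scale)
    panel = simulate_frequency_landscape(cfg)
    table = simulate_pool_counts(panel, cfg)

    others = [p for p in cfg.pop_names if p != cfg.focal_pop]
    triplets = triplet_combinations(cfg.focal_pop, others)
    tracks = [
        pbs_scan(table, trip, cfg.genome,
                 window=BENCH_WINDOW, step=BENCH_STEP,
                 min_cov=BENCH_MIN_COV, max_cov=BENCH_MAX_COV,
                 min_sites=BENCH_MIN_SITES)
        for trip in triplets
    ]
    scan_cfg = ScanConfig(triplets=triplets, top_fraction=BENCH_TOP_FRACTION,
                          min_support=BENCH_MIN_SUPPORT)
    loci = consensus_loci(tracks, scan_cfg)

    recovered = sum(any(_overlaps(l, s) for l in loci) for s in cfg.sweeps)
    false = sum(not any(_overlaps(l, s) for s in cfg.sweeps) for l in loci)
    return ReplicateResult(seed=seed, n_sweeps=len(cfg.sweeps),
                           n_recovered=recovered, n_loci=len(loci),
                           n_false_loci=false, loci=loci)


def sweep_recovery(n_replicates: int = 20, seed: int = 0,
                   scale: float = 1.0) -> dict:
    """Aggregate recall and false-locus fraction over replicate worlds.

    Replicate seeds derive deterministically from ``seed``; results pool the
    counts over all replicates before forming the two fractions.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(c.generate_state(1, np.uint32)[0]) % (2 ** 31)
                   for c in ss.spawn(n_replicates)]
    results = [run_replicate(s, scale=scale) for s in child_seeds]
    n_sweeps = sum(r.n_sweeps for r in results)
    n_recovered = sum(r.n_recovered for r in results)
    n_loci = sum(r.n_loci for r in results)
    n_false = sum(r.n_false_loci for r in results)
    return {
        "n_replicates": n_replicates,
        "n_sweeps": n_sweeps,
        "n_recovered": n_recovered,
        "n_loci": n_loci,
        "n_false_loci": n_false,
        "recall": n_recovered / n_sweeps if n_sweeps else float("nan"),
        "false_locus_fraction": n_false / n_loci if n_loci else 0.0,
        "replicates": results,
    }
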