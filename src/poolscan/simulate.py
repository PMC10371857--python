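"""Synthetic pool-seq data with known divergence structure and planted sweeps.

The generator follows the Balding–Nichols divergence model: each population's
allele frequency at a site is a Beta draw around the ancestral frequency p,

    p_i ~ Beta(p (1 - F) / F,  (1 - p)(1 - F) / F),

whose variance is exactly ``F p (1 - p)``.  The drift coefficient F is
``baseline_F`` everywhere except for the *focal* population inside planted
sweep intervals, where the larger ``sweep_F`` produces the elevated
focal-branch differentiation that the scan stage is meant to recover.

Sequencing of a pool is a two-stage sampling process: the 2N chromosomes of
the pool are drawn binomially from the population frequency, then reads are
drawn binomially from the realised pool frequency at a negative-binomially
distributed depth.  Sites are biallelic; reference and alternate bases are
assigned per site and counts placed in the matching sync columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import GeneFeature, SyncTable, SYNC_ALLELES

_BASES = np.array(["A", "T", "C", "G"])
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class Sweep:
    """A planted interval of elevated focal-branch drift, half-open."""

    chrom: str
    start: int
    end: int
    sweep_F: float


@dataclass
class SimConfig:
    """Full description of the synthetic world.

    Parameters
    ----------
    pop_names : names of the pooled populations (>= 3).
    focal_pop : the population carrying the planted sweeps.
    genome : list of (chrom, length) pairs.
    n_snps : total segregating sites scattered over the genome.
    baseline_F : Balding–Nichols drift coefficient of every branch.
    sweeps : intervals in which the focal branch drifts with ``sweep_F``.
    pool_diploids : diploid individuals per pool (default 8, i.e. 16
        chromosomes — the usual design for small pooled samples).
    depth_mean, depth_shape : negative-binomial read-depth model; the shape
        parameter controls overdispersion (variance = m + m^2/shape).
    seed : master seed; every stochastic stage derives a child stream.
    """

    pop_names: Sequence[str]
    focal_pop: str
    genome: Sequence[tuple[str, int]]
    n_snps: int
    baseline_F: float
    sweeps: Sequence[Sweep] = field(default_factory=list)
    pool_diploids: int = 8
    depth_mean: float = 20.0
    depth_shape: float = 5.0
    ancestral_p_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self):
        self.pop_names = list(self.pop_names)
        if len(self.pop_names) < 3:
            raise ConfigurationError("need at least 3 populations")
        if len(set(self.pop_names)) != len(self.pop_names):
            raise ConfigurationError("duplicate population names")
        if self.focal_pop not in self.pop_names:
            raise ConfigurationError(f"focal_pop {self.focal_pop!r} not among pools")
        if not 0.0 < self.baseline_F < 1.0:
            raise ConfigurationError("baseline_F must lie in (0, 1)")
        chrom_len = dict(self.genome)
        if len(chrom_len) != len(self.genome):
            raise ConfigurationError("duplicate chromosome names in genome")
        self.sweeps = [s if isinstance(s, Sweep) else Sweep(*s) for s in self.sweeps]
        for s in self.sweeps:
            if s.chrom not in chrom_len:
                raise ConfigurationError(f"sweep on unknown chromosome {s.chrom!r}")
            if not (0 <= s.start < s.end <= chrom_len[s.chrom]):
                raise ConfigurationError(
                    f"sweep [{s.start}, {s.end}) outside {s.chrom} "
                    f"(length {chrom_len[s.chrom]})"
                )
            if not self.baseline_F < s.sweep_F < 1.0:
                raise ConfigurationError(
                    "sweep_F must lie in (baseline_F, 1)"
                )
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be positive")
        if self.depth_mean <= 0 or self.depth_shape <= 0:
            raise ConfigurationError("depth parameters must be positive")
        if self.pool_diploids < 1:
            raise ConfigurationError("pool_diploids must be positive")
        lo, hi = self.ancestral_p_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ConfigurationError("invalid ancestral_p_range")

    @property
    def n_pops(self) -> int:
        return len(self.pop_names)

    @property
    def focal_index(self) -> int:
        return self.pop_names.index(self.focal_pop)


@dataclass
class FrequencyPanel:
    """True per-site allele frequencies of the simulated populations."""

    pop_names: list[str]
    chroms: np.ndarray          # per-site chromosome
    pos: np.ndarray             # 0-based positions, sorted within chromosome
    ancestral_p: np.ndarray
    pop_p: np.ndarray           # (n_sites, n_pops)
    is_swept: np.ndarray        # bool

    @property
    def n_sites(self) -> int:
        return len(self.pos)


def _stage_rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    """Independent stream per simulation stage, all derived from cfg.seed."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[stage])


def _scatter_sites(cfg: SimConfig, rng: np.random.Generator):
    """Place n_snps distinct positions uniformly over the genome, sorted."""
    lengths = np.array([l for _, l in cfg.genome], dtype=np.int64)
    total = lengths.sum()
    if cfg.n_snps > total:
        raise ConfigurationError("more SNPs than genome positions")
    # distinct global offsets; rejection sampling avoids materialising the
    # full position space (the genome can be hundreds of Mb)
    if cfg.n_snps == total:
        offsets = np.arange(total, dtype=np.int64)
    else:
        chosen = np.empty(0, dtype=np.int64)
        while len(chosen) < cfg.n_snps:
            extra = rng.integers(0, total, size=2 * (cfg.n_snps - len(chosen)) + 16)
            chosen = np.unique(np.concatenate([chosen, extra]))
        chosen = rng.permutation(chosen)[: cfg.n_snps]
        offsets = np.sort(chosen)
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    chrom_idx = np.searchsorted(bounds, offsets, side="right") - 1
    pos = offsets - bounds[chrom_idx]
    chroms = np.array([cfg.genome[i][0] for i in chrom_idx], dtype=object)
    return chroms, pos.astype(np.int64)


def _swept_mask(cfg: SimConfig, chroms, pos) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for s in cfg.sweeps:
        mask |= (chroms == s.chrom) & (pos >= s.start) & (pos < s.end)
    return mask


def _balding_nichols(rng, p, F):
    """Beta draw with mean p and variance F p (1-p); degenerate F handled."""
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def simulate_frequency_landscape(cfg: SimConfig) -> FrequencyPanel:
    """Draw the true allele-frequency landscape for every population.

    Ancestral frequencies are uniform on ``cfg.ancestral_p_range``; each
    population then drifts independently under Balding–Nichols with its
    branch F.  Deterministic under ``cfg.seed``.
    """
    rng = _stage_rng(cfg, 0)
    chroms, pos = _scatter_sites(cfg, rng)
    lo, hi = cfg.ancestral_p_range
    p = rng.uniform(lo, hi, size=cfg.n_snps)
    swept = _swept_mask(cfg, chroms, pos)

    pop_p = np.empty((cfg.n_snps, cfg.n_pops))
    for i, name in enumerate(cfg.pop_names):
        pop_p[:, i] = _balding_nichols(rng, p, cfg.baseline_F)
    # redraw focal frequencies at swept sites with the per-sweep F
    fi = cfg.focal_index
    for s in cfg.sweeps:
        m = (chroms == s.chrom) & (pos >= s.start) & (pos < s.end)
        if m.any():
            pop_p[m, fi] = _balding_nichols(rng, p[m], s.sweep_F)
    return FrequencyPanel(list(cfg.pop_names), chroms, pos, p, pop_p, swept)


def simulate_pool_counts(panel: FrequencyPanel, cfg: SimConfig) -> SyncTable:
    """Sample sequencing read counts for every pool from the true frequencies.

    Per site and pool: the 2N pool chromosomes are a binomial draw from the
    population frequency, the site depth is negative-binomial with mean
    ``depth_mean``, and the alternate-read count is binomial in the realised
    pool frequency.  Each site gets a reference base (uniform over ACGT) and
    an alternate base (uniform over the remaining three); counts land in the
    corresponding sync columns.
    """
    if panel.pop_names != list(cfg.pop_names):
        raise ConfigurationError("panel and config populations differ")
    rng = _stage_rng(cfg, 1)
    n_sites, n_pops = panel.pop_p.shape
    two_n = 2 * cfg.pool_diploids

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4

    # pool chromosome sampling, then read sampling at NB depth
    k = rng.binomial(two_n, panel.pop_p)                       # (sites, pops)
    pool_freq = k / two_n
    nb_p = cfg.depth_shape / (cfg.depth_shape + cfg.depth_mean)
    depth = rng.negative_binomial(cfg.depth_shape, nb_p, size=(n_sites, n_pops))
    alt_reads = rng.binomial(depth, pool_freq)
    ref_reads = depth - alt_reads

    counts = np.zeros((n_sites, n_pops, 6), dtype=np.int64)
    rows = np.arange(n_sites)
    for pool in range(n_pops):
        counts[rows, pool, ref_idx] += ref_reads[:, pool]
        counts[rows, pool, alt_idx] += alt_reads[:, pool]
    ref_bases = _BASES[ref_idx]
    return SyncTable(panel.chroms, panel.pos, ref_bases, counts,
                     pools=list(cfg.pop_names))


def simulate_annotation(cfg: SimConfig, n_genes: int, gene_len: int,
                        seed: int | None = None) -> list[GeneFeature]:
    """Place non-overlapping genes uniformly over the genome.

    Guarantees, for every sweep, at least one gene inside the sweep interval
    and at least one gene more than 50 kb away from it, so that downstream
    gene-association logic is exercised on both sides of the flank rule.

    Raises :class:`ConfigurationError` when the requested genes cannot be
    packed into the genome.
    """
    rng = np.random.default_rng(seed if seed is not None else
                                np.random.SeedSequence(cfg.seed).spawn(8)[2])
    if n_genes == 0:
        return []
    chrom_len = dict(cfg.genome)
    if gene_len < 1 or gene_len > max(chrom_len.values()):
        raise ConfigurationError("gene_len does not fit in any chromosome")
    if n_genes * gene_len > sum(chrom_len.values()):
        raise ConfigurationError("genes do not fit in the genome")

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_len}

    def overlaps(chrom, start, end):
        return any(start < e and s < end for s, e in placed[chrom])

    intervals: list[tuple[str, int, int]] = []

    def put(chrom, start):
        end = start + gene_len
        placed[chrom].append((start, end))
        intervals.append((chrom, start, end))

    # one gene inside each sweep
    for s in cfg.sweeps:
        if len(intervals) >= n_genes:
            break
        start = max(s.start, min(s.end - 1, (s.start + s.end) // 2) - gene_len // 2)
        start = min(start, chrom_len[s.chrom] - gene_len)
        if overlaps(s.chrom, start, start + gene_len):
            continue
        put(s.chrom, start)

    # the rest uniformly, rejecting overlaps
    lengths = np.array([chrom_len[c] for c, _ in cfg.genome], dtype=float)
    weights = lengths / lengths.sum()
    tries = 0
    max_tries = 1000 * n_genes
    while len(intervals) < n_genes:
        tries += 1
        if tries > max_tries:
            raise ConfigurationError("could not pack genes without overlap")
        ci = rng.choice(len(cfg.genome), p=weights)
        chrom, clen = cfg.genome[ci]
        if clen < gene_len:
            continue
        start = int(rng.integers(0, clen - gene_len + 1))
        if overlaps(chrom, start, start + gene_len):
            continue
        put(chrom, start)

    # ensure a gene far (>50 kb) from every sweep exists somewhere
    def far_from_all_sweeps(chrom, start, end):
        for s in cfg.sweeps:
            if chrom == s.chrom and start < s.end + 50_000 and s.start - 50_000 < end:
                return False
        return True

    if cfg.sweeps and not any(far_from_all_sweeps(*iv) for iv in intervals):
        raise ConfigurationError(
            "annotation has no gene distant from the sweeps; "
            "increase n_genes or the genome size"
        )

    intervals.sort()
    return [
        GeneFeature(f"g{i + 1:05d}", chrom, start, end)
        for i, (chrom, start, end) in enumerate(intervals)
    ]


def write_truth(panel: FrequencyPanel, dest) -> None:
    """Emit the per-site truth (true p per population, sweep flag) as TSV."""
    import pandas as pd
    from .io import _open_text

    df = pd.DataFrame({
        "chrom": panel.chroms,
        "pos": panel.pos + 1,
        "ancestral_p": panel.ancestral_p,
        "is_swept": panel.is_swept.astype(int),
    })
    for i, name in enumerate(panel.pop_names):
        df[f"p_{name}"] = panel.pop_p[:, i]
    stream, close = _open_text(dest, "wt")
    try:
        df.to_csv(stream, sep="\t", index=False)
    finally:
        if close:
            stream.close()


def simulate_effect_scores(variants, seed: int) -> "pd.DataFrame":
    """Draw PROVEAN/SIFT-like effect scores for a table of substitutions.

    Real effect scores come from conservation-based predictors run outside
    this package; for a fully synthetic pipeline run we emulate their joint
    output: PROVEAN-like scores roughly normal around mild deleteriousness,
    SIFT-like scores Beta-distributed on [0, 1], with an occasional missing
    SIFT value (the predictor fails when too few orthologues align).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = len(variants)
    provean = np.round(rng.normal(-1.0, 1.8, size=n), 2)
    sift = np.round(rng.beta(0.7, 2.0, size=n), 3)
    sift = np.where(rng.random(n) < 0.15, np.nan, sift)
    out = variants[["gene_id", "position", "ref_aa", "alt_aa"]].copy()
    out["provean"] = provean
    out["sift"] = sift
    return out
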