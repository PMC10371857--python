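"""Pairwise FST from pooled read counts and the population branch statistic.

FST uses the Hudson-type estimator in its ratio-of-averages form.  At a
biallelic site with read frequencies p1, p2 and nucleotide depths C1, C2 the
per-site components are

    numerator   = (p1 - p2)^2 - p1 (1 - p1) / (C1 - 1) - p2 (1 - p2) / (C2 - 1)
    denominator = p1 (1 - p2) + p2 (1 - p1)

and a window's FST is the sum of numerators over the sum of denominators.
Reads stand in for sampled chromosomes in the correction terms: only read
counts are observed in pool-seq, and at the moderate depths retained by the
coverage filters the difference from a chromosome-based correction is
second-order.  Window FST is clamped into [0, 1 - 1e-6] so the log transform
below stays finite.

The population branch statistic (PBS) for a triplet (A, B, C) with A focal is

    PBS_A = (T_AB + T_AC - T_BC) / 2,        T = -log(1 - FST),

the length of A's branch in the three-population tree.  A window missing any
pairwise FST yields a missing PBS rather than a fabricated zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import WindowStatTrack, window_grid
from .io import SyncTable

FST_CAP = 1.0 - 1e-6


@dataclass(frozen=True)
class FstComponents:
    """Per-site Hudson estimator components."""

    chrom: str
    pos: int
    numerator: float
    denominator: float


@dataclass
class TripletPbsTrack:
    """Focal-branch PBS of one population triplet across windows."""

    triplet: tuple[str, str, str]     # (focal, pop2, pop3)
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    t_ab: np.ndarray
    t_ac: np.ndarray
    t_bc: np.ndarray
    pbs: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def to_frame(self) -> pd.DataFrame:
        a, b, c = self.triplet
        return pd.DataFrame({
            "chrom": self.chroms,
            "start": self.starts + 1,
            "end": self.ends,
            f"T_{a}_{b}": self.t_ab,
            f"T_{a}_{c}": self.t_ac,
            f"T_{b}_{c}": self.t_bc,
            "pbs": self.pbs,
        })


def biallelic_reduce(counts, min_minor_count: int = 2):
    """Reduce one site's per-pool count tuples to biallelic frequencies.

    Identifies the two most frequent nucleotides pooled over all populations
    and returns ``(p, n)`` with p the per-pool frequency of the minor
    (alternate) allele among reads of those two bases and n the per-pool
    biallelic read depth.  Returns ``None`` (skip) when the site is
    monomorphic across all pools or when more than two alleles reach
    ``min_minor_count`` reads overall.
    """
    counts = np.asarray(counts, dtype=np.int64)
    nt = counts[:, :4]
    total = nt.sum(axis=0)
    order = np.argsort(-total, kind="stable")
    major, alt = order[0], order[1]
    if total[alt] == 0:
        return None  # monomorphic everywhere
    if int(np.sum(total >= min_minor_count)) > 2:
        return None  # more than two real alleles
    n = nt[:, major] + nt[:, alt]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, nt[:, alt] / np.maximum(n, 1), np.nan)
    return p, n


def site_fst(p1: float, c1: float, p2: float, c2: float) -> tuple[float, float]:
    """Hudson per-site components (numerator, denominator) for one pair."""
    if c1 < 2 or c2 < 2:
        raise ValueError("need at least 2 reads per pool")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (c1 - 1) - p2 * (1 - p2) / (c2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def branch_length(fst):
    """PBS branch length T = -log(1 - FST); requires FST in [0, 1 - 1e-6]."""
    arr = np.asarray(fst, dtype=float)
    finite = np.isfinite(arr)
    if np.any((arr[finite] < 0) | (arr[finite] > FST_CAP)):
        raise ValueError(f"FST outside [0, {FST_CAP}]; clamp upstream")
    out = -np.log1p(-arr)
    return float(out) if np.isscalar(fst) else out


# ---------------------------------------------------------------------------
# vectorised site-level machinery
# ---------------------------------------------------------------------------

def _reduce_table(table: SyncTable, min_minor_count: int):
    """Vectorised biallelic reduction of a whole table.

    Returns (keep, p, n): a per-site mask of reducible sites, the per-site
    per-pool alternate frequency and the biallelic depth.
    """
    nt = table.counts[:, :, :4]
    total = nt.sum(axis=1)                       # (sites, 4)
    order = np.argsort(-total, axis=1, kind="stable")
    major = order[:, 0]
    alt = order[:, 1]
    rows = np.arange(table.n_sites)
    alt_total = total[rows, alt]
    n_real = (total >= min_minor_count).sum(axis=1)
    keep = (alt_total > 0) & (n_real <= 2)

    maj_reads = nt[rows, :, major]
    alt_reads = nt[rows, :, alt]
    n = maj_reads + alt_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt_reads / np.maximum(n, 1), np.nan)
    return keep, p, n


def _pair_components(p, n, i, j, min_cov, max_cov):
    """Per-site Hudson components for pool pair (i, j); NaN where unusable."""
    ni, nj = n[:, i].astype(float), n[:, j].astype(float)
    usable = (ni >= max(min_cov, 2)) & (ni <= max_cov) & \
             (nj >= max(min_cov, 2)) & (nj <= max_cov)
    pi_, pj = p[:, i], p[:, j]
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (pi_ - pj) ** 2 \
            - pi_ * (1 - pi_) / np.maximum(ni - 1, 1) \
            - pj * (1 - pj) / np.maximum(nj - 1, 1)
        den = pi_ * (1 - pj) + pj * (1 - pi_)
    num = np.where(usable, num, np.nan)
    den = np.where(usable, den, np.nan)
    return num, den


def _window_ratio(chroms, pos, num, den, genome, window, step):
    """Ratio-of-averages over windows; returns (grid, fst, n_sites_used)."""
    w_chroms, w_starts, w_ends = window_grid(genome, window, step)
    fst = np.full(len(w_starts), np.nan)
    n_used = np.zeros(len(w_starts), dtype=np.int64)

    usable = np.isfinite(num) & np.isfinite(den) & (den > 0)
    for chrom in dict.fromkeys(c for c, _ in genome):
        sel = chroms == chrom
        if not sel.any():
            continue
        cpos = pos[sel]
        order = np.argsort(cpos, kind="stable")
        cpos = cpos[order]
        u = usable[sel][order]
        cnum = np.where(u, np.nan_to_num(num[sel][order]), 0.0)
        cden = np.where(u, np.nan_to_num(den[sel][order]), 0.0)
        cum_n = np.concatenate([[0.0], np.cumsum(cnum)])
        cum_d = np.concatenate([[0.0], np.cumsum(cden)])
        cum_u = np.concatenate([[0], np.cumsum(u.astype(np.int64))])

        wsel = np.flatnonzero(w_chroms == chrom)
        lo = np.searchsorted(cpos, w_starts[wsel], side="left")
        hi = np.searchsorted(cpos, w_ends[wsel], side="left")
        used = cum_u[hi] - cum_u[lo]
        dsum = cum_d[hi] - cum_d[lo]
        nsum = cum_n[hi] - cum_n[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where((used > 0) & (dsum > 0),
                             nsum / np.where(dsum > 0, dsum, 1.0), np.nan)
        fst[wsel] = np.clip(ratio, 0.0, FST_CAP)
        n_used[wsel] = used
    return (w_chroms, w_starts, w_ends), fst, n_used


def window_fst(table: SyncTable, pair: tuple[str, str],
               genome: Sequence[tuple[str, int]],
               window: int = 5000, step: int = 4000,
               min_cov: int = 4, max_cov: int = 16,
               min_minor_count: int = 2, min_sites: int = 1) -> WindowStatTrack:
    """Windowed Hudson FST between two pools.

    Default windows are 5 kb advancing by 4 kb, i.e. consecutive windows
    share 1 kb.  Sites enter a window only when both pools' biallelic depths
    lie within [min_cov, max_cov].  Values are clamped into [0, 1 - 1e-6];
    windows with fewer than ``min_sites`` usable sites are NaN (a higher
    value suppresses the heavy ratio noise of near-empty windows).
    """
    i = table.pool_index(pair[0])
    j = table.pool_index(pair[1])
    keep, p, n = _reduce_table(table, min_minor_count)
    num, den = _pair_components(p, n, i, j, min_cov, max_cov)
    num = np.where(keep, num, np.nan)
    den = np.where(keep, den, np.nan)
    (w_chroms, w_starts, w_ends), fst, n_used = _window_ratio(
        table.chroms, table.pos, num, den, genome, window, step)
    if min_sites > 1:
        fst = np.where(n_used >= min_sites, fst, np.nan)
    return WindowStatTrack(w_chroms, w_starts, w_ends, fst,
                           n_snps=n_used, n_covered=n_used, name="fst")


def pbs_from_fst(fst_ab, fst_ac, fst_bc):
    """PBS of the focal branch from the three pairwise FST values/arrays."""
    t_ab = branch_length(fst_ab)
    t_ac = branch_length(fst_ac)
    t_bc = branch_length(fst_bc)
    return (t_ab + t_ac - t_bc) / 2.0


def pbs_scan(table: SyncTable, triplet: tuple[str, str, str],
             genome: Sequence[tuple[str, int]],
             window: int = 5000, step: int = 4000,
             min_cov: int = 4, max_cov: int = 16,
             min_minor_count: int = 2, min_sites: int = 1) -> TripletPbsTrack:
    """Genome-wide focal-branch PBS for one population triplet.

    ``triplet`` is ordered (focal, pop2, pop3).  The three pairwise FST
    tracks are computed on a shared window grid; PBS is missing wherever any
    component FST is missing (including windows failing ``min_sites``).
    """
    a, b, c = triplet
    for name in triplet:
        table.pool_index(name)  # raises KeyError for unknown populations

    keep, p, n = _reduce_table(table, min_minor_count)
    tracks = {}
    for pair in ((a, b), (a, c), (b, c)):
        i, j = table.pool_index(pair[0]), table.pool_index(pair[1])
        num, den = _pair_components(p, n, i, j, min_cov, max_cov)
        num = np.where(keep, num, np.nan)
        den = np.where(keep, den, np.nan)
        grid, fst, n_used = _window_ratio(table.chroms, table.pos, num, den,
                                          genome, window, step)
        if min_sites > 1:
            fst = np.where(n_used >= min_sites, fst, np.nan)
        tracks[pair] = fst
    w_chroms, w_starts, w_ends = grid
    t_ab = branch_length(tracks[(a, b)])
    t_ac = branch_length(tracks[(a, c)])
    t_bc = branch_length(tracks[(b, c)])
    pbs = (t_ab + t_ac - t_bc) / 2.0
    return TripletPbsTrack(tuple(triplet), w_chroms, w_starts, w_ends,
                           t_ab, t_ac, t_bc, pbs)
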