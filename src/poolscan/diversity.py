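"""Coverage normalisation and windowed pooled nucleotide diversity (pi).

Pool-seq depth is heterogeneous, and excess depth usually flags collapsed
repeats or mapping artefacts, so per-pool coverage is bounded before any
diversity estimate: sites below ``min_cov`` or above a ceiling of 1.5x the
modal depth ("mode plus half the mode") are dropped, and sites can optionally
be subsampled without replacement to a uniform target depth.

Per-site diversity is the sample heterozygosity with the small-depth
correction,

    pi_site = C / (C - 1) * (1 - sum_a p_a^2),

with C the nucleotide depth and p_a the read frequency of base a.  A site
whose minor-read count falls below ``min_minor_count`` is treated as
monomorphic (pi = 0) — singleton reads at these depths are more often
sequencing error than polymorphism.  Window pi is the sum of per-site values
divided by the number of *covered* sites in the window, so masked or
low-coverage stretches do not deflate the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SyncTable


@dataclass
class CoverageFilter:
    """Per-pool coverage and minor-allele filters for diversity estimates."""

    min_cov: int = 4
    max_cov_rule: str = "mode_plus_half"   # or "fixed"
    max_cov: int | None = None             # used when max_cov_rule == "fixed"
    min_minor_count: int = 2

    def __post_init__(self):
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if self.max_cov_rule not in ("mode_plus_half", "fixed"):
            raise ValueError(f"unknown max_cov_rule {self.max_cov_rule!r}")
        if self.max_cov_rule == "fixed" and self.max_cov is None:
            raise ValueError("fixed rule needs max_cov")

    def ceiling(self, depths) -> int:
        if self.max_cov_rule == "fixed":
            return int(self.max_cov)
        return coverage_ceiling(depths)


@dataclass
class WindowStatTrack:
    """Per-window statistic with SNP and coverage bookkeeping.

    ``value`` is NaN (missing), not zero, where no covered site fell in the
    window.  Coordinates are 0-based half-open internally.
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    value: np.ndarray
    n_snps: np.ndarray
    n_covered: np.ndarray
    name: str = "value"

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chroms,
            "start": self.starts + 1,   # 1-based inclusive on output
            "end": self.ends,
            self.name: self.value,
            "n_snps": self.n_snps,
            "n_covered": self.n_covered,
        })


def window_grid(genome: Sequence[tuple[str, int]], window: int, step: int):
    """Window starts/ends over a genome; full windows only, except that a
    chromosome shorter than ``window`` gets a single truncated window."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    chroms, starts, ends = [], [], []
    for chrom, length in genome:
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        if length < window:
            s = np.array([0], dtype=np.int64)
            e = np.array([length], dtype=np.int64)
        else:
            s = np.arange(0, length - window + 1, step, dtype=np.int64)
            e = s + window
        chroms.extend([chrom] * len(s))
        starts.append(s)
        ends.append(e)
    return (np.array(chroms, dtype=object),
            np.concatenate(starts) if starts else np.empty(0, dtype=np.int64),
            np.concatenate(ends) if ends else np.empty(0, dtype=np.int64))


def coverage_ceiling(depths) -> int:
    """Maximum usable depth: floor(1.5 * modal depth), mode ties broken low."""
    depths = np.asarray(depths, dtype=np.int64)
    if depths.size == 0:
        raise ValueError("empty depth collection")
    freq = np.bincount(depths)
    mode = int(np.argmax(freq))  # argmax returns the first (smallest) maximiser
    return (3 * mode) // 2


def subsample_counts(counts, target_depth: int, rng) -> tuple[int, ...] | None:
    """Hypergeometric subsample of a site's nucleotide reads to a uniform depth.

    Draws ``target_depth`` reads without replacement from the site's A/T/C/G
    reads; N and del columns pass through untouched.  Returns ``None`` when
    the site has too few reads (the caller marks it unusable).
    """
    counts = tuple(int(c) for c in counts)
    nt = counts[:4]
    total = sum(nt)
    if total < target_depth:
        return None
    if total == target_depth:
        return counts
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    drawn = rng.multivariate_hypergeometric(nt, target_depth)
    return tuple(int(d) for d in drawn) + counts[4:]


def site_pi(counts, filt: CoverageFilter = CoverageFilter(),
            max_depth: int | None = None) -> float:
    """Heterozygosity-based diversity of one pool at one site.

    Returns NaN when the site fails the coverage bounds; returns 0.0 when the
    minor-read filter demotes the site to monomorphic.  ``max_depth``
    overrides the filter's ceiling (callers that computed a modal ceiling
    from the whole region pass it here).
    """
    nt = np.asarray(counts, dtype=np.int64)[:4]
    C = int(nt.sum())
    ceiling = max_depth if max_depth is not None else (
        filt.max_cov if filt.max_cov_rule == "fixed" else None)
    if C < filt.min_cov or (ceiling is not None and C > ceiling):
        return float("nan")
    minor = C - int(nt.max())
    if 0 < minor < filt.min_minor_count:
        return 0.0
    p = nt / C
    return float(C / (C - 1) * (1.0 - np.sum(p * p)))


def _site_pi_vector(nt_counts: np.ndarray, filt: CoverageFilter,
                    ceiling: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`site_pi`; returns (pi, usable_mask)."""
    C = nt_counts.sum(axis=1)
    usable = (C >= filt.min_cov) & (C <= ceiling)
    minor = C - nt_counts.max(axis=1)
    demote = (minor > 0) & (minor < filt.min_minor_count)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = nt_counts / C[:, None]
        pi = C / (C - 1.0) * (1.0 - np.sum(p * p, axis=1))
    pi = np.where(demote, 0.0, pi)
    pi = np.where(usable, pi, np.nan)
    return pi, usable


def window_pi(table: SyncTable, pool, genome: Sequence[tuple[str, int]],
              window: int = 5000, step: int = 5000,
              filt: CoverageFilter = CoverageFilter(),
              subsample_to: int | None = None,
              seed: int | None = None) -> WindowStatTrack:
    """Windowed nucleotide diversity of one pool.

    The coverage ceiling under the ``mode_plus_half`` rule is computed from
    the pool's depth distribution over all sites in ``table``.  With
    ``subsample_to`` set, every usable site is first subsampled to that
    uniform depth (sites below it become unusable), mirroring the common
    normalisation protocol for pooled libraries.
    """
    pool_idx = table.pool_index(pool) if isinstance(pool, str) else int(pool)
    nt = table.counts[:, pool_idx, :4]
    depths = nt.sum(axis=1)
    ceiling = filt.ceiling(depths[depths > 0]) if depths.any() else filt.min_cov

    if subsample_to is not None:
        rng = np.random.default_rng(seed)
        nt = nt.copy()
        ok = (depths >= subsample_to) & (depths <= ceiling)
        for i in np.flatnonzero(ok & (depths != subsample_to)):
            nt[i] = rng.multivariate_hypergeometric(nt[i], subsample_to)
        nt[~ok] = 0  # unusable after normalisation

    pi, usable = _site_pi_vector(nt, filt, ceiling)
    snp = usable & (pi > 0)

    w_chroms, w_starts, w_ends = window_grid(genome, window, step)
    value = np.full(len(w_starts), np.nan)
    n_snps = np.zeros(len(w_starts), dtype=np.int64)
    n_covered = np.zeros(len(w_starts), dtype=np.int64)

    for chrom in dict.fromkeys(c for c, _ in genome):
        sel = table.chroms == chrom
        if not sel.any():
            continue
        pos = table.pos[sel]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        pi_c = np.nan_to_num(pi[sel][order], nan=0.0)
        usable_c = usable[sel][order].astype(np.int64)
        snp_c = snp[sel][order].astype(np.int64)
        cum_pi = np.concatenate([[0.0], np.cumsum(pi_c * usable_c)])
        cum_cov = np.concatenate([[0], np.cumsum(usable_c)])
        cum_snp = np.concatenate([[0], np.cumsum(snp_c)])

        wsel = np.flatnonzero(w_chroms == chrom)
        lo = np.searchsorted(pos, w_starts[wsel], side="left")
        hi = np.searchsorted(pos, w_ends[wsel], side="left")
        cov = cum_cov[hi] - cum_cov[lo]
        s = cum_pi[hi] - cum_pi[lo]
        n_covered[wsel] = cov
        n_snps[wsel] = cum_snp[hi] - cum_snp[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            value[wsel] = np.where(cov > 0, s / np.maximum(cov, 1), np.nan)

    return WindowStatTrack(w_chroms, w_starts, w_ends, value, n_snps,
                           n_covered, name="pi")
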