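import io

import numpy as np
import pytest

from poolscan.io import SyncTable, read_sync
from poolscan.simulate import SimConfig, Sweep


def table_from_text(text: str, pools=None) -> SyncTable:
    return read_sync(io.StringIO(text), pools=pools)


@pytest.fixture
def two_pool_table() -> SyncTable:
    text = (
        "chr1\t5\tA\t10:0:0:0:0:0\t8:2:0:0:0:0\n"
        "chr1\t50\tA\t5:5:0:0:0:0\t10:0:0:0:0:0\n"
        "chr1\t120\tT\t0:10:0:0:0:0\t0:4:6:0:0:0\n"
    )
    return table_from_text(text, pools=["p1", "p2"])


@pytest.fixture
def small_sim_config() -> SimConfig:
    return SimConfig(
        pop_names=("focal", "east", "west"),
        focal_pop="focal",
        genome=[("chr1", 200_000), ("chr2", 100_000)],
        n_snps=1500,
        baseline_F=0.05,
        sweeps=[Sweep("chr1", 50_000, 75_000, 0.6)],
        pool_diploids=8,
        depth_mean=20.0,
        depth_shape=5.0,
        seed=42,
    )


def hudson_components_bruteforce(counts_site, i, j, min_minor_count=2,
                                 min_cov=4, max_cov=1_000_000):
    """Independent per-site Hudson components from raw count tuples.

    Slow, explicit re-derivation used as the oracle for the vectorised path:
    picks the two most frequent nucleotides summed over pools, computes read
    frequencies and the Hudson numerator/denominator from first principles.
    Returns None when the site must be skipped.
    """
    nt = [[int(c) for c in pool[:4]] for pool in counts_site]
    totals = [sum(pool[a] for pool in nt) for a in range(4)]
    order = sorted(range(4), key=lambda a: (-totals[a], a))
    major, alt = order[0], order[1]
    if totals[alt] == 0:
        return None
    if sum(1 for t in totals if t >= min_minor_count) > 2:
        return None
    ni = nt[i][major] + nt[i][alt]
    nj = nt[j][major] + nt[j][alt]
    if ni < max(min_cov, 2) or nj < max(min_cov, 2):
        return None
    if ni > max_cov or nj > max_cov:
        return None
    pi = nt[i][alt] / ni
    pj = nt[j][alt] / nj
    num = (pi - pj) ** 2 - pi * (1 - pi) / (ni - 1) - pj * (1 - pj) / (nj - 1)
    den = pi * (1 - pj) + pj * (1 - pi)
    if den <= 0:
        return None
    return num, den


def random_count_table(rng, n_sites=100, n_pools=2, chrom="chr1",
                       span=5000) -> SyncTable:
    """A random biallelic-ish sync table for oracle comparisons."""
    pos = np.sort(rng.choice(span, size=n_sites, replace=False))
    counts = np.zeros((n_sites, n_pools, 6), dtype=np.int64)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    for s in range(n_sites):
        for p in range(n_pools):
            depth = rng.integers(4, 30)
            alt = rng.binomial(depth, rng.uniform(0, 1))
            counts[s, p, ref_idx[s]] += depth - alt
            counts[s, p, alt_idx[s]] += alt
    ref = np.array(["ATCG"[k] for k in ref_idx], dtype=object)
    chroms = np.array([chrom] * n_sites, dtype=object)
    return SyncTable(chroms, pos, ref, counts, pools=[f"p{k}" for k in range(n_pools)])
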