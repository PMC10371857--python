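"""Empirical-outlier selection scan: thresholds, triplet consensus, genes.

A window is an outlier in a triplet when its focal-branch PBS lies strictly
above the top ``top_fraction`` (default 0.1%) nearest-rank quantile of that
triplet's own genome-wide PBS distribution.  Strict inequality makes tie
handling deterministic and guarantees the flagged fraction never exceeds
``top_fraction``.  A window becomes part of a selection locus when it is an
outlier in at least ``min_support`` of the triplets sharing the focal
population; overlapping or book-ended selected windows merge into one locus.
Genes are associated to a locus when their interval intersects the locus
extended by ``flank_bp`` (default 50 kb) on each side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .differentiation import TripletPbsTrack
from .io import GeneFeature


@dataclass
class ScanConfig:
    """Parameters of the outlier scan and consensus call."""

    triplets: Sequence[tuple[str, str, str]]
    top_fraction: float = 0.001
    min_support: int = 2
    flank_bp: int = 50_000

    def __post_init__(self):
        if not 0.0 < self.top_fraction < 1.0:
            raise ValueError("top_fraction must lie in (0, 1)")
        if not 1 <= self.min_support <= len(self.triplets):
            raise ValueError("min_support must lie in [1, number of triplets]")
        focals = {t[0] for t in self.triplets}
        if len(focals) != 1:
            raise ValueError(
                f"all triplets must share one focal population, got {sorted(focals)}"
            )

    @property
    def focal(self) -> str:
        return self.triplets[0][0]


@dataclass
class SelectionLocus:
    """A merged run of consensus outlier windows."""

    chrom: str
    start: int
    end: int
    supporting_triplets: tuple[tuple[str, str, str], ...]
    peak_pbs: float
    window_ids: tuple[int, ...]
    genes: tuple[str, ...] = ()

    @property
    def n_windows(self) -> int:
        return len(self.window_ids)


def loci_to_frame(loci: Sequence[SelectionLocus]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [l.chrom for l in loci],
        "start": [l.start + 1 for l in loci],
        "end": [l.end for l in loci],
        "n_windows": [l.n_windows for l in loci],
        "support": [len(l.supporting_triplets) for l in loci],
        "supporting_triplets": [
            ";".join("-".join(t) for t in l.supporting_triplets) for l in loci
        ],
        "peak_pbs": [l.peak_pbs for l in loci],
        "genes": [";".join(l.genes) for l in loci],
    })


class _LociFrame:
    """Adapter giving a list of loci the ``to_frame`` protocol of tracks."""

    def __init__(self, loci):
        self.loci = list(loci)

    def to_frame(self):
        return loci_to_frame(self.loci)


def empirical_threshold(values, top_fraction: float = 0.001) -> float:
    """Nearest-rank (1 - top_fraction) quantile of the finite values.

    Windows with a value *strictly greater* than this threshold are outliers;
    under ties this guarantees at most a ``top_fraction`` share is flagged.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0, 1)")
    arr = np.asarray(values, dtype=float)
    finite = np.sort(arr[np.isfinite(arr)])
    n = len(finite)
    if n == 0:
        raise ValueError("no finite values to threshold")
    if n < 1.0 / top_fraction:
        warnings.warn(
            f"only {n} finite values for a top-{top_fraction:g} threshold; "
            "the empirical quantile is poorly resolved",
            stacklevel=2,
        )
    # nearest rank h = ceil(q n); the epsilon guards ceil against the float
    # representation of q n landing infinitesimally above an integer
    h = math.ceil((1.0 - top_fraction) * n - 1e-9)
    h = min(max(h, 1), n)
    return float(finite[h - 1])


def outlier_mask(values, threshold: float) -> np.ndarray:
    """Boolean mask of finite values strictly above the threshold."""
    arr = np.asarray(values, dtype=float)
    return np.isfinite(arr) & (arr > threshold)


def triplet_combinations(focal: str, others: Sequence[str]):
    """All (focal, x, y) triplets over unordered pairs of the other pools."""
    return [(focal, x, y) for x, y in combinations(others, 2)]


def consensus_loci(tracks: Sequence[TripletPbsTrack],
                   cfg: ScanConfig) -> list[SelectionLocus]:
    """Call selection loci from per-triplet PBS tracks.

    Each track is thresholded against its own genome-wide distribution;
    windows that are outliers in at least ``cfg.min_support`` triplets are
    selected and merged (overlapping or book-ended) into loci.  All tracks
    must share one window grid.
    """
    if len(tracks) != len(cfg.triplets):
        raise ValueError("one track per configured triplet required")
    for track, trip in zip(tracks, cfg.triplets):
        if tuple(track.triplet) != tuple(trip):
            raise ValueError(f"track order mismatch: {track.triplet} vs {trip}")
    ref = tracks[0]
    for track in tracks[1:]:
        if not (np.array_equal(track.starts, ref.starts)
                and np.array_equal(track.chroms, ref.chroms)):
            raise ValueError("tracks are not on a shared window grid")

    masks = []
    for track in tracks:
        thr = empirical_threshold(track.pbs, cfg.top_fraction)
        masks.append(outlier_mask(track.pbs, thr))
    support = np.sum(masks, axis=0)
    selected = np.flatnonzero(support >= cfg.min_support)

    loci: list[SelectionLocus] = []
    current: list[int] = []

    def flush():
        if not current:
            return
        idx = np.array(current)
        trips = tuple(
            tuple(cfg.triplets[k]) for k in range(len(tracks))
            if masks[k][idx].any()
        )
        peak = max(
            float(tracks[k].pbs[i])
            for k in range(len(tracks)) for i in idx if masks[k][i]
        )
        loci.append(SelectionLocus(
            chrom=str(ref.chroms[idx[0]]),
            start=int(ref.starts[idx[0]]),
            end=int(ref.ends[idx].max()),
            supporting_triplets=trips,
            peak_pbs=peak,
            window_ids=tuple(int(i) for i in idx),
        ))

    last_end = None
    for i in selected:
        if current and str(ref.chroms[i]) == str(ref.chroms[current[0]]) \
                and ref.starts[i] <= last_end:
            current.append(int(i))
            last_end = max(last_end, int(ref.ends[i]))
        else:
            flush()
            current = [int(i)]
            last_end = int(ref.ends[i])
    flush()
    return loci


def associate_genes(loci: Sequence[SelectionLocus],
                    features: Sequence[GeneFeature],
                    flank_bp: int = 50_000) -> list[SelectionLocus]:
    """Attach genes whose interval intersects each locus +/- ``flank_bp``.

    Intervals are half-open, so a gene starting exactly at ``end + flank``
    does not associate.  Returns new loci with the ``genes`` field filled;
    a gene may support several loci but appears once per locus.
    """
    by_chrom: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    out = []
    for locus in loci:
        lo = locus.start - flank_bp
        hi = locus.end + flank_bp
        hits = sorted(
            f.gene_id for f in by_chrom.get(locus.chrom, ())
            if f.start < hi and lo < f.end
        )
        out.append(SelectionLocus(
            locus.chrom, locus.start, locus.end, locus.supporting_triplets,
            locus.peak_pbs, locus.window_ids, genes=tuple(hits),
        ))
    return out


def read_loci(source) -> list[SelectionLocus]:
    """Read a loci TSV written by :func:`poolscan.io.write_results` back in."""
    df = pd.read_csv(source, sep="\t")
    loci = []
    for _, row in df.iterrows():
        trips = tuple(
            tuple(t.split("-")) for t in str(row.get("supporting_triplets", "")).split(";")
            if t and t != "nan"
        )
        genes = tuple(
            g for g in str(row.get("genes", "")).split(";") if g and g != "nan"
        )
        loci.append(SelectionLocus(
            chrom=str(row["chrom"]),
            start=int(row["start"]) - 1,
            end=int(row["end"]),
            supporting_triplets=trips,
            peak_pbs=float(row.get("peak_pbs", np.nan)),
            window_ids=(),
            genes=genes,
        ))
    return loci


def selected_gene_set(loci: Sequence[SelectionLocus]) -> set[str]:
    """The genome-wide set of genes under selection (each counted once)."""
    genes: set[str] = set()
    for locus in loci:
        genes.update(locus.genes)
    return genes


def intersect_gene_sets(named_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Counts for every region of the Venn partition over the given sets.

    One row per non-empty membership pattern (2^k - 1 rows for k sets), with
    boolean membership columns and the count of genes falling exactly in
    that region.
    """
    names = list(named_sets)
    sets = {name: set(named_sets[name]) for name in names}
    universe = set().union(*sets.values()) if sets else set()
    rows = []
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            inside = set(universe)
            for m in members:
                inside &= sets[m]
            for other in names:
                if other not in members:
                    inside -= sets[other]
            rows.append({**{n: n in members for n in names},
                         "count": len(inside)})
    return pd.DataFrame(rows)
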