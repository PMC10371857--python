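"""Screening of non-synonymous variants inside selection loci.

For each candidate substitution the focal population's allele frequency is
contrasted with the mean over the comparison populations (dAF), the read
counts are tested with a two-sided Fisher's exact test (focal alt/ref versus
the pooled alt/ref of the others) with Benjamini-Hochberg correction across
the screened set, and the substitution is classified as deleterious when

    PROVEAN < -2.5   or   SIFT < 0.05,

a missing score simply dropping its disjunct (PROVEAN alone decides when the
SIFT predictor could not be run, and vice versa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .differentiation import biallelic_reduce
from .io import SyncTable
from .scan import SelectionLocus


@dataclass
class DeleteriousnessRule:
    """Effect-score thresholds below which a substitution is deleterious."""

    provean_cutoff: float = -2.5
    sift_cutoff: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.sift_cutoff < 1.0:
            raise ValueError("sift_cutoff must lie in (0, 1)")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def classify_deleterious(provean, sift,
                         rule: DeleteriousnessRule = DeleteriousnessRule()) -> bool:
    """Apply the PROVEAN/SIFT disjunction; at least one score required."""
    if _missing(provean) and _missing(sift):
        raise ValueError("both effect scores missing")
    hit = False
    if not _missing(provean):
        hit = hit or provean < rule.provean_cutoff
    if not _missing(sift):
        hit = hit or sift < rule.sift_cutoff
    return bool(hit)


def delta_af(af_focal: float, af_others: Sequence[float]) -> float:
    """Focal allele frequency minus the mean over the other populations."""
    others = np.asarray(af_others, dtype=float)
    if others.size == 0:
        raise ValueError("need at least one comparison population")
    return float(af_focal - others.mean())


def fisher_exact_af(alt_focal: int, ref_focal: int,
                    alt_others: int, ref_others: int) -> float:
    """Two-sided Fisher's exact p for the focal-vs-pooled-others 2x2 table.

    Returns NaN for an all-zero table (no reads on either side).
    """
    table = np.array([[alt_focal, ref_focal], [alt_others, ref_others]])
    if table.sum() == 0:
        return float("nan")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs propagate unadjusted."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def af_contrast(table: SyncTable, variants: pd.DataFrame,
                focal: str, others: Sequence[str],
                min_minor_count: int = 2) -> pd.DataFrame:
    """Allele-frequency contrast of listed variant sites.

    ``variants`` needs columns ``chrom`` and ``pos`` (1-based, as in the
    annotation files) plus any identifying columns, which are carried
    through.  Adds per-population allele frequencies, ``d_af``, the Fisher
    p-value of the pooled read-count contrast, and its BH adjustment across
    the whole screened set.
    """
    fi = table.pool_index(focal)
    oi = [table.pool_index(o) for o in others]
    site_index = {(str(c), int(p)): k
                  for k, (c, p) in enumerate(zip(table.chroms, table.pos))}

    rows = []
    for _, var in variants.iterrows():
        key = (str(var["chrom"]), int(var["pos"]) - 1)
        rec = dict(var)
        k = site_index.get(key)
        if k is None:
            warnings.warn(f"variant {key[0]}:{var['pos']} absent from sync table",
                          stacklevel=2)
            rec.update(af_focal=np.nan, d_af=np.nan, p_value=np.nan,
                       **{f"af_{o}": np.nan for o in others})
            rows.append(rec)
            continue
        reduced = biallelic_reduce(table.counts[k], min_minor_count)
        if reduced is None:
            rec.update(af_focal=np.nan, d_af=np.nan, p_value=np.nan,
                       **{f"af_{o}": np.nan for o in others})
            rows.append(rec)
            continue
        p, n = reduced
        alt_reads = np.round(p * n).astype(int)
        ref_reads = n - alt_reads
        rec["af_focal"] = p[fi]
        for o, idx in zip(others, oi):
            rec[f"af_{o}"] = p[idx]
        af_others = [p[idx] for idx in oi]
        rec["d_af"] = delta_af(p[fi], af_others) if np.isfinite(p[fi]) \
            and np.all(np.isfinite(af_others)) else np.nan
        rec["p_value"] = fisher_exact_af(
            int(alt_reads[fi]), int(ref_reads[fi]),
            int(alt_reads[oi].sum()), int(ref_reads[oi].sum()))
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_value"]) if len(out) else pd.Series(dtype=float)
    return out


def _in_locus(chrom, pos0, loci: Sequence[SelectionLocus]) -> bool:
    return any(l.chrom == chrom and l.start <= pos0 < l.end for l in loci)


def screen_candidates(contrasts: pd.DataFrame,
                      loci: Sequence[SelectionLocus],
                      effects: pd.DataFrame | None = None,
                      rule: DeleteriousnessRule = DeleteriousnessRule(),
                      daf_floor: float = 0.5,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Compile the candidate table of focal-specific deleterious substitutions.

    Keeps variants that (i) fall inside a selection locus, (ii) have a
    significant adjusted AF contrast (``p_adjusted < alpha``), and (iii) show
    ``|d_af| >= daf_floor``.  Effect scores are joined on
    (gene_id, position, ref_aa, alt_aa); unmatched variants are kept with
    missing scores and a warning.  Output is sorted by |d_af| descending.
    """
    if contrasts.empty:
        return contrasts.assign(provean=pd.Series(dtype=float),
                                sift=pd.Series(dtype=float),
                                deleterious=pd.Series(dtype=object))
    df = contrasts.copy()
    keep = df.apply(
        lambda r: _in_locus(str(r["chrom"]), int(r["pos"]) - 1, loci), axis=1)
    df = df[keep]
    df = df[(df["p_adjusted"] < alpha) & (df["d_af"].abs() >= daf_floor)]

    key = ["gene_id", "position", "ref_aa", "alt_aa"]
    if effects is not None and not df.empty:
        df = df.merge(effects[key + ["provean", "sift"]], on=key, how="left")
        unmatched = df["provean"].isna() & df["sift"].isna()
        if unmatched.any():
            warnings.warn(
                f"{int(unmatched.sum())} screened variants without effect scores",
                stacklevel=2,
            )
    else:
        df["provean"] = np.nan
        df["sift"] = np.nan

    def _call(row):
        if _missing(row["provean"]) and _missing(row["sift"]):
            return pd.NA
        return classify_deleterious(row["provean"], row["sift"], rule)

    df["deleterious"] = df.apply(_call, axis=1) if len(df) else pd.Series(dtype=object)
    return df.sort_values("d_af", key=lambda s: s.abs(),
                          ascending=False).reset_index(drop=True)
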