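"""Best-hit gene families and the duplicated-gene proportion P_D.

Genes are clustered by their best protein hit against a reference proteome
(classically the fly): every query gene whose top hit is the same reference
gene belongs to the same family.  The duplicated-gene proportion of a
species is then

    P_D = (# genes in families of size >= 2) / (# clustered genes),

a simple genome-quality-robust summary of how much of the gene complement is
duplicated.  Family-size matrices across species are emitted in the
tab-separated layout expected by gene-family birth-death tools (CAFE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io import _open_text


@dataclass
class FamilyTable:
    """Best-hit gene families of one species."""

    species: str
    families: dict[str, list[str]]       # reference gene -> member genes
    n_unassigned: int = 0                # genes without any hit

    @property
    def n_genes(self) -> int:
        return sum(len(m) for m in self.families.values())


def read_best_hits(source, fmt: str = "besthit") -> pd.DataFrame:
    """Read a best-hit table.

    ``besthit``: TSV with header ``gene_id  ref_gene  score  ref_length``
    (missing ref_gene marks a no-hit gene).  ``blast6``: headerless BLAST
    ``-outfmt 6`` (qseqid sseqid ... bitscore); the alignment length column
    serves as the tie-break length.
    """
    if fmt == "besthit":
        df = pd.read_csv(source, sep="\t", dtype={"gene_id": str, "ref_gene": str})
        required = {"gene_id", "ref_gene", "score", "ref_length"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"best-hit table missing columns {sorted(missing)}")
        return df
    if fmt == "blast6":
        cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
        raw = pd.read_csv(source, sep="\t", header=None, names=cols)
        return pd.DataFrame({
            "gene_id": raw["qseqid"].astype(str),
            "ref_gene": raw["sseqid"].astype(str),
            "score": raw["bitscore"],
            "ref_length": raw["length"],
        })
    raise ValueError(f"unknown best-hit format {fmt!r}")


def build_families(best_hits: pd.DataFrame, species: str = "sample") -> FamilyTable:
    """Cluster genes by best reference hit.

    Multiple hits per gene are reduced to the top score; equal scores fall
    back to the longer reference sequence, then to the lexicographically
    smallest reference id for determinism.  Genes whose ``ref_gene`` is
    missing are excluded from the families and counted in ``n_unassigned``.
    Duplicate (gene, reference) best hits after reduction raise.
    """
    df = best_hits.copy()
    no_hit = df["ref_gene"].isna()
    n_unassigned = int(df.loc[no_hit, "gene_id"].nunique())
    df = df[~no_hit]

    if df["gene_id"].duplicated().any():
        df = (df.sort_values(["score", "ref_length", "ref_gene"],
                             ascending=[False, False, True], kind="stable")
                .drop_duplicates("gene_id", keep="first"))
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
        raise ValueError(f"duplicate gene ids {list(dupes)[:5]}")

    families: dict[str, list[str]] = {}
    for gene, ref in zip(df["gene_id"], df["ref_gene"]):
        families.setdefault(str(ref), []).append(str(gene))
    for members in families.values():
        members.sort()
    return FamilyTable(species=species, families=families,
                       n_unassigned=n_unassigned)


def proportion_duplicated(table: FamilyTable,
                          include_unassigned: bool = False) -> float:
    """P_D: share of genes sitting in families with two or more members.

    ``include_unassigned`` adds no-hit genes to the denominator (they can
    never be duplicated under best-hit clustering, so this lowers P_D).
    """
    denom = table.n_genes + (table.n_unassigned if include_unassigned else 0)
    if denom < 1:
        raise ValueError("empty family table")
    dup = sum(len(m) for m in table.families.values() if len(m) >= 2)
    return dup / denom


def family_size_matrix(tables: Sequence[FamilyTable]) -> pd.DataFrame:
    """Reference-family x species member-count matrix (0 where absent)."""
    if len(tables) < 2:
        raise ValueError("need at least two species")
    counts = {
        t.species: {ref: len(m) for ref, m in t.families.items()} for t in tables
    }
    df = pd.DataFrame(counts).fillna(0).astype(int)
    df.index.name = "family"
    return df.sort_index()


def write_cafe_matrix(matrix: pd.DataFrame, dest) -> None:
    """Emit the family-size matrix in CAFE's input layout.

    Columns: ``Desc``, ``Family ID``, then one count column per species.
    """
    out = matrix.reset_index().rename(columns={matrix.index.name or "index":
                                               "Family ID"})
    out.insert(0, "Desc", "(null)")
    stream, close = _open_text(dest, "wt")
    try:
        out.to_csv(stream, sep="\t", index=False)
    finally:
        if close:
            stream.close()


def read_cafe_matrix(source) -> pd.DataFrame:
    """Inverse of :func:`write_cafe_matrix`."""
    df = pd.read_csv(source, sep="\t")
    df = df.drop(columns=["Desc"]).set_index("Family ID")
    df.index.name = "family"
    return df.astype(int)
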