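"""Readers and writers for the pipeline's external formats.

The pipeline speaks four plain-text dialects:

* **sync** — the PoPoolation2 per-site count table: ``chrom  pos  ref`` followed
  by one ``A:T:C:G:N:del`` colon tuple per pool.  This is the universal input
  of every statistic in the package.
* **BED4+** and **GFF3** gene annotations (``gene`` features, ``ID`` attribute).
* result TSVs for window tracks and selection loci.

All genomic intervals are 0-based half-open internally; sync positions are
converted on read (``pos - 1``) and on write (``pos + 1``), and result TSVs
emit 1-based inclusive coordinates for human readability.  Gzipped input is
accepted transparently wherever a path is given.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: Column order of the six count fields in a sync tuple.
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")

#: Indices of the four true nucleotide columns (N and del are not alleles).
NUCLEOTIDE_SLICE = slice(0, 4)


class SyncFormatError(ValueError):
    """Malformed sync input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class AnnotationFormatError(ValueError):
    """Malformed BED/GFF3 annotation input."""


@dataclass(frozen=True)
class SyncRecord:
    """One genomic site of a sync table.

    ``pos`` is 0-based internally.  ``counts`` holds one six-tuple per pool in
    ``A, T, C, G, N, del`` order.
    """

    chrom: str
    pos: int
    ref: str
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        for tup in self.counts:
            if len(tup) != 6:
                raise ValueError("each pool needs exactly six count fields")
            if any(c < 0 for c in tup):
                raise ValueError("negative nucleotide count")


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval, stored 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.start < self.end:
            raise AnnotationFormatError(
                f"gene {self.gene_id}: empty or inverted interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationFormatError(f"bad strand {self.strand!r}")


class SyncTable:
    """Column-oriented container for a whole sync table.

    Attributes
    ----------
    pools : list of str
        Pool (population) names.  Synthesised as ``pool0..pool{k-1}`` when the
        source format carries none.
    chroms, pos, ref : ndarray
        Per-site sequence name, 0-based position and reference base.
    counts : ndarray of shape ``(n_sites, n_pools, 6)``
        Nucleotide counts in ``A, T, C, G, N, del`` order.
    """

    def __init__(self, chroms, pos, ref, counts, pools=None):
        self.chroms = np.asarray(chroms, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[2] != 6:
            raise ValueError("counts must have shape (n_sites, n_pools, 6)")
        if not (len(self.chroms) == len(self.pos) == len(self.ref) == self.counts.shape[0]):
            raise ValueError("column length mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        n_pools = self.counts.shape[1]
        self.pools = list(pools) if pools is not None else [f"pool{i}" for i in range(n_pools)]
        if len(self.pools) != n_pools:
            raise ValueError("pool name count does not match count columns")

    # -- basic protocol -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pools(self) -> int:
        return self.counts.shape[1]

    def __len__(self) -> int:
        return self.n_sites

    def __eq__(self, other) -> bool:
        if not isinstance(other, SyncTable):
            return NotImplemented
        return (
            self.pools == other.pools
            and np.array_equal(self.chroms, other.chroms)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.counts, other.counts)
        )

    def pool_index(self, name: str) -> int:
        try:
            return self.pools.index(name)
        except ValueError:
            raise KeyError(f"unknown population {name!r}; have {self.pools}") from None

    def records(self) -> Iterator[SyncRecord]:
        for i in range(self.n_sites):
            yield SyncRecord(
                chrom=str(self.chroms[i]),
                pos=int(self.pos[i]),
                ref=str(self.ref[i]),
                counts=tuple(tuple(int(c) for c in pool) for pool in self.counts[i]),
            )

    @classmethod
    def from_records(cls, records: Iterable[SyncRecord], pools=None) -> "SyncTable":
        records = list(records)
        n_pools = len(records[0].counts) if records else (len(pools) if pools else 0)
        chroms = [r.chrom for r in records]
        pos = [r.pos for r in records]
        ref = [r.ref for r in records]
        counts = np.array([r.counts for r in records], dtype=np.int64).reshape(
            len(records), n_pools, 6
        )
        return cls(chroms, pos, ref, counts, pools=pools)

    def subset(self, mask) -> "SyncTable":
        mask = np.asarray(mask)
        return SyncTable(
            self.chroms[mask], self.pos[mask], self.ref[mask], self.counts[mask],
            pools=self.pools,
        )


# ---------------------------------------------------------------------------
# stream plumbing
# ---------------------------------------------------------------------------

def _open_text(source, mode: str = "rt"):
    """Return (stream, should_close).  Paths ending in .gz are decompressed."""
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.suffix == ".gz":
            return gzip.open(p, mode), True
        return open(p, mode), True
    return source, False


# ---------------------------------------------------------------------------
# sync
# ---------------------------------------------------------------------------

def read_sync(source, pools: Sequence[str] | None = None) -> SyncTable:
    """Parse a sync table.

    Parameters
    ----------
    source : path or text stream
        Tab-separated lines ``chrom  pos  ref  A:T:C:G:N:del ...`` with one
        colon tuple per pool.  Positions are 1-based in the file.
    pools : optional
        Names for the pools, in column order.

    Raises
    ------
    SyncFormatError
        On a malformed count tuple or an inconsistent number of pools,
        naming the offending line.
    """
    stream, close = _open_text(source)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    counts: list[list[tuple[int, ...]]] = []
    n_pools: int | None = None
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncFormatError(
                    f"expected chrom, pos, ref and at least one pool, got "
                    f"{len(fields)} fields", lineno,
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise SyncFormatError(f"non-integer position {pos_s!r}", lineno)
            if pos < 1:
                raise SyncFormatError(f"position {pos} is not 1-based", lineno)
            site_counts = []
            for tup in fields[3:]:
                parts = tup.split(":")
                if len(parts) != 6:
                    raise SyncFormatError(
                        f"count tuple {tup!r} has {len(parts)} fields, expected 6",
                        lineno,
                    )
                try:
                    vals = tuple(int(x) for x in parts)
                except ValueError:
                    raise SyncFormatError(f"non-integer count in {tup!r}", lineno)
                if any(v < 0 for v in vals):
                    raise SyncFormatError(f"negative count in {tup!r}", lineno)
                site_counts.append(vals)
            if n_pools is None:
                n_pools = len(site_counts)
            elif len(site_counts) != n_pools:
                raise SyncFormatError(
                    f"{len(site_counts)} pools but previous lines had {n_pools}",
                    lineno,
                )
            chroms.append(chrom)
            positions.append(pos - 1)  # to 0-based
            refs.append(ref.upper())
            counts.append(site_counts)
    finally:
        if close:
            stream.close()

    if n_pools is None:
        n_pools = len(pools) if pools else 0
    arr = np.array(counts, dtype=np.int64).reshape(len(chroms), n_pools, 6)
    return SyncTable(chroms, positions, refs, arr, pools=pools)


def write_sync(table: SyncTable, dest) -> None:
    """Write ``table`` in sync format (positions back to 1-based)."""
    stream, close = _open_text(dest, "wt")
    try:
        for i in range(table.n_sites):
            tuples = "\t".join(
                ":".join(str(int(c)) for c in pool) for pool in table.counts[i]
            )
            stream.write(f"{table.chroms[i]}\t{int(table.pos[i]) + 1}\t{table.ref[i]}\t{tuples}\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_features(source, fmt: str | None = None,
                  gff_types: frozenset[str] = frozenset({"gene"})) -> list[GeneFeature]:
    """Read gene features from BED4+ or GFF3 into 0-based half-open intervals.

    ``fmt`` is ``"bed"`` or ``"gff3"``; when omitted it is inferred from the
    file extension.  BED input is taken as written (already half-open); GFF3
    start/end (1-based inclusive) are converted with ``start - 1``.
    Only features of type ``gene`` are kept from GFF3, identified by their
    ``ID`` attribute.
    """
    if fmt is None:
        if isinstance(source, (str, Path)):
            name = str(source)
            if name.endswith(".gz"):
                name = name[:-3]
            if name.endswith(".bed"):
                fmt = "bed"
            elif name.endswith((".gff", ".gff3")):
                fmt = "gff3"
        if fmt is None:
            raise AnnotationFormatError("cannot infer annotation format; pass fmt=")
    fmt = fmt.lower()
    if fmt not in ("bed", "gff3"):
        raise AnnotationFormatError(f"unknown annotation format {fmt!r}")

    stream, close = _open_text(source)
    features: list[GeneFeature] = []
    seen: set[str] = set()
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                if len(fields) < 4:
                    raise AnnotationFormatError(
                        f"line {lineno}: BED4+ needs at least 4 columns"
                    )
                chrom, start, end, gene_id = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5] if len(fields) >= 6 else "."
            else:
                if len(fields) < 9:
                    raise AnnotationFormatError(
                        f"line {lineno}: GFF3 needs 9 columns"
                    )
                if fields[2] not in gff_types:
                    continue
                chrom = fields[0]
                start = int(fields[3]) - 1  # 1-based inclusive -> half-open
                end = int(fields[4])
                strand = fields[6] if fields[6] in ("+", "-") else "."
                attrs = _parse_gff3_attributes(fields[8])
                gene_id = attrs.get("ID")
                if gene_id is None:
                    raise AnnotationFormatError(
                        f"line {lineno}: gene feature without ID attribute"
                    )
            if gene_id in seen:
                raise AnnotationFormatError(f"duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                features.append(GeneFeature(gene_id, chrom, start, end, strand))
            except AnnotationFormatError as exc:
                raise AnnotationFormatError(f"line {lineno}: {exc}") from None
    finally:
        if close:
            stream.close()
    return features


def write_features(features: Iterable[GeneFeature], dest, fmt: str = "bed") -> None:
    """Write features as BED4+6 or GFF3 (inverse of :func:`read_features`)."""
    fmt = fmt.lower()
    stream, close = _open_text(dest, "wt")
    try:
        if fmt == "bed":
            for f in features:
                stream.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.gene_id}\t0\t{f.strand}\n")
        elif fmt == "gff3":
            stream.write("##gff-version 3\n")
            for f in features:
                stream.write(
                    f"{f.chrom}\tpoolscan\tgene\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
                    f"ID={f.gene_id}\n"
                )
        else:
            raise AnnotationFormatError(f"unknown annotation format {fmt!r}")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(obj, dest) -> None:
    """Serialise a window track, a PBS track or selection loci as TSV.

    Dispatches on the object's ``to_frame`` method (all result containers in
    this package provide one).  Window coordinates are emitted 1-based
    inclusive; floats at full repr precision; missing values as ``NA``.
    """
    frame = obj.to_frame() if hasattr(obj, "to_frame") else obj
    if not isinstance(frame, pd.DataFrame):
        raise TypeError(f"cannot serialise {type(obj).__name__}")
    stream, close = _open_text(dest, "wt")
    try:
        frame.to_csv(stream, sep="\t", index=False, na_rep="NA")
    finally:
        if close:
            stream.close()
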