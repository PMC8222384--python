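"""Readers and writers for the file dialects the pipeline touches.

Coordinate conventions are strict: per-cytosine positions are 1-based
(the convention of bisulfite callers), interval files are 0-based
half-open (the BED standard).  A cytosine at 1-based position ``p``
overlaps a BED interval ``[s, e)`` iff ``s < p <= e``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

VALID_CONTEXTS = {"CpG", "CHG", "CHH", "CpH"}
FEATURE_CLASSES = {
    "cpg_island",
    "shore",
    "promoter",
    "enhancer",
    "super_enhancer",
    "exon",
    "intron",
    "intergenic",
}
BIOTYPES = {"protein_coding", "lncRNA", "ncRNA", "pseudogene", "other"}


class ParseError(ValueError):
    """A malformed line in an input file; message names the line number."""


class SchemaError(ValueError):
    """An input table does not have the required columns."""


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's methylated/unmethylated read counts in one sample."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str  # CpG, CHG, CHH or the collapsed CpH
    meth_count: int
    unmeth_count: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError("counts must be non-negative")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")

    @property
    def total(self) -> int:
        return self.meth_count + self.unmeth_count

    @property
    def meth_fraction(self) -> float:
        if self.total == 0:
            return float("nan")
        return self.meth_count / self.total


@dataclass(frozen=True)
class FeatureInterval:
    """A genomic interval, 0-based half-open, tagged with a feature class."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    feature_class: str
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")

    def contains_pos(self, pos: int) -> bool:
        """Whether a 1-based cytosine position falls inside this interval."""
        return self.start < pos <= self.end


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    gene_name: str
    chrom: str
    tss_pos: int  # 1-based
    strand: str
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.tss_pos < 1:
            raise ValueError(f"tss_pos must be >= 1, got {self.tss_pos}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    source: str = ""


def _normalize_context(raw: str, collapse_cph: bool) -> str:
    ctx = raw.strip()
    low = ctx.lower()
    if low == "cpg" or low == "cg":
        ctx = "CpG"
    elif low == "chg":
        ctx = "CHG"
    elif low == "chh":
        ctx = "CHH"
    elif low == "cph":
        ctx = "CpH"
    else:
        raise ValueError(f"unknown context {raw!r}")
    if collapse_cph and ctx in {"CHG", "CHH"}:
        ctx = "CpH"
    return ctx


def read_coverage_file(
    path: str | Path,
    context_filter: str | None = None,
    collapse_cph: bool = True,
) -> list[CytosineRecord]:
    """Read a per-sample cytosine count table.

    Tab-separated columns: chrom, pos, strand, context, meth_count,
    unmeth_count.  A header line is auto-detected (a line whose count
    columns do not parse as integers).  CHG/CHH contexts are collapsed
    to CpH when ``collapse_cph`` is set; ``context_filter`` (applied
    after collapsing) keeps only records of one context.
    """
    records: list[CytosineRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated input
                fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(fields)}"
                )
            if lineno == 1:
                try:
                    int(fields[1]), int(fields[4]), int(fields[5])
                except ValueError:
                    continue  # header line
            try:
                pos = int(fields[1])
                meth = int(fields[4])
                unmeth = int(fields[5])
                context = _normalize_context(fields[3], collapse_cph)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if meth < 0 or unmeth < 0:
                raise ParseError(
                    f"{path}: line {lineno}: negative count"
                )
            rec = CytosineRecord(
                chrom=fields[0],
                pos=pos,
                strand=fields[2],
                context=context,
                meth_count=meth,
                unmeth_count=unmeth,
            )
            if context_filter is None or rec.context == context_filter:
                records.append(rec)
    return records


def write_coverage_file(records: Iterable[CytosineRecord], path: str | Path) -> None:
    """Write records in the dialect :func:`read_coverage_file` consumes."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.context}\t"
                f"{r.meth_count}\t{r.unmeth_count}\n"
            )


def read_bed(path: str | Path, feature_class: str) -> list[FeatureInterval]:
    """Read a BED3/BED6 file, tagging every interval with ``feature_class``.

    Coordinates are taken verbatim (0-based half-open); no shifting.
    """
    intervals: list[FeatureInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: BED needs >= 3 columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            name = fields[3] if len(fields) >= 4 else None
            intervals.append(
                FeatureInterval(fields[0], start, end, feature_class, name)
            )
    return intervals


def write_bed(intervals: Iterable[FeatureInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


GENE_TABLE_COLUMNS = ["gene_id", "gene_name", "chrom", "tss_pos", "strand", "biotype"]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a TSV gene/TSS registry with named columns.

    Required columns: gene_id, gene_name, chrom, tss_pos, strand, biotype.
    Biotypes outside the closed vocabulary map to "other"; duplicated
    gene_ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise SchemaError(f"{path}: duplicated gene_id(s): {dups}")
    genes = []
    for row in df.itertuples(index=False):
        biotype = row.biotype if row.biotype in BIOTYPES else "other"
        genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                gene_name=row.gene_name,
                chrom=row.chrom,
                tss_pos=int(row.tss_pos),
                strand=row.strand,
                biotype=biotype,
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        (g.gene_id, g.gene_name, g.chrom, g.tss_pos, g.strand, g.biotype)
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT gene-set file: name, description, then member gene ids."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT needs name, description, members"
                )
            members = frozenset(m for m in fields[2:] if m)
            sets.append(GeneSet(name=fields[0], members=members, source=fields[1]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source, *sorted(s.members)]) + "\n")


DM_TABLE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "context",
    "meth_diff",
    "pvalue",
    "qvalue",
    "significant",
    "direction",
]


def write_dm_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write per-cytosine differential methylation results as TSV.

    ``results`` must carry the :data:`DM_TABLE_COLUMNS`; floats are
    written in full repr precision so the table round-trips losslessly.
    """
    missing = [c for c in DM_TABLE_COLUMNS if c not in results.columns]
    if missing:
        raise SchemaError(f"dm table missing columns {missing}")
    out = results[DM_TABLE_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.17g",
               quoting=csv.QUOTE_NONE)


def read_dm_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "context": str, "direction": str, "strand": str},
    )
    missing = [c for c in DM_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: dm table missing columns {missing}")
    df["significant"] = df["significant"].astype(bool)
    return df


def records_to_frame(records: Sequence[CytosineRecord]) -> pd.DataFrame:
    """Tabular view of a record list (one row per cytosine)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "strand": [r.strand for r in records],
            "context": [r.context for r in records],
            "meth_count": [r.meth_count for r in records],
            "unmeth_count": [r.unmeth_count for r in records],
        }
    )
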