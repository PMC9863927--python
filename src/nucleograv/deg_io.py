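"""Gene annotations and differential-expression result tables.

Reads GTF / BED gene annotations and DESeq2-style result tables (TSV with
``gene_id``, ``log2FoldChange``, ``pvalue``, ``padj`` columns), and classifies
genes as up- / downregulated / not significant under an FDR-adjusted p-value
threshold with an optional absolute log2 fold-change cutoff.

The package never re-runs differential-expression testing itself; it consumes
tables produced upstream.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "DEResultTable",
    "DEGStatusMap",
    "read_annotation",
    "write_annotation",
    "read_de_table",
    "write_de_table",
    "classify_degs",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: 0-based half-open genomic span plus biotype label."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


#: default DESeq2 column names; keys are the internal field names
DESEQ2_COLUMNS = {
    "gene_id": "gene_id",
    "base_mean": "baseMean",
    "log2fc": "log2FoldChange",
    "pvalue": "pvalue",
    "padj": "padj",
}


@dataclass
class DEResultTable:
    """Per-gene DE statistics for one comparison on one track.

    ``data`` holds columns gene_id, base_mean, log2fc, pvalue, padj; the
    universe of tested genes is the set of rows.
    """

    comparison: str
    track: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "log2fc", "padj"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"DE table missing columns: {missing}")
        if self.data["gene_id"].duplicated().any():
            dupes = self.data.loc[self.data["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids in DE table: {sorted(set(dupes))[:5]}")
        padj = self.data["padj"].dropna()
        if ((padj < 0) | (padj > 1)).any():
            raise ValueError("padj values outside [0, 1]")

    @property
    def universe(self) -> set[str]:
        return set(self.data["gene_id"])

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DEGStatusMap:
    """Partition of a tested-gene universe into up / down / ns."""

    comparison: str
    track: str
    status: dict[str, str] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s for s in self.status.values() if s not in ("up", "down", "ns")}
        if bad:
            raise ValueError(f"invalid DEG status labels: {bad}")

    @property
    def universe(self) -> set[str]:
        return set(self.status)

    def genes(self, label: str) -> set[str]:
        return {g for g, s in self.status.items() if s == label}

    @property
    def up(self) -> set[str]:
        return self.genes("up")

    @property
    def down(self) -> set[str]:
        return self.genes("down")

    @property
    def ns(self) -> set[str]:
        return self.genes("ns")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(path: Path) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "gene":
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            if "gene_id" not in attr:
                raise ValueError(f"{path}:{lineno}: gene feature without gene_id attribute")
            biotype = attr.get("gene_biotype", attr.get("gene_type", "protein_coding"))
            # GTF is 1-based inclusive; convert to 0-based half-open
            genes.append(
                GeneAnnotation(
                    gene_id=attr["gene_id"],
                    chrom=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    biotype=biotype,
                )
            )
    return genes


def _parse_bed(path: Path) -> list[GeneAnnotation]:
    """BED6 with the gene biotype as an optional seventh column."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) > 5 else "."
            biotype = fields[6] if len(fields) > 6 else "protein_coding"
            genes.append(
                GeneAnnotation(
                    gene_id=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    biotype=biotype,
                )
            )
    return genes


def read_annotation(path: str | Path, format: str | None = None) -> list[GeneAnnotation]:
    """Read a gene annotation from GTF or BED6(+biotype).

    ``format`` is inferred from the file suffix when not given. Duplicate
    gene ids are rejected.
    """
    path = Path(path)
    if format is None:
        format = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed"
    if format == "gtf":
        genes = _parse_gtf(path)
    elif format == "bed":
        genes = _parse_bed(path)
    else:
        raise ValueError(f"unknown annotation format: {format!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id in annotation: {g.gene_id}")
        seen.add(g.gene_id)
    return genes


def write_annotation(genes: list[GeneAnnotation], path: str | Path, format: str = "gtf") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            if format == "gtf":
                attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
                fh.write(
                    f"{g.chrom}\tnucleograv\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            elif format == "bed":
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t{g.biotype}\n"
                )
            else:
                raise ValueError(f"unknown annotation format: {format!r}")


def read_de_table(
    path: str | Path,
    comparison: str = "",
    track: str = "regular",
    columns: dict[str, str] | None = None,
) -> DEResultTable:
    """Read a DESeq2-style TSV result table.

    ``columns`` maps internal names (gene_id, base_mean, log2fc, pvalue,
    padj) to the file's column names; DESeq2 defaults apply. ``NA`` values
    in padj are kept as missing and later classified not-significant.
    """
    colmap = dict(DESEQ2_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t")
    missing = [v for k, v in colmap.items() if v not in df.columns and k in ("gene_id", "log2fc", "padj")]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    rename = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    keep = [c for c in ("gene_id", "base_mean", "log2fc", "pvalue", "padj") if c in df.columns]
    df = df[keep].copy()
    df["gene_id"] = df["gene_id"].astype(str)
    for c in keep[1:]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    if not comparison:
        comparison = Path(path).stem
    return DEResultTable(comparison=comparison, track=track, data=df.reset_index(drop=True))


def write_de_table(table: DEResultTable, path: str | Path) -> None:
    """Write a DE table back out with DESeq2 column names."""
    df = table.data.rename(columns=DESEQ2_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def classify_degs(
    table: DEResultTable, alpha: float = 0.05, lfc_cutoff: float = 0.0
) -> DEGStatusMap:
    """Classify every tested gene as up / down / ns.

    A gene is up iff padj < alpha and log2fc > +lfc_cutoff, down iff
    padj < alpha and log2fc < -lfc_cutoff; everything else (including
    missing padj) is ns. Inequalities are strict on both p and fold change.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if lfc_cutoff < 0:
        raise ValueError(f"lfc_cutoff must be >= 0, got {lfc_cutoff}")
    padj = table.data["padj"].to_numpy(dtype=float)
    lfc = table.data["log2fc"].to_numpy(dtype=float)
    sig = ~np.isnan(padj) & (padj < alpha) & ~np.isnan(lfc)
    status = np.where(
        sig & (lfc > lfc_cutoff), "up", np.where(sig & (lfc < -lfc_cutoff), "down", "ns")
    )
    return DEGStatusMap(
        comparison=table.comparison,
        track=table.track,
        status=dict(zip(table.data["gene_id"], status)),
    )
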