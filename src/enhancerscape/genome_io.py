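"""Readers/writers for the interval, gene-model and matrix formats the pipeline touches.

All coordinates are 0-based half-open (BED convention) internally; GFF3 is
converted at the boundary.  Sorting is total and stable on
``(chrom, start, end, name)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "FragmentSet",
    "ParseError",
    "read_intervals",
    "write_intervals",
    "read_gene_models",
    "read_matrix",
    "write_matrix",
    "sort_peaks",
]


class ParseError(ValueError):
    """Malformed record in a genomic text file (carries the line number)."""


@dataclasses.dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open 0-based genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap length in bp (0 when disjoint or on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclasses.dataclass(frozen=True)
class Peak:
    """A called region with a single-base summit and an enrichment score."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside {self.interval.chrom}:"
                f"{self.interval.start}-{self.interval.end}"
            )
        if self.score < 0:
            raise ValueError("score must be nonnegative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """Gene with a strand-aware transcription start site.

    For '+' genes the TSS is the interval start; for '-' genes it is the last
    base (``end - 1``).
    """

    gene_id: str
    interval: GenomicInterval
    strand: str
    tss: int = -1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        expected = self.interval.start if self.strand == "+" else self.interval.end - 1
        if self.tss == -1:
            object.__setattr__(self, "tss", expected)
        elif self.tss != expected:
            raise ValueError(
                f"tss {self.tss} inconsistent with strand {self.strand} for "
                f"{self.gene_id} (expected {expected})"
            )


@dataclasses.dataclass
class FragmentSet:
    """Aligned fragments for one sample (stand-in for a BAM file)."""

    sample_id: str
    assay: str
    group: str
    fragments: list[GenomicInterval]

    ASSAYS = ("ATAC", "H3K27ac", "RNA")
    GROUPS = ("L", "M", "H")

    def __post_init__(self) -> None:
        if self.assay not in self.ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.group not in self.GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def _sort_key(p: Peak) -> tuple:
    return (p.chrom, p.start, p.end, p.name)


def sort_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    """Stable total sort on (chrom lexicographic, start, end, name)."""
    return sorted(peaks, key=_sort_key)


def read_intervals(path: str | Path, dialect: Literal["BED", "narrowPeak"] = "BED") -> list[Peak]:
    """Read a BED3/BED6 or ENCODE narrowPeak file into sorted :class:`Peak` records.

    For summit-less dialects the summit defaults to the interval midpoint
    (rounded down); narrowPeak column 10 carries the summit offset, with -1
    meaning "unknown" (midpoint rule applies).
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "narrowPeak":
                    if len(fields) < 10:
                        raise ValueError("narrowPeak needs 10 columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3]
                    score = max(0.0, float(fields[6]))
                    offset = int(fields[9])
                    iv = GenomicInterval(chrom, start, end)
                    summit = iv.midpoint if offset == -1 else start + offset
                elif dialect == "BED":
                    if len(fields) < 3:
                        raise ValueError("BED needs at least 3 columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else "."
                    score = float(fields[4]) if len(fields) > 4 else 0.0
                    iv = GenomicInterval(chrom, start, end)
                    summit = iv.midpoint
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
                peaks.append(Peak(iv, summit=summit, score=score, name=name))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return sort_peaks(peaks)


def write_intervals(
    peaks: Sequence[Peak], path: str | Path, dialect: Literal["BED", "narrowPeak"] = "BED"
) -> None:
    """Write peaks as BED6 or narrowPeak (summit offset in column 10)."""
    with open(path, "w") as fh:
        for p in peaks:
            if dialect == "narrowPeak":
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                    f"{p.score:.6g}\t-1\t-1\t{p.summit - p.start}\n"
                )
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:.6g}\t.\n")


def read_gene_models(path: str | Path, dialect: Literal["GFF3", "TSV"] = "GFF3") -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive -> half-open) or a TSV.

    The GFF3 reader keeps ``gene`` features only and takes the identifier from
    the ``ID=`` attribute.  The TSV dialect expects columns
    ``gene_id  chrom  start  end  strand  tss`` (0-based half-open, validated
    against the strand rule).
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "GFF3":
                    if len(fields) < 9:
                        raise ValueError("GFF3 needs 9 columns")
                    if fields[2] != "gene":
                        continue
                    chrom, start1, end1, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    gene_id = attrs.get("ID", f"gene_line{lineno}")
                    iv = GenomicInterval(chrom, start1 - 1, end1)
                    genes.append(GeneModel(gene_id, iv, strand))
                elif dialect == "TSV":
                    if fields[0] == "gene_id":  # header
                        continue
                    gene_id, chrom = fields[0], fields[1]
                    start, end, strand, tss = int(fields[2]), int(fields[3]), fields[4], int(fields[5])
                    genes.append(GeneModel(gene_id, GenomicInterval(chrom, start, end), strand, tss))
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))


def write_gene_models_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models back to GFF3 (1-based inclusive printed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.interval.chrom}\tenhancerscape\tgene\t{g.interval.start + 1}\t"
                f"{g.interval.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature x sample matrix as TSV (NA sentinel for missing)."""
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].tolist()
        raise ValueError(f"duplicate row ids: {dups}")
    matrix.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g", index_label="feature")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix written by :func:`write_matrix` (lossless at 6 s.d.)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate row ids in {path}: {dups}")
    if df.isna().all(axis=None) and df.shape[1] == 0:
        raise ValueError(f"empty matrix in {path}")
    return df
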