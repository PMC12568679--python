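"""Region-to-gene assignment and gene-set (term) enrichment.

Peaks are assigned to genes by the basal-plus-nearest rule: a basal
regulatory domain of 5 kb upstream / 1 kb downstream of each TSS
(strand-aware); a peak overlapping one or more basal domains is assigned to
all of those genes, otherwise to the single gene with the nearest TSS within
1 Mb of the peak midpoint.  Assigned gene sets feed a hypergeometric
over-representation test against a term map, BH-adjusted.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome_io import GeneModel, GenomicInterval, Peak
from .motifs import EnrichmentResult, hypergeom_upper_tail
from .peaks import bh_adjust

__all__ = [
    "RegulatoryDomain",
    "GeneAssignment",
    "TermMap",
    "basal_domain",
    "assign_regions",
    "term_enrichment",
    "read_term_map",
]

BASAL_UPSTREAM = 5_000
BASAL_DOWNSTREAM = 1_000
MAX_DISTANCE = 1_000_000


@dataclasses.dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    basal: GenomicInterval
    tss: int
    strand: str


@dataclasses.dataclass(frozen=True)
class GeneAssignment:
    peak_id: str
    gene_ids: tuple[str, ...]
    mode: str  # basal_overlap | nearest

    def __post_init__(self) -> None:
        if self.mode == "nearest" and len(self.gene_ids) != 1:
            raise ValueError("nearest mode assigns exactly one gene")
        if not self.gene_ids:
            raise ValueError("assignment needs >= 1 gene")


@dataclasses.dataclass
class TermMap:
    terms: dict[str, set[str]]  # term id -> gene ids
    names: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {t!r} has no genes")


def basal_domain(
    gene: GeneModel,
    upstream_bp: int = BASAL_UPSTREAM,
    downstream_bp: int = BASAL_DOWNSTREAM,
) -> RegulatoryDomain:
    """Strand-aware basal regulatory window around the TSS."""
    if gene.strand == "+":
        lo, hi = gene.tss - upstream_bp, gene.tss + downstream_bp
    else:
        lo, hi = gene.tss - downstream_bp + 1, gene.tss + upstream_bp + 1
    return RegulatoryDomain(
        gene.gene_id, GenomicInterval(gene.interval.chrom, max(0, lo), hi), gene.tss, gene.strand
    )


def assign_regions(
    peaks: list[Peak],
    genes: Sequence[GeneModel],
    max_distance: int = MAX_DISTANCE,
    upstream_bp: int = BASAL_UPSTREAM,
    downstream_bp: int = BASAL_DOWNSTREAM,
) -> list[GeneAssignment]:
    """Basal-overlap assignment with nearest-TSS (< ``max_distance``) fallback.

    Deterministic and independent of input order: genes within a basal
    assignment are reported sorted; nearest ties break on the lower gene
    coordinate.
    """
    domains = [basal_domain(g, upstream_bp, downstream_bp) for g in genes]
    trees: dict[str, IntervalTree] = {}
    tss_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for d, g in zip(domains, genes):
        chrom = d.basal.chrom
        trees.setdefault(chrom, IntervalTree()).addi(d.basal.start, d.basal.end, d.gene_id)
        tss_by_chrom.setdefault(chrom, []).append((g.tss, g.interval.start, g.gene_id))

    out: list[GeneAssignment] = []
    for p in peaks:
        tree = trees.get(p.chrom)
        hits = sorted(iv.data for iv in tree.overlap(p.start, p.end)) if tree else []
        if hits:
            out.append(GeneAssignment(p.name, tuple(hits), "basal_overlap"))
            continue
        mid = p.interval.midpoint
        best = None
        for tss, gstart, gid in tss_by_chrom.get(p.chrom, []):
            d = abs(mid - tss)
            key = (d, gstart, gid)
            if best is None or key < best:
                best = key
        if best is not None and best[0] < max_distance:
            out.append(GeneAssignment(p.name, (best[2],), "nearest"))
    return out


def term_enrichment(
    gene_set: set[str],
    universe: set[str],
    term_map: TermMap,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail over-representation per term, BH-adjusted.

    Significance means q <= ``alpha``; the universe defaults in callers to all
    genes carrying at least one term annotation.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    N = len(universe)
    n = len(gene_set)
    results = []
    for term, genes in sorted(term_map.terms.items()):
        K = len(genes & universe)
        if K == 0:
            continue
        k = len(gene_set & genes)
        p = hypergeom_upper_tail(k, n, K, N)
        fold = (k / n) / (K / N) if n > 0 else 0.0
        results.append(EnrichmentResult(term, k=k, n=n, K=K, N=N, fold=fold, pvalue=p))
    qs = bh_adjust(np.array([r.pvalue for r in results]))
    return [dataclasses.replace(r, qvalue=float(q)) for r, q in zip(results, qs)]


def read_term_map(path: str | Path, names_path: str | Path | None = None) -> TermMap:
    """Two-column TSV (term, gene) plus an optional (term, name) file."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, gene = line.split("\t")[:2]
            terms.setdefault(term, set()).add(gene)
    names: dict[str, str] = {}
    if names_path is not None:
        with open(names_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                term, name = line.split("\t")[:2]
                names[term] = name
    return TermMap(terms=terms, names=names)
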