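"""Candidate cis-regulatory element annotation.

Active-mark (H3K27ac) peaks are first required to co-occur with open
chromatin (ATAC overlap filter), then split into promoters and enhancers by a
strand-aware TSS window (default 1 kb upstream / 500 bp downstream), and
finally annotated with a genomic-feature category and a signed TSS-distance
bin.  Feature assignment walks a fixed priority list, ChIPseeker-style.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

from intervaltree import IntervalTree

from .genome_io import GeneModel, Peak, sort_peaks

__all__ = [
    "CREAnnotation",
    "GenomeAnnotation",
    "atac_overlap_filter",
    "classify_cre",
    "annotate_peak",
    "annotate_peaks",
    "FEATURES",
    "DISTANCE_BINS",
]

FEATURES = (
    "promoter_region",
    "5'UTR",
    "3'UTR",
    "exon",
    "first_intron",
    "other_intron",
    "downstream",
    "distal_intergenic",
    "non_coding",
)

#: (label, inclusive lower bound bp, exclusive upper bound bp) on |TSS distance|
DISTANCE_BINS = (
    ("0-1 kb", 0, 1_000),
    ("1-3 kb", 1_000, 3_000),
    ("3-10 kb", 3_000, 10_000),
    ("10-100 kb", 10_000, 100_000),
    ("100 kb-1 Mb", 100_000, 1_000_000),
    (">1 Mb", 1_000_000, float("inf")),
)

DOWNSTREAM_BP = 3_000


@dataclasses.dataclass(frozen=True)
class CREAnnotation:
    peak_id: str
    cre_class: str  # promoter | enhancer
    feature: str
    signed_tss_distance: int  # negative = upstream of the nearest TSS
    distance_bin: str


def distance_bin(abs_distance: int) -> str:
    for label, lo, hi in DISTANCE_BINS:
        if lo <= abs_distance < hi:
            return label
    raise AssertionError("unreachable")


def promoter_window(gene: GeneModel, upstream_bp: int, downstream_bp: int) -> tuple[int, int]:
    """Half-open strand-aware window around the TSS (upstream is rightward on '-')."""
    if gene.strand == "+":
        return gene.tss - upstream_bp, gene.tss + downstream_bp
    return gene.tss - downstream_bp + 1, gene.tss + upstream_bp + 1


class GenomeAnnotation:
    """Prebuilt per-chromosome interval indexes over a gene set.

    ``exons`` optionally maps gene_id -> list of (start, end) half-open exon
    intervals (in transcription order); genes absent from it are treated as
    single-exon.  ``utr5``/``utr3``/``noncoding_ids`` refine the feature call
    when available.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        upstream_bp: int = 1_000,
        downstream_bp: int = 500,
        exons: dict[str, list[tuple[int, int]]] | None = None,
        utr5: dict[str, list[tuple[int, int]]] | None = None,
        utr3: dict[str, list[tuple[int, int]]] | None = None,
        noncoding_ids: set[str] | None = None,
    ):
        self.genes = list(genes)
        self.upstream_bp = upstream_bp
        self.downstream_bp = downstream_bp
        self.exons = exons or {}
        self.utr5 = utr5 or {}
        self.utr3 = utr3 or {}
        self.noncoding_ids = noncoding_ids or set()

        self._promoters: dict[str, IntervalTree] = {}
        self._bodies: dict[str, IntervalTree] = {}
        self._tss: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            chrom = g.interval.chrom
            lo, hi = promoter_window(g, upstream_bp, downstream_bp)
            self._promoters.setdefault(chrom, IntervalTree()).addi(max(0, lo), hi, g)
            self._bodies.setdefault(chrom, IntervalTree()).addi(
                g.interval.start, g.interval.end, g
            )
            self._tss.setdefault(chrom, []).append(g)

    # -- promoter/enhancer split ------------------------------------------
    def cre_class(self, peak: Peak) -> str:
        tree = self._promoters.get(peak.chrom)
        if tree is not None and tree.overlap(peak.start, peak.end):
            return "promoter"
        return "enhancer"

    # -- nearest TSS ------------------------------------------------------
    def nearest_tss(self, peak: Peak) -> tuple[GeneModel | None, int]:
        """Nearest gene by |peak midpoint - TSS| and the signed distance.

        The sign is strand-aware: negative means the peak lies upstream of the
        nearest TSS.
        """
        mid = peak.interval.midpoint
        best: GeneModel | None = None
        best_abs = None
        for g in self._tss.get(peak.chrom, []):
            d = abs(mid - g.tss)
            if best_abs is None or d < best_abs or (
                d == best_abs and g.interval.start < best.interval.start
            ):
                best, best_abs = g, d
        if best is None:
            return None, 0
        signed = mid - best.tss if best.strand == "+" else best.tss - mid
        return best, signed

    # -- genomic feature --------------------------------------------------
    def _gene_feature(self, peak: Peak, g: GeneModel) -> str | None:
        """Feature of the peak relative to one overlapping gene, or None."""
        s, e = peak.start, peak.end

        def hits(ivs: list[tuple[int, int]]) -> bool:
            return any(s < b and a < e for a, b in ivs)

        if hits(self.utr5.get(g.gene_id, [])):
            return "5'UTR"
        if hits(self.utr3.get(g.gene_id, [])):
            return "3'UTR"
        if g.gene_id in self.noncoding_ids:
            return "non_coding"
        exons = self.exons.get(
            g.gene_id, [(g.interval.start, g.interval.end)]
        )
        if hits(exons):
            return "exon"
        # introns between consecutive exons in coordinate order; "first" is
        # transcription-order first (leftmost for '+', rightmost for '-')
        exs = sorted(exons)
        introns = [(exs[i][1], exs[i + 1][0]) for i in range(len(exs) - 1)]
        for i, iv in enumerate(introns):
            if s < iv[1] and iv[0] < e:
                first = i == 0 if g.strand == "+" else i == len(introns) - 1
                return "first_intron" if first else "other_intron"
        return None

    def feature(self, peak: Peak) -> str:
        s, e = peak.start, peak.end
        tree = self._promoters.get(peak.chrom)
        if tree is not None and tree.overlap(s, e):
            return "promoter_region"
        body_hits = []
        bt = self._bodies.get(peak.chrom)
        if bt is not None:
            body_hits = [iv.data for iv in bt.overlap(s, e)]
        ranked: list[str] = []
        for g in body_hits:
            f = self._gene_feature(peak, g)
            if f is not None:
                ranked.append(f)
        if ranked:
            return min(ranked, key=FEATURES.index)
        # downstream: within 3 kb past the gene end, strand-aware
        for g in self._tss.get(peak.chrom, []):
            if g.strand == "+":
                lo, hi = g.interval.end, g.interval.end + DOWNSTREAM_BP
            else:
                lo, hi = g.interval.start - DOWNSTREAM_BP, g.interval.start
            if s < hi and lo < e:
                return "downstream"
        return "distal_intergenic"

    def annotate(self, peak: Peak) -> CREAnnotation:
        _, signed = self.nearest_tss(peak)
        return CREAnnotation(
            peak_id=peak.name,
            cre_class=self.cre_class(peak),
            feature=self.feature(peak),
            signed_tss_distance=signed,
            distance_bin=distance_bin(abs(signed)),
        )


def atac_overlap_filter(
    k27_peaks: list[Peak], atac_peaks: list[Peak], min_overlap_bp: int = 1
) -> list[Peak]:
    """Keep active-mark peaks with >= ``min_overlap_bp`` overlap with open chromatin."""
    trees: dict[str, IntervalTree] = {}
    for p in atac_peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    kept = []
    for p in k27_peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(p.start, p.end):
            if min(iv.end, p.end) - max(iv.begin, p.start) >= min_overlap_bp:
                kept.append(p)
                break
    return sort_peaks(kept)


def classify_cre(
    peak: Peak,
    tss_index: GenomeAnnotation | Sequence[GeneModel],
    upstream_bp: int = 1_000,
    downstream_bp: int = 500,
) -> str:
    """'promoter' iff the peak overlaps any strand-aware TSS window, else 'enhancer'."""
    if not isinstance(tss_index, GenomeAnnotation):
        if len(tss_index) == 0:
            warnings.warn("empty gene set: everything classified as enhancer", RuntimeWarning)
            return "enhancer"
        tss_index = GenomeAnnotation(tss_index, upstream_bp, downstream_bp)
    return tss_index.cre_class(peak)


def annotate_peak(
    peak: Peak, gene_models: GenomeAnnotation | Sequence[GeneModel], **kwargs
) -> CREAnnotation:
    if not isinstance(gene_models, GenomeAnnotation):
        gene_models = GenomeAnnotation(gene_models, **kwargs)
    return gene_models.annotate(peak)


def annotate_peaks(
    peaks: list[Peak], gene_models: GenomeAnnotation | Sequence[GeneModel], **kwargs
) -> list[CREAnnotation]:
    if not isinstance(gene_models, GenomeAnnotation):
        gene_models = GenomeAnnotation(gene_models, **kwargs)
    return [gene_models.annotate(p) for p in peaks]
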