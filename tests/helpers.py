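"""Small constructors shared across test modules."""

from enhancerscape.genome_io import GeneModel, GenomicInterval, Peak


def make_peak(
    chrom: str,
    start: int,
    end: int,
    summit: int | None = None,
    score: float = 1.0,
    name: str = ".",
) -> Peak:
    iv = GenomicInterval(chrom, start, end)
    return Peak(iv, summit=iv.midpoint if summit is None else summit, score=score, name=name)


def make_gene(gene_id: str, chrom: str, start: int, end: int, strand: str) -> GeneModel:
    return GeneModel(gene_id, GenomicInterval(chrom, start, end), strand)
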