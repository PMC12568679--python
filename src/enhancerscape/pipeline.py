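"""End-to-end orchestration on synthetic inputs with planted ground truth.

Runs the full enhancer-landscape analysis — replicate peak calling, within-
group IDR filtering, consensus peaks, ATAC co-occurrence filtering,
promoter/enhancer classification, signal normalization, dynamic-enhancer
profiling against the L baseline, motif enrichment of up- vs non-up
enhancers, region-to-gene assignment, and the RNA/phenotype stage — then
scores the result against the planted truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import dynamics, motifs, signal as signal_mod
from .association import assign_regions
from .cre_annotation import GenomeAnnotation, atac_overlap_filter
from .expression_pheno import de_filter, fpkm, gene_trait_network, venn_intersect
from .genome_io import FragmentSet, Peak
from .peaks import call_peaks_genome, make_coverage
from .reproducibility import (
    consensus_peaks,
    fit_idr,
    idr_filter,
    pair_replicate_peaks,
)
from .synthetic_data import (
    GROUPS,
    SimConfig,
    TruthSet,
    make_pwm_set,
    simulate_expression_phenotypes,
    simulate_fragments,
    simulate_landscape,
    simulate_sequences_with_motifs,
)

__all__ = ["PipelineResult", "run_pipeline", "group_idr_peaks", "assay_consensus"]


@dataclasses.dataclass
class PipelineResult:
    truth: TruthSet
    consensus: dict[str, list[Peak]]  # per assay
    filtered_k27: list[Peak]
    promoter_peaks: list[Peak]
    enhancer_peaks: list[Peak]
    signal: pd.DataFrame
    assignments: list[dynamics.ProfileAssignment]
    profile_tests: list[dynamics.ProfileTest]
    variability_p: float
    enrichment: list[motifs.EnrichmentResult]
    up_recovery: float
    motif_rank: int
    deg_common: set[str]
    n_edges: int


def group_idr_peaks(
    frag_sets: list[FragmentSet],
    genome: dict[str, int],
    *,
    alpha: float = 0.05,
    idr_threshold: float = 0.05,
    bin_size: int = 100,
) -> list[Peak]:
    """IDR-filtered peaks for one group's replicates.

    With more than two replicates the two deepest samples (by fragment count)
    are paired, mirroring common practice for replicate-pair IDR.
    """
    reps = sorted(frag_sets, key=lambda fs: len(fs.fragments), reverse=True)[:2]
    if len(reps) < 2:
        raise ValueError("need >= 2 replicates for IDR")
    called = []
    for fs in reps:
        tracks = make_coverage(fs, bin_size, genome)
        called.append(call_peaks_genome(tracks, alpha=alpha))
    pairs = pair_replicate_peaks(called[0], called[1])
    scored = [(p1, p2, p1.score, p2.score) for p1, p2 in pairs]
    result = fit_idr(scored)
    return idr_filter(result, threshold=idr_threshold)


def assay_consensus(
    frag_sets: list[FragmentSet],
    genome: dict[str, int],
    *,
    alpha: float = 0.05,
    idr_threshold: float = 0.05,
    fraction_F: float = 0.5,
    bin_size: int = 100,
) -> list[Peak]:
    """Union-of-group IDR peaks intersected with pooled-sample peaks."""
    idr_union: list[Peak] = []
    for group in GROUPS:
        group_sets = [fs for fs in frag_sets if fs.group == group]
        idr_union.extend(
            group_idr_peaks(
                group_sets,
                genome,
                alpha=alpha,
                idr_threshold=idr_threshold,
                bin_size=bin_size,
            )
        )
    return consensus_peaks(
        frag_sets,
        idr_union,
        genome,
        alpha=alpha,
        fraction_F=fraction_F,
        bin_size=bin_size,
    )


def _overlaps_site(peak: Peak, site_iv) -> bool:
    return peak.chrom == site_iv.chrom and peak.interval.overlap(site_iv) > 0


def run_pipeline(
    config: SimConfig | None = None,
    *,
    top_k: int = 5_000,
    cv_min: float = 0.5,
    unit_c: int = 2,
) -> PipelineResult:
    """Simulate a landscape and run every stage; score against the truth.

    ``up_recovery`` is the fraction of planted up-trending enhancer sites that
    end up in an up-direction profile; ``motif_rank`` is the 1-based rank of
    the planted motif among all scanned motifs by enrichment p-value.
    """
    config = config or SimConfig()
    truth = simulate_landscape(config)
    frag_sets = simulate_fragments(truth, config)
    genome = truth.genome

    consensus: dict[str, list[Peak]] = {}
    for assay in ("ATAC", "H3K27ac"):
        assay_sets = [fs for fs in frag_sets if fs.assay == assay]
        consensus[assay] = assay_consensus(assay_sets, genome)

    filtered = atac_overlap_filter(consensus["H3K27ac"], consensus["ATAC"])

    annotation = GenomeAnnotation(truth.genes)
    promoter_peaks = [p for p in filtered if annotation.cre_class(p) == "promoter"]
    enhancer_peaks = [p for p in filtered if annotation.cre_class(p) == "enhancer"]

    k27_sets = [fs for fs in frag_sets if fs.assay == "H3K27ac"]
    cm = signal_mod.count_in_peaks(filtered, k27_sets)
    sig = signal_mod.normalize_signal(cm)
    groups = {
        g: [fs.sample_id for fs in k27_sets if fs.group == g] for g in GROUPS
    }
    merged_by_id = {p.name: p for p in signal_mod.merge_overlapping(filtered)}
    all_signals = dynamics.group_means(sig, groups)
    enh_ids = {p.name for p in enhancer_peaks}
    prom_ids = {p.name for p in promoter_peaks}
    enh_signals = [gs for gs in all_signals if gs.peak_id in enh_ids]
    prom_signals = [gs for gs in all_signals if gs.peak_id in prom_ids]

    if len(prom_signals) >= 2 and len(enh_signals) >= 2:
        _, var_p = dynamics.compare_variability(prom_signals, enh_signals)
    else:
        var_p = float("nan")

    selected = set(dynamics.select_dynamic(enh_signals, top_k=top_k, cv_min=cv_min))
    sel_signals = [gs for gs in enh_signals if gs.peak_id in selected]
    assignments = dynamics.assign_profiles(sel_signals, unit_c=unit_c)
    profile_tests = (
        dynamics.test_profiles(assignments, sel_signals, unit_c=unit_c)
        if assignments
        else []
    )

    # planted up-site recovery: an up site counts as recovered when some
    # enhancer peak assigned an up-direction profile overlaps it
    up_peak_ids = {a.peak_id for a in assignments if a.direction == "up"}
    up_peaks = [merged_by_id[i] for i in up_peak_ids if i in merged_by_id]
    up_sites = truth.sites_by_trend("up")
    recovered = sum(
        any(_overlaps_site(p, s.interval) for p in up_peaks) for s in up_sites
    )
    up_recovery = recovered / len(up_sites) if up_sites else float("nan")

    # motif enrichment: up enhancers vs the remaining enhancers
    pwms = make_pwm_set(config)
    sequences = simulate_sequences_with_motifs(truth, pwms, config)
    non_up_peaks = [p for p in enhancer_peaks if p.name not in up_peak_ids]
    enrichment: list[motifs.EnrichmentResult] = []
    motif_rank = 0
    if up_peaks and non_up_peaks:
        target = motifs.extract_summit_windows(up_peaks, sequences)
        background = motifs.extract_summit_windows(non_up_peaks, sequences)
        background = {k: v for k, v in background.items() if k not in target}
        enrichment = motifs.motif_enrichment(target, background, pwms)
        ranked = sorted(enrichment, key=lambda r: (r.pvalue, r.unit_id))
        motif_rank = 1 + [r.unit_id for r in ranked].index("M_UP")

    # region-to-gene assignment feeds downstream interpretation
    assign_regions(enhancer_peaks, truth.genes)

    expr, traits = simulate_expression_phenotypes(truth, config)
    fk = fpkm(expr)
    rna_groups = {
        g: [c for c in fk.columns if c.startswith(g)] for g in GROUPS
    }
    degs = {
        comp: {r.gene_id for r in de_filter(fk, rna_groups, comp) if r.passes}
        for comp in ("HvsM", "HvsL", "MvsL")
    }
    _, common = venn_intersect(degs["HvsM"], degs["HvsL"], degs["MvsL"])
    core = sorted(common) if common else sorted(degs["HvsL"])[:10]
    n_edges = 0
    if core:
        edges, _ = gene_trait_network(fk.loc[core], traits)
        n_edges = len(edges)

    return PipelineResult(
        truth=truth,
        consensus=consensus,
        filtered_k27=filtered,
        promoter_peaks=promoter_peaks,
        enhancer_peaks=enhancer_peaks,
        signal=sig,
        assignments=assignments,
        profile_tests=profile_tests,
        variability_p=var_p,
        enrichment=enrichment,
        up_recovery=up_recovery,
        motif_rank=motif_rank,
        deg_common=common,
        n_edges=n_edges,
    )
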