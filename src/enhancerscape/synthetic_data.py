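"""Synthetic multi-omics inputs with planted ground truth.

The generator emulates the study design the pipeline targets: three ordered
diet groups (L, M, H) with replicated ATAC and H3K27ac samples over a small
genome.  Regulatory sites are planted as promoter-proximal or distal
(enhancer) intervals; enhancer strength follows monotone up/down/flat trends
along the group gradient while accessibility (ATAC) and promoter activity
stay flat; a known motif is planted preferentially in up-trending enhancer
sequence; differentially expressed genes sit nearest to trending enhancers
and designated phenotype traits track designated genes monotonically.

Every generator is a pure function of ``(config, seed)``; per-stage random
substreams are derived from the single global seed so stages reproduce
independently.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_pheno import ExpressionMatrix
from .genome_io import FragmentSet, GeneModel, GenomicInterval
from .motifs import PWM, reverse_complement

__all__ = [
    "SimConfig",
    "TrueSite",
    "TruthSet",
    "simulate_landscape",
    "simulate_fragments",
    "simulate_sequences_with_motifs",
    "simulate_expression_phenotypes",
    "make_pwm_set",
    "write_fasta",
]

_STAGE_LANDSCAPE = 1
_STAGE_FRAGMENTS = 2
_STAGE_SEQUENCES = 3
_STAGE_EXPRESSION = 4

GROUPS = ("L", "M", "H")
TRAITS = (
    "live_weight",
    "carcass_weight",
    "dressing_pct",
    "ph45",
    "ph24",
    "thaw_loss_pct",
    "cook_loss_pct",
    "hardness",
    "chewiness",
)


@dataclasses.dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are desk-scale study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 400  # >= proximal site count: one TSS hosts ~1 site at spacing
    n_sites: int = 600
    fraction_distal: float = 0.5
    reproducible_fraction: float = 0.9  # pi1
    background_rate: float = 0.02  # fragments/bp/sample
    fragment_depth: int | None = None  # optional: expected background frags/sample
    fragment_length: int = 100
    site_width: int = 400
    min_site_spacing: int = 3_000
    distal_min_tss_distance: int = 10_000
    n_replicates: int = 2
    #: fold enrichment over background per trend class, ordered (L, M, H)
    trend_strengths: dict = dataclasses.field(
        default_factory=lambda: {
            "up": (4.0, 10.0, 24.0),
            "down": (24.0, 10.0, 4.0),
            "flat": (12.0, 12.0, 12.0),
        }
    )
    atac_strength: float = 12.0
    site_strength_sd: float = 0.6  # lognormal sd of per-site baseline strength
    replicate_jitter_sd: float = 0.15  # lognormal sd of per-site replicate noise
    gc: float = 0.5
    motif_plant_rate: float = 0.9
    n_decoy_motifs: int = 10
    # expression / phenotype stage
    n_rna_replicates: int = 3
    n_de_genes: int = 40
    de_fold: float = 4.0  # H vs L linear fold for planted DE genes
    rna_depth: int = 1_000_000
    nb_dispersion: float = 0.05
    trait_noise_sd: float = 0.1  # relative to trait signal scale

    def __post_init__(self) -> None:
        for name in ("fraction_distal", "reproducible_fraction", "motif_plant_rate", "gc"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.background_rate <= 0 and self.fragment_depth is None:
            raise ValueError("need positive background_rate or fragment_depth")

    @property
    def genome(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    @property
    def effective_background_rate(self) -> float:
        if self.fragment_depth is not None:
            return self.fragment_depth / (self.n_chroms * self.chrom_length)
        return self.background_rate

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclasses.dataclass
class TrueSite:
    site_id: str
    interval: GenomicInterval
    cre_class: str  # promoter | enhancer
    trend: str  # up | down | flat
    strengths: tuple[float, float, float]  # fold enrichment (L, M, H)
    reproducible: bool = True
    #: site-specific baseline multiplier, shared across groups and replicates
    #: (real peak strengths span orders of magnitude; replicate score ranks
    #: correlate through this shared component)
    scale: float = 1.0

    @property
    def summit(self) -> int:
        return self.interval.midpoint


@dataclasses.dataclass
class TruthSet:
    genome: dict[str, int]
    genes: list[GeneModel]
    sites: list[TrueSite]
    planted_motifs: dict[str, set[str]]  # motif id -> site ids
    de_genes: dict[str, tuple[float, float, float]]  # gene -> fold per group
    trait_links: dict[str, tuple[str, int]]  # trait -> (gene id, direction)

    def sites_by_trend(self, trend: str) -> list[TrueSite]:
        return [s for s in self.sites if s.trend == trend]


def _place_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    chroms = list(config.genome)
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        length = int(rng.integers(5_000, 20_000))
        start = int(rng.integers(50_000, config.chrom_length - length - 50_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{i:04d}", GenomicInterval(chrom, start, start + length), strand))
    return sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start))


def _min_tss_distance(pos: int, chrom: str, tss: dict[str, np.ndarray]) -> int:
    arr = tss.get(chrom)
    if arr is None or arr.size == 0:
        return 10**9
    return int(np.abs(arr - pos).min())


def simulate_landscape(config: SimConfig) -> TruthSet:
    """Plant genes, regulatory sites, trends, motifs, DE genes and trait links."""
    rng = config.rng(_STAGE_LANDSCAPE)
    genes = _place_genes(config, rng)
    tss: dict[str, np.ndarray] = {}
    for g in genes:
        tss.setdefault(g.interval.chrom, [])
        tss[g.interval.chrom].append(g.tss)
    tss = {c: np.sort(np.array(v)) for c, v in tss.items()}

    n_distal = int(round(config.n_sites * config.fraction_distal))
    n_prox = config.n_sites - n_distal
    chroms = list(config.genome)
    half = config.site_width // 2
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def free(chrom: str, lo: int, hi: int) -> bool:
        pad = config.min_site_spacing
        return all(hi + pad <= a or b + pad <= lo for a, b in occupied[chrom])

    sites: list[TrueSite] = []

    def add_site(chrom: str, center: int, cls: str) -> None:
        lo, hi = center - half, center + half
        occupied[chrom].append((lo, hi))
        sites.append(
            TrueSite(
                site_id=f"site{len(sites):04d}",
                interval=GenomicInterval(chrom, lo, hi),
                cre_class=cls,
                trend="flat",
                strengths=config.trend_strengths["flat"],
            )
        )

    max_tries = 200 * config.n_sites
    tries = 0
    placed = 0
    while placed < n_distal:
        tries += 1
        if tries > max_tries:
            raise ValueError("genome too small for n_sites at the requested spacing")
        chrom = chroms[int(rng.integers(len(chroms)))]
        center = int(rng.integers(half + 1, config.chrom_length - half - 1))
        if _min_tss_distance(center, chrom, tss) <= config.distal_min_tss_distance:
            continue
        if not free(chrom, center - half, center + half):
            continue
        add_site(chrom, center, "enhancer")
        placed += 1
    placed = 0
    while placed < n_prox:
        tries += 1
        if tries > max_tries:
            raise ValueError("genome too small for n_sites at the requested spacing")
        g = genes[int(rng.integers(len(genes)))]
        offset = int(rng.integers(-500, 400))  # near the TSS window
        center = g.tss + (offset if g.strand == "+" else -offset)
        chrom = g.interval.chrom
        if not (half < center < config.chrom_length - half):
            continue
        if not free(chrom, center - half, center + half):
            continue
        add_site(chrom, center, "promoter")
        placed += 1

    # trends: promoter sites stay flat; enhancers split evenly up/down/flat
    enh_idx = [i for i, s in enumerate(sites) if s.cre_class == "enhancer"]
    perm = rng.permutation(len(enh_idx))
    third = len(enh_idx) // 3
    for rank, j in enumerate(perm):
        i = enh_idx[j]
        trend = "up" if rank < third else ("down" if rank < 2 * third else "flat")
        sites[i] = dataclasses.replace(
            sites[i], trend=trend, strengths=config.trend_strengths[trend]
        )

    # site-specific baseline strength (shared across groups and replicates)
    scales = np.exp(rng.normal(0.0, config.site_strength_sd, size=len(sites)))
    for i, s in enumerate(sites):
        sites[i] = dataclasses.replace(
            s,
            scale=float(scales[i]),
            strengths=tuple(float(v * scales[i]) for v in s.strengths),
        )

    # irreproducibility plant
    n_irr = int(round((1 - config.reproducible_fraction) * len(sites)))
    for i in rng.choice(len(sites), size=n_irr, replace=False):
        sites[i] = dataclasses.replace(sites[i], reproducible=False)

    # motif planting: the known motif goes to up-trending enhancer sites
    up_ids = [s.site_id for s in sites if s.trend == "up"]
    n_plant = int(round(config.motif_plant_rate * len(up_ids)))
    chosen = set(
        np.array(up_ids)[rng.choice(len(up_ids), size=n_plant, replace=False)]
    ) if up_ids else set()
    planted_motifs = {"M_UP": set(map(str, chosen))}

    # DE genes: nearest gene to trending enhancers, matching direction
    def nearest_gene(site: TrueSite) -> str | None:
        cands = [g for g in genes if g.interval.chrom == site.interval.chrom]
        if not cands:
            return None
        return min(cands, key=lambda g: abs(g.tss - site.summit)).gene_id

    de_genes: dict[str, tuple[float, float, float]] = {}
    f = config.de_fold
    per_direction = config.n_de_genes // 2
    for trend, folds in (("up", (1.0, np.sqrt(f), f)), ("down", (1.0, 1 / np.sqrt(f), 1 / f))):
        n_added = 0
        for s in sorted((x for x in sites if x.trend == trend), key=lambda s: s.site_id):
            if n_added >= per_direction:
                break
            g = nearest_gene(s)
            if g is not None and g not in de_genes:
                de_genes[g] = tuple(float(x) for x in folds)
                n_added += 1

    # trait links: alternate direction over the DE genes
    trait_links: dict[str, tuple[str, int]] = {}
    de_list = sorted(de_genes)
    for i, trait in enumerate(TRAITS):
        if not de_list:
            break
        gene = de_list[i % len(de_list)]
        trait_links[trait] = (gene, 1 if i % 2 == 0 else -1)

    return TruthSet(
        genome=config.genome,
        genes=genes,
        sites=sites,
        planted_motifs=planted_motifs,
        de_genes=de_genes,
        trait_links=trait_links,
    )


def simulate_fragments(truth: TruthSet, config: SimConfig) -> list[FragmentSet]:
    """Per-sample fragments: Poisson background plus site-local pileups.

    Site pileups scale with the group strength of the site (ATAC uses the flat
    accessibility strength for every site); replicate-specific lognormal
    jitter perturbs each site's depth; irreproducible sites receive signal in
    only the first replicate of each group.
    """
    rng = config.rng(_STAGE_FRAGMENTS)
    genome = truth.genome
    rate = config.effective_background_rate
    flen = config.fragment_length
    out: list[FragmentSet] = []
    for assay in ("ATAC", "H3K27ac"):
        for gi, group in enumerate(GROUPS):
            for rep in range(1, config.n_replicates + 1):
                frags: list[GenomicInterval] = []
                for chrom, clen in genome.items():
                    n_bg = rng.poisson(rate * clen)
                    starts = rng.integers(0, clen - flen, size=n_bg)
                    frags.extend(
                        GenomicInterval(chrom, int(s), int(s) + flen) for s in starts
                    )
                for site in truth.sites:
                    if not site.reproducible and rep != 1:
                        continue
                    strength = (
                        config.atac_strength * site.scale
                        if assay == "ATAC"
                        else site.strengths[gi]
                    )
                    lam = strength * rate * len(site.interval)
                    lam *= float(np.exp(rng.normal(0.0, config.replicate_jitter_sd)))
                    n_site = rng.poisson(lam)
                    centers = rng.normal(
                        site.summit, len(site.interval) / 4.0, size=n_site
                    )
                    lo_bound = site.interval.start - flen
                    hi_bound = site.interval.end + flen
                    centers = np.clip(centers, lo_bound, hi_bound)
                    clen = genome[site.interval.chrom]
                    for c in centers:
                        s = int(np.clip(round(c - flen / 2), 0, clen - flen))
                        frags.append(
                            GenomicInterval(site.interval.chrom, s, s + flen)
                        )
                frags.sort(key=lambda f: (f.chrom, f.start))
                out.append(
                    FragmentSet(
                        sample_id=f"{assay}_{group}{rep}",
                        assay=assay,
                        group=group,
                        fragments=frags,
                    )
                )
    return out


def make_pwm_set(config: SimConfig) -> list[PWM]:
    """The planted motif plus decoys, as sharp consensus-dominated PWMs.

    Deterministic for a given seed; decoy consensi are distinct from the
    planted one.
    """
    rng = config.rng(_STAGE_SEQUENCES)
    bases = "ACGT"

    def random_pwm(motif_id: str, length: int) -> PWM:
        cons = rng.integers(0, 4, size=length)
        mat = np.full((length, 4), 0.03)
        mat[np.arange(length), cons] = 0.91
        return PWM(motif_id, mat)

    pwms = [random_pwm("M_UP", 10)]
    seen = {pwms[0].consensus}
    i = 0
    while len(pwms) < 1 + config.n_decoy_motifs:
        p = random_pwm(f"DECOY{i:02d}", 10)
        i += 1
        if p.consensus in seen:
            continue
        seen.add(p.consensus)
        pwms.append(p)
    return pwms


def simulate_sequences_with_motifs(
    truth: TruthSet, pwm_set: list[PWM], config: SimConfig
) -> dict[str, str]:
    """i.i.d. background genome at the configured GC with planted consensi.

    Each planted motif's consensus is inserted at a random offset within
    summit +/- 100 bp of each of its assigned sites, on a random strand.
    """
    rng = config.rng(_STAGE_SEQUENCES)
    rng = np.random.default_rng(rng.integers(2**31))  # independent of PWM stream
    gc = config.gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome: dict[str, np.ndarray] = {}
    for chrom, clen in truth.genome.items():
        genome[chrom] = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=clen, p=probs)
    site_by_id = {s.site_id: s for s in truth.sites}
    pwm_by_id = {p.motif_id: p for p in pwm_set}
    for motif_id in sorted(truth.planted_motifs):
        pwm = pwm_by_id[motif_id]
        cons = pwm.consensus
        for site_id in sorted(truth.planted_motifs[motif_id]):
            site = site_by_id[site_id]
            lo = site.summit - 100
            hi = site.summit + 100 - len(cons)
            pos = int(rng.integers(lo, hi + 1))
            seq = cons if rng.random() < 0.5 else reverse_complement(cons)
            arr = genome[site.interval.chrom]
            arr[pos : pos + len(seq)] = np.frombuffer(seq.encode(), dtype="S1")
    return {c: a.tobytes().decode() for c, a in genome.items()}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sequences:
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_expression_phenotypes(
    truth: TruthSet, config: SimConfig
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial count table plus monotonically linked trait table.

    DE genes carry the planted per-group fold changes; each linked trait is an
    affine function of its gene's per-sample expression (with the configured
    direction) plus Gaussian noise.
    """
    rng = config.rng(_STAGE_EXPRESSION)
    genes = [g.gene_id for g in truth.genes]
    lengths = pd.Series(
        [len(g.interval) for g in truth.genes], index=genes, dtype=int
    )
    samples = [f"{g}{r}" for g in GROUPS for r in range(1, config.n_rna_replicates + 1)]
    base = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=len(genes))
    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    rel_len = lengths.to_numpy() / lengths.to_numpy().mean()
    for j, sample in enumerate(samples):
        gi = GROUPS.index(sample[0])
        mu = base * rel_len
        folds = np.array(
            [truth.de_genes.get(g, (1.0, 1.0, 1.0))[gi] for g in genes]
        )
        mu = mu * folds
        mu = mu / mu.sum() * config.rna_depth
        if config.nb_dispersion <= 0:
            counts[:, j] = rng.poisson(mu)
        else:
            size = 1.0 / config.nb_dispersion
            p = size / (size + mu)
            counts[:, j] = rng.negative_binomial(size, p)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    mapped = pd.Series(counts.sum(axis=0), index=samples)
    expr = ExpressionMatrix(counts=counts_df, lengths=lengths, mapped_totals=mapped)

    trait_rows = {}
    for trait, (gene, direction) in truth.trait_links.items():
        x = counts_df.loc[gene].to_numpy(dtype=float)
        scale = max(x.std(), 1e-9)
        noise = rng.normal(0.0, config.trait_noise_sd, size=len(samples))
        trait_rows[trait] = direction * (x / scale) + noise
    traits = pd.DataFrame(trait_rows, index=samples)
    return expr, traits
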