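# enhancerscape

Reproducible analysis of diet-responsive enhancer landscapes from
open-chromatin (ATAC) and active-histone-mark (H3K27ac) data collected over an
ordered treatment gradient — for example skeletal-muscle epigenomes of
ruminants fed low/medium/high dietary NFC/NDF (non-fibrous carbohydrate to
neutral detergent fiber) ratios.

The package is aimed at epigenomics analysts who want every stage of such a
study — peak identification, replicate-reproducibility filtering, signal
normalization, enhancer/promoter classification, trend profiling, motif and
gene-set enrichment, and gene–trait correlation — as tested, composable
library functions rather than a chain of external tools, with a synthetic-data
generator that plants known ground truth so the whole pipeline can be
validated end to end.

## What it computes

- **Peak calling** — binned fragment coverage scored against a Poisson
  background (λ = median bin count), one-sided upper-tail p-values with
  Benjamini–Hochberg control, significant bins merged into peaks with summits.
- **IDR (irreproducible discovery rate)** — replicate peak scores are paired,
  rank-transformed, and fitted with a two-component Gaussian copula mixture
  (null: standard bivariate normal, ρ = 0; reproducible: N(μ, σ²) with
  correlation ρ) by EM. The posterior null probability is the local IDR;
  pairs are filtered on the running-mean (global) IDR.
- **Consensus peaks** — pooled-sample peaks retained when they absorb ≥ F
  (default 0.5) of an IDR peak's length, the `bedtools intersect -F`
  convention.
- **Signal matrix** — fragment counts per consensus peak, TPM-normalized
  within sample (columns sum to 10⁶) and divided by trimmed-mean-of-M-values
  (TMM) factors, cross-checked against edgeR.
- **CRE annotation** — H3K27ac peaks filtered for ATAC overlap, split into
  promoters (TSS window −1000/+500 bp, strand-aware, configurable) and
  enhancers, and annotated with a nine-way genomic feature and a six-bin
  signed TSS distance.
- **Dynamic enhancers and profiles** — coefficient-of-variation selection of
  the most variable enhancers, log₂ fold-change series anchored at the low
  (L) group, assignment to template profiles (0, a, b) by Pearson
  correlation, and an exact six-permutation enrichment test per profile.
- **Motifs** — PWM log-odds scanning of summit ± 100 bp windows on both
  strands (hit = 80 % of maximum score), ZOOPS hypergeometric enrichment of
  up- vs non-up-regulated enhancers, Z-scored −log₁₀ p matrices, and
  correlation-distance clustering with Newick export.
- **Region-to-gene association** — basal regulatory domains (−5 kb/+1 kb of
  the TSS) with nearest-TSS fallback under 1 Mb; hypergeometric term
  enrichment with BH control.
- **Expression and phenotypes** — FPKM, a defined differential-expression
  filter (fold change ≥ 2 and Welch-t p < 0.05 on log₂(FPKM+1)), three-way
  Venn partitions, sequencing-QC summaries, carcass/meat-quality formulas
  (dressing %, thaw and cooking loss, NFC/NDF ratio), and Spearman gene–trait
  networks with exact permutation p-values at small n.

## Worked example

Run the full pipeline on the default synthetic landscape (two 5-Mb
chromosomes, 400 genes, 600 regulatory sites, three groups × two replicates ×
two assays, a motif planted in up-trending enhancers):

```python
from enhancerscape.pipeline import run_pipeline
from enhancerscape.synthetic_data import SimConfig

result = run_pipeline(SimConfig(seed=1))
print("consensus H3K27ac peaks:", len(result.consensus["H3K27ac"]))
print("promoters / enhancers:", len(result.promoter_peaks), "/", len(result.enhancer_peaks))
print("up-enhancer recovery:", result.up_recovery)
print("planted motif rank:", result.motif_rank)
print("enhancer-vs-promoter variance p:", f"{result.variability_p:.2e}")
```

prints (seed 1):

```
consensus H3K27ac peaks: 477
promoters / enhancers: 231 / 246
up-enhancer recovery: 0.85
planted motif rank: 1
enhancer-vs-promoter variance p: 1.52e-37
```

That is: of 600 planted sites, 477 survive peak calling, IDR filtering and
consensus intersection (the generator deliberately makes ~10 % of sites
irreproducible); the promoter/enhancer split matches the planted
proximal/distal design; 85 % of planted up-trending enhancers are assigned an
up-direction profile; the planted motif ranks first among eleven scanned
PWMs; and enhancer signal is vastly more variable across diet groups than
promoter signal, as expected for distal regulatory elements.

The same stages are available from the shell:

```sh
enhancerscape simulate --seed 1 --outdir fixtures/
enhancerscape idr --rep1 a.narrowPeak --rep2 b.narrowPeak --threshold 0.05
enhancerscape consensus --pooled pooled.narrowPeak --idr idr.narrowPeak -F 0.5
enhancerscape annotate --k27 k27.narrowPeak --atac atac.narrowPeak --genes genes.gff3
enhancerscape run --seed 1 --out summary.json
```

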