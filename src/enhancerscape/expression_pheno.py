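"""RNA-seq-side statistics, carcass/meat phenotype formulas and gene-trait networks.

Expression is summarized as FPKM; differential expression between ordered
diet groups uses a defined, reproducible statistic (linear fold change of
pseudocounted group means plus a two-sided Welch t-test on log2(FPKM + 1)),
with genes carrying missing values excluded up front.  Phenotype formulas
follow the standard carcass and meat-quality definitions: dressing
percentage, thawing loss, cooking loss, and the dietary NFC/NDF ratio.
Gene-trait association uses Spearman rank correlation (exact permutation
p-values at small n) with BH adjustment; trait-trait structure uses Pearson.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import itertools
import math
import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import bh_adjust

__all__ = [
    "ExpressionMatrix",
    "DEGRecord",
    "SampleQC",
    "TraitRecord",
    "CorrelationEdge",
    "fpkm",
    "de_filter",
    "venn_intersect",
    "qc_summary",
    "pheno_formulas",
    "gene_trait_network",
    "load_diet_composition",
    "load_rnaseq_qc",
    "round2",
]


@dataclasses.dataclass
class ExpressionMatrix:
    counts: pd.DataFrame  # genes x samples
    lengths: pd.Series  # bp per gene
    mapped_totals: pd.Series  # mapped reads per sample

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("counts rows and lengths index differ")
        if list(self.counts.columns) != list(self.mapped_totals.index):
            raise ValueError("counts columns and mapped_totals index differ")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.fillna(0).to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")


@dataclasses.dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    comparison: str  # HvsM | HvsL | MvsL
    log2fc: float
    pvalue: float
    passes: bool


@dataclasses.dataclass(frozen=True)
class SampleQC:
    sample_id: str
    raw_reads: float  # millions
    clean_reads: float
    q20: float
    q30: float
    gc: float

    def __post_init__(self) -> None:
        if self.clean_reads > self.raw_reads:
            raise ValueError("clean reads cannot exceed raw reads")
        for v in (self.q20, self.q30, self.gc):
            if not (0 <= v <= 100):
                raise ValueError("percentages must be in [0, 100]")


@dataclasses.dataclass
class TraitRecord:
    sample_id: str
    live_weight: float | None = None  # kg
    carcass_weight: float | None = None
    pre_freeze_weight: float | None = None  # g
    post_thaw_weight: float | None = None
    pre_cook_weight: float | None = None
    post_cook_weight: float | None = None
    nfc_pct: float | None = None
    ndf_pct: float | None = None


@dataclasses.dataclass(frozen=True)
class CorrelationEdge:
    gene_id: str
    trait: str
    rho: float
    pvalue: float
    qvalue: float
    sign: int


def round2(x: float) -> float:
    """Round half-up to 2 decimals (matching printed-table precision)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def fpkm(expr: ExpressionMatrix) -> pd.DataFrame:
    """FPKM = count / (length in kb x mapped reads in millions)."""
    if (expr.mapped_totals <= 0).any():
        raise ValueError("mapped totals must be positive")
    denom = np.outer(expr.lengths / 1_000.0, expr.mapped_totals / 1e6)
    return expr.counts / pd.DataFrame(denom, index=expr.counts.index, columns=expr.counts.columns)


def de_filter(
    fpkm_matrix: pd.DataFrame,
    groups: dict[str, list[str]],
    comparison: str,
    fc_min: float = 2.0,
    alpha: float = 0.05,
) -> list[DEGRecord]:
    """Differential-expression filter for one pairwise comparison.

    ``comparison`` is of the form "HvsL" (B vs A).  A gene passes when its
    linear fold change ``max(r, 1/r)`` of pseudocounted group means reaches
    ``fc_min`` and the two-sided Welch t on log2(FPKM + 1) gives p < alpha.
    """
    b_name, a_name = comparison.split("vs")
    for g in (a_name, b_name):
        if len(groups.get(g, [])) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
    mat = fpkm_matrix.dropna(axis=0)  # genes with missing values excluded
    a = mat[groups[a_name]]
    b = mat[groups[b_name]]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + 1.0) / (mean_a + 1.0))
    la = np.log2(a + 1.0)
    lb = np.log2(b + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    pvals = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)
    records = []
    for i, gene in enumerate(mat.index):
        fc = float(log2fc.iloc[i])
        p = float(pvals[i])
        passes = abs(fc) >= math.log2(fc_min) and p < alpha
        records.append(DEGRecord(gene, comparison, fc, p, passes))
    return records


def venn_intersect(
    set_hm: set[str], set_hl: set[str], set_ml: set[str]
) -> tuple[dict[str, int], set[str]]:
    """Seven-region Venn counts for three DEG sets plus the triple intersection."""
    regions = {
        "HvsM_only": len(set_hm - set_hl - set_ml),
        "HvsL_only": len(set_hl - set_hm - set_ml),
        "MvsL_only": len(set_ml - set_hm - set_hl),
        "HvsM_HvsL": len((set_hm & set_hl) - set_ml),
        "HvsM_MvsL": len((set_hm & set_ml) - set_hl),
        "HvsL_MvsL": len((set_hl & set_ml) - set_hm),
        "all_three": len(set_hm & set_hl & set_ml),
    }
    return regions, set_hm & set_hl & set_ml


def qc_summary(records: list[SampleQC]) -> pd.DataFrame:
    """Per-metric min/max/mean (mean rounded half-up to 2 decimals)."""
    if not records:
        raise ValueError("no QC records")
    df = pd.DataFrame(
        {
            "raw_reads": [r.raw_reads for r in records],
            "clean_reads": [r.clean_reads for r in records],
            "q20": [r.q20 for r in records],
            "q30": [r.q30 for r in records],
            "gc": [r.gc for r in records],
        }
    )
    return pd.DataFrame(
        {
            "min": df.min(),
            "max": df.max(),
            "mean": [round2(v) for v in df.mean()],
        }
    )


def pheno_formulas(record: TraitRecord) -> dict[str, float]:
    """Derived phenotype quantities from one trait record.

    dressing_pct = carcass / live x 100; thaw/cook loss are percent weight
    lost relative to the pre-treatment weight; nfc_ndf_ratio is reported to
    2 decimals like the diet table.
    """
    out: dict[str, float] = {}
    if record.carcass_weight is not None and record.live_weight is not None:
        if record.live_weight <= 0:
            raise ValueError("live weight must be positive")
        out["dressing_pct"] = record.carcass_weight / record.live_weight * 100.0
    if record.pre_freeze_weight is not None and record.post_thaw_weight is not None:
        if record.pre_freeze_weight <= 0:
            raise ValueError("pre-freezing weight must be positive")
        out["thaw_loss_pct"] = (
            (record.pre_freeze_weight - record.post_thaw_weight)
            / record.pre_freeze_weight
            * 100.0
        )
    if record.pre_cook_weight is not None and record.post_cook_weight is not None:
        if record.pre_cook_weight <= 0:
            raise ValueError("pre-cooking weight must be positive")
        out["cook_loss_pct"] = (
            (record.pre_cook_weight - record.post_cook_weight)
            / record.pre_cook_weight
            * 100.0
        )
    if record.nfc_pct is not None and record.ndf_pct is not None:
        if record.ndf_pct <= 0:
            raise ValueError("NDF percent must be positive")
        out["nfc_ndf_ratio"] = round2(record.nfc_pct / record.ndf_pct)
    return out


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        return float("nan")
    return float((rxc @ ryc) / denom)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 8)."""
    n = len(x)
    ry = stats.rankdata(y, method="average")
    rx = stats.rankdata(x, method="average")
    rxc = rx - rx.mean()
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        ryp = ry[list(perm)]
        ryc = ryp - ryp.mean()
        denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
        r = (rxc @ ryc) / denom
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def gene_trait_network(
    expr: pd.DataFrame,
    traits: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "spearman",
) -> tuple[list[CorrelationEdge], pd.DataFrame]:
    """Gene-trait correlation edges plus the trait-trait Pearson matrix.

    ``expr`` is genes x samples (core genes), ``traits`` samples x traits on
    the same samples.  Rank correlation is primary (``method='pearson'``
    available); p-values are exact by permutation for n <= 8, otherwise the
    t approximation; edges require BH q < ``alpha``.
    """
    samples = [s for s in expr.columns if s in traits.index]
    if len(samples) < 4:
        raise ValueError("need >= 4 paired observations")
    rows = []
    for gene in expr.index:
        x = expr.loc[gene, samples].to_numpy(dtype=float)
        for trait in traits.columns:
            y = traits.loc[samples, trait].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"zero-variance vector for ({gene}, {trait}); edge omitted",
                    RuntimeWarning,
                )
                continue
            if method == "pearson":
                r, p = stats.pearsonr(x, y)
            else:
                r = _spearman_rho(x, y)
                if len(samples) <= 8:
                    p = _spearman_exact_p(x, y, r)
                else:
                    p = stats.spearmanr(x, y).pvalue
            rows.append((gene, trait, float(r), float(p)))
    qs = bh_adjust(np.array([r[3] for r in rows])) if rows else np.array([])
    edges = [
        CorrelationEdge(g, t, rho, p, float(q), 1 if rho >= 0 else -1)
        for (g, t, rho, p), q in zip(rows, qs)
        if q < alpha
    ]
    trait_corr = traits.loc[samples].corr(method="pearson")
    return edges, trait_corr


def _data_path(name: str):
    return importlib.resources.files("enhancerscape.data") / name


def load_diet_composition() -> pd.DataFrame:
    """Analyzed diet composition per group (percent of dry matter)."""
    with importlib.resources.as_file(_data_path("diet_composition.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col=0)


def load_rnaseq_qc() -> list[SampleQC]:
    """The nine-sample RNA-seq sequencing QC table."""
    with importlib.resources.as_file(_data_path("rnaseq_qc.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return [
        SampleQC(r.sample, r.raw_reads, r.clean_reads, r.q20, r.q30, r.gc)
        for r in df.itertuples()
    ]
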