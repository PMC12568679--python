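"""PWM scanning of summit-centred windows and motif enrichment.

Scanning scores every offset on both strands with a log2-odds sum against the
background base composition (probability floor 1e-3); a hit requires at
least ``score_fraction`` (default 0.8) of the maximum achievable score.
Enrichment counts sequences (ZOOPS: a sequence counts once) and compares
target vs background sets with a hypergeometric upper tail, BH-adjusted
across motifs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .genome_io import Peak
from .peaks import bh_adjust

__all__ = [
    "PWM",
    "MotifHit",
    "EnrichmentResult",
    "read_jaspar",
    "write_jaspar",
    "extract_summit_windows",
    "scan_pwm",
    "motif_enrichment",
    "cluster_motifs",
    "hypergeom_upper_tail",
]

BASES = "ACGT"
PROB_FLOOR = 1e-3
_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


@dataclasses.dataclass
class PWM:
    """Position probability matrix over A/C/G/T with a background composition."""

    motif_id: str
    matrix: np.ndarray  # length x 4, rows sum to 1
    background: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be length x 4")
        if len(self) < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("matrix rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = np.maximum(self.matrix, PROB_FLOOR)
        bg = np.maximum(self.background, PROB_FLOOR)
        return np.log2(p / bg)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclasses.dataclass(frozen=True)
class MotifHit:
    seq_id: str
    position: int
    strand: str
    score: float


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    """Generic over-representation record (motif or term)."""

    unit_id: str
    k: int  # target hits
    n: int  # target size
    K: int  # universe hits
    N: int  # universe size
    fold: float
    pvalue: float
    qvalue: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.k <= self.n <= self.N and self.k <= self.K <= self.N):
            raise ValueError("inconsistent contingency counts")


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) drawing n from a universe of N with K successes."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def read_jaspar(path: str | Path) -> list[PWM]:
    """Read JASPAR-format PFM/PPM records (via Bio.motifs) into :class:`PWM`."""
    from Bio import motifs as bio_motifs

    pwms = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float).T
            probs = counts / counts.sum(axis=1, keepdims=True)
            pwms.append(PWM(m.matrix_id or m.name, probs))
    return pwms


def write_jaspar(pwms: Sequence[PWM], path: str | Path, scale: int = 100) -> None:
    """Write PWMs as JASPAR count matrices (probabilities scaled by ``scale``)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
            for j, b in enumerate(BASES):
                vals = " ".join(f"{v * scale:.0f}" for v in pwm.matrix[:, j])
                fh.write(f"{b} [ {vals} ]\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_summit_windows(
    peaks: list[Peak], genome_fasta, flank: int = 100
) -> dict[str, str]:
    """Uppercase sequence of ``[summit - flank, summit + flank)`` per peak.

    ``genome_fasta`` is a ``pyfaidx.Fasta`` (or path to one) or a plain
    ``dict[chrom, sequence]``.  Windows are clipped at chromosome ends.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if isinstance(genome_fasta, (str, Path)):
        from pyfaidx import Fasta

        genome_fasta = Fasta(str(genome_fasta))
    out: dict[str, str] = {}
    for p in peaks:
        ref = genome_fasta[p.chrom]
        chrom_len = len(ref)
        if not (0 <= p.summit < chrom_len):
            raise ValueError(f"summit {p.summit} outside {p.chrom} (len {chrom_len})")
        lo = max(0, p.summit - flank)
        hi = min(chrom_len, p.summit + flank)
        seq = ref[lo:hi]
        out[p.name] = str(seq).upper()
    return out


def _scores_one_strand(seq: str, lo_matrix: np.ndarray) -> np.ndarray:
    L = lo_matrix.shape[0]
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        code[ord(b)] = i
    enc = code[idx]
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        window = enc[j : j + n]
        bad = window < 0
        valid &= ~bad
        scores += lo_matrix[j, np.where(bad, 0, window)]
    scores[~valid] = -np.inf
    return scores


def scan_pwm(
    sequence: str, pwm: PWM, score_fraction: float = 0.8, seq_id: str = "."
) -> list[MotifHit]:
    """Log-odds scan of both strands; hits reach ``score_fraction`` of max score.

    A minus-strand hit at position i refers to the window starting at i on the
    forward sequence whose reverse complement matches the motif.
    """
    if not (0 < score_fraction <= 1):
        raise ValueError("score_fraction must be in (0, 1]")
    seq = sequence.upper()
    L = len(pwm)
    if len(seq) < L:
        return []
    threshold = score_fraction * pwm.max_score
    lo = pwm.log_odds
    hits: list[MotifHit] = []
    fwd = _scores_one_strand(seq, lo)
    rc = _scores_one_strand(reverse_complement(seq), lo)
    n = len(seq) - L + 1
    for i in range(n):
        if fwd[i] >= threshold:
            hits.append(MotifHit(seq_id, i, "+", float(fwd[i])))
        # window [i, i+L) on '-' strand corresponds to rc offset n-1-i
        if rc[n - 1 - i] >= threshold:
            hits.append(MotifHit(seq_id, i, "-", float(rc[n - 1 - i])))
    return hits


def has_hit(sequence: str, pwm: PWM, score_fraction: float = 0.8) -> bool:
    seq = sequence.upper()
    L = len(pwm)
    if len(seq) < L:
        return False
    threshold = score_fraction * pwm.max_score
    lo = pwm.log_odds
    fwd = _scores_one_strand(seq, lo)
    if fwd.size and fwd.max() >= threshold:
        return True
    rc = _scores_one_strand(reverse_complement(seq), lo)
    return bool(rc.size and rc.max() >= threshold)


def motif_enrichment(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    pwms: Sequence[PWM],
    score_fraction: float = 0.8,
) -> list[EnrichmentResult]:
    """ZOOPS hypergeometric enrichment of each motif in target vs background."""
    if not target_seqs or not background_seqs:
        raise ValueError("target and background sets must be non-empty")
    if set(target_seqs) & set(background_seqs):
        raise ValueError("target and background ids must be disjoint")
    n = len(target_seqs)
    N = n + len(background_seqs)
    results = []
    for pwm in pwms:
        k = sum(has_hit(s, pwm, score_fraction) for s in target_seqs.values())
        K = k + sum(has_hit(s, pwm, score_fraction) for s in background_seqs.values())
        p = hypergeom_upper_tail(k, n, K, N)
        fold = (k / n) / (K / N) if K > 0 else 0.0
        results.append(
            EnrichmentResult(pwm.motif_id, k=k, n=n, K=K, N=N, fold=fold, pvalue=p)
        )
    qs = bh_adjust(np.array([r.pvalue for r in results]))
    return [dataclasses.replace(r, qvalue=float(q)) for r, q in zip(results, qs)]


def cluster_motifs(neglog_p: "pd.DataFrame"):
    """Z-score rows and cluster motifs by correlation distance (average linkage).

    ``neglog_p`` is a motifs x peak-sets matrix of -log10 p-values.  Returns
    ``(zscores, linkage_matrix, leaf_order)`` with a deterministic leaf order
    (ties broken by motif id via lexicographic input ordering).
    """
    import pandas as pd
    from scipy.cluster import hierarchy

    if neglog_p.shape[0] < 2 or neglog_p.shape[1] < 2:
        raise ValueError("need >= 2 motifs and >= 2 peak-sets")
    neglog_p = neglog_p.sort_index()  # deterministic tie-break on motif id
    X = neglog_p.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    z = (X - X.mean(axis=1, keepdims=True)) / np.maximum(sd, 1e-12)[:, None]
    zscores = pd.DataFrame(z, index=neglog_p.index, columns=neglog_p.columns)

    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    norm = np.maximum(norm, 1e-12)
    corr = (Xc @ Xc.T) / np.outer(norm, norm)
    dist = 1.0 - corr
    iu = np.triu_indices(len(dist), k=1)
    link = hierarchy.linkage(np.maximum(dist[iu], 0.0), method="average")
    order = [neglog_p.index[i] for i in hierarchy.leaves_list(link)]
    return zscores, link, order


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    from scipy.cluster import hierarchy

    tree = hierarchy.to_tree(link)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return rec(tree) + ";"
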