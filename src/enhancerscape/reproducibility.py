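"""Within-group reproducibility filtering (IDR) and consensus-peak derivation.

The irreproducible discovery rate model treats replicate peak scores as draws
from a two-component Gaussian copula mixture: scores are rank-transformed to
normal scores per replicate, the irreproducible (null) component is standard
bivariate normal with correlation 0, and the reproducible component is
bivariate normal with common mean ``mu``, variance ``sigma**2`` and
correlation ``rho``.  The posterior probability of the null component is the
local IDR; the global IDR of a pair is the running mean of local IDRs over
the pairs at least as reproducible.

Consensus peaks follow the three-step recipe used with pooled samples: call
peaks on the pooled fragments, then keep pooled peaks that absorb at least a
fraction ``F`` of some reproducible (IDR-passing) peak's length.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from .genome_io import FragmentSet, GenomicInterval, Peak, sort_peaks
from .peaks import call_peaks, make_coverage

__all__ = [
    "IDRModel",
    "IDRResult",
    "pair_replicate_peaks",
    "fit_idr",
    "idr_filter",
    "consensus_peaks",
    "filter_by_idr_overlap",
]

MIN_PAIRS = 50


@dataclasses.dataclass
class IDRModel:
    """Fitted copula-mixture parameters.

    Attributes use the estimator convention of trailing underscores on the
    fitted values exposed via :meth:`fit`.
    """

    pi1: float
    rho: float
    mu: float
    sigma: float
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pi1 <= 1):
            raise ValueError("pi1 must be in [0, 1]")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.mu < 0 or self.sigma <= 0:
            raise ValueError("need mu >= 0 and sigma > 0")


@dataclasses.dataclass
class IDRResult:
    """Per-pair local/global IDR values plus the fitted model.

    ``pairs`` holds ``(item1, item2, local_idr, global_idr)`` in input order;
    items are whatever was scored (typically :class:`Peak`).
    """

    pairs: list[tuple]
    model: IDRModel


def _pair_key(p1: Peak, p2: Peak) -> tuple:
    return (
        abs(p1.summit - p2.summit),
        -p1.interval.overlap(p2.interval),
        p1.chrom,
        p1.start,
        p2.start,
    )


def pair_replicate_peaks(rep1: list[Peak], rep2: list[Peak]) -> list[tuple[Peak, Peak]]:
    """Match mutually overlapping peaks one-to-one between two replicates.

    Candidate pairs are all overlapping peak pairs; matching is greedy by
    smallest summit distance, then larger overlap, then lower coordinate, so
    each peak joins at most one pair.
    """
    candidates: list[tuple[tuple, Peak, Peak]] = []
    by_chrom: dict[str, list[Peak]] = {}
    for p in rep2:
        by_chrom.setdefault(p.chrom, []).append(p)
    for peaks in by_chrom.values():
        peaks.sort(key=lambda p: p.start)
    for p1 in rep1:
        others = by_chrom.get(p1.chrom, [])
        for p2 in others:
            if p2.start >= p1.end:
                break
            if p1.interval.overlap(p2.interval) > 0:
                candidates.append((_pair_key(p1, p2), p1, p2))
    candidates.sort(key=lambda c: c[0])
    used1: set[int] = set()
    used2: set[int] = set()
    pairs: list[tuple[Peak, Peak]] = []
    for _, p1, p2 in candidates:
        if id(p1) in used1 or id(p2) in used2:
            continue
        used1.add(id(p1))
        used2.add(id(p2))
        pairs.append((p1, p2))
    pairs.sort(key=lambda pr: (pr[0].chrom, pr[0].start, pr[1].start))
    return pairs


def _uniform_ranks(scores: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(scores, method="average")
    return ranks / (len(scores) + 1)


def _log_bvn(x: np.ndarray, y: np.ndarray, mu: float, sigma: float, rho: float) -> np.ndarray:
    """Log density of a symmetric bivariate normal with common mean/variance."""
    det = sigma**4 * (1 - rho**2)
    dx = x - mu
    dy = y - mu
    quad = (dx**2 - 2 * rho * dx * dy + dy**2) / (sigma**2 * (1 - rho**2))
    return -np.log(2 * np.pi) - 0.5 * np.log(det) - 0.5 * quad


def _em_one_start(
    u1: np.ndarray,
    u2: np.ndarray,
    init: tuple[float, float, float, float],
    tol: float,
    max_iter: int,
) -> tuple:
    pi1, mu, sigma, rho = init
    prev_params = None
    converged = False
    it = 0
    w = np.full_like(u1, pi1)
    ll = -np.inf
    for it in range(1, max_iter + 1):
        # pseudo-data: ranks mapped through the current mixture marginal
        # (one shared quantile grid serves both margins)
        lo = min(-6.0, mu - 6 * sigma)
        hi = max(6.0, mu + 6 * sigma)
        t_grid = np.linspace(lo, hi, 2048)
        G = pi1 * stats.norm.cdf((t_grid - mu) / sigma) + (1 - pi1) * stats.norm.cdf(
            t_grid
        )
        x = np.interp(u1, G, t_grid)
        y = np.interp(u2, G, t_grid)
        log_f0 = stats.norm.logpdf(x) + stats.norm.logpdf(y)
        log_f1 = _log_bvn(x, y, mu, sigma, rho)
        log_num = np.log(max(pi1, 1e-300)) + log_f1
        log_den = np.logaddexp(log_num, np.log(max(1 - pi1, 1e-300)) + log_f0)
        w = np.exp(log_num - log_den)  # responsibility of reproducible comp.
        ll = float(np.sum(log_den))
        params = np.array([pi1, mu, sigma, rho])
        if prev_params is not None and np.max(np.abs(params - prev_params)) < tol:
            converged = True
            break
        prev_params = params
        wsum = max(w.sum(), 1e-12)
        # small pseudo-count penalty on the mixing weight: harmless when the
        # reproducible component is identifiable, resolves the pi1 ridge
        # toward 0 when the two components coincide (pure-null input)
        kappa = 0.02 * len(w)
        pi1 = float(np.clip(w.sum() / (len(w) + kappa), 1e-6, 1 - 1e-6))
        mu = float(max(0.0, np.sum(w * (x + y)) / (2 * wsum)))
        var = float(np.sum(w * ((x - mu) ** 2 + (y - mu) ** 2)) / (2 * wsum))
        sigma = float(np.sqrt(max(var, 0.09)))  # floor guards collapse
        rho = float(
            np.clip(np.sum(w * (x - mu) * (y - mu)) / (wsum * sigma**2), 0.0, 0.999)
        )
    return pi1, mu, sigma, rho, w, converged, it, ll


def fit_idr(
    score_pairs: list[tuple],
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> IDRResult:
    """Fit the copula mixture to replicate score pairs by EM.

    ``score_pairs`` is a list of ``(item1, item2, score1, score2)`` or bare
    ``(score1, score2)`` tuples.  Being rank-based, the fit is invariant to
    strictly monotone transforms of either score list.
    """
    if len(score_pairs) < MIN_PAIRS:
        raise ValueError(f"need >= {MIN_PAIRS} pairs, got {len(score_pairs)}")
    first = score_pairs[0]
    if len(first) == 4:
        items1 = [p[0] for p in score_pairs]
        items2 = [p[1] for p in score_pairs]
        s1 = np.array([p[2] for p in score_pairs], dtype=float)
        s2 = np.array([p[3] for p in score_pairs], dtype=float)
    else:
        items1 = items2 = [None] * len(score_pairs)
        s1 = np.array([p[0] for p in score_pairs], dtype=float)
        s2 = np.array([p[1] for p in score_pairs], dtype=float)
    if np.ptp(s1) == 0 or np.ptp(s2) == 0:
        raise ValueError("degenerate scores: all values equal in one replicate")

    u1 = _uniform_ranks(s1)
    u2 = _uniform_ranks(s2)

    # deterministic multi-start: one generic, one high-correlation, one
    # sparse-reproducible init; the fit with the best final pseudo
    # log-likelihood wins (EM on the adaptive pseudo-data can stall in a
    # start-dependent local solution)
    inits = [
        (0.5, 1.0, 1.0, 0.5),
        (0.9, 0.5, 1.0, 0.95),
        (0.1, 2.0, 1.0, 0.8),
        (0.95, 0.0, 1.0, 0.99),  # near-comonotone scores
    ]
    best = None
    for init in inits:
        fitted = _em_one_start(u1, u2, init, tol=tol, max_iter=max_iter)
        if best is None or fitted[-1] > best[-1]:
            best = fitted
    pi1, mu, sigma, rho, w, converged, it, _ll = best
    if not converged:
        warnings.warn("IDR EM did not converge; returning best iterate", RuntimeWarning)

    local_idr = 1.0 - w
    order = np.argsort(local_idr, kind="stable")
    global_sorted = np.cumsum(local_idr[order]) / np.arange(1, len(local_idr) + 1)
    global_idr = np.empty_like(local_idr)
    global_idr[order] = global_sorted

    model = IDRModel(pi1=pi1, rho=rho, mu=mu, sigma=sigma, converged=converged, n_iter=it)
    pairs = [
        (items1[i], items2[i], float(local_idr[i]), float(global_idr[i]))
        for i in range(len(local_idr))
    ]
    return IDRResult(pairs=pairs, model=model)


def idr_filter(result: IDRResult, threshold: float = 0.05) -> list[Peak]:
    """Keep pairs with global IDR <= threshold; return the union-interval peaks.

    The retained peak spans the union of the pair's intervals and inherits the
    summit of the higher-scoring member.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    kept: list[Peak] = []
    for p1, p2, _local, glob in result.pairs:
        if glob > threshold:
            continue
        if p1 is None or p2 is None:
            raise ValueError("idr_filter needs peak-bearing pairs")
        iv = GenomicInterval(p1.chrom, min(p1.start, p2.start), max(p1.end, p2.end))
        best = p1 if p1.score >= p2.score else p2
        kept.append(Peak(iv, summit=best.summit, score=best.score, name=best.name))
    return sort_peaks(kept)


def filter_by_idr_overlap(
    pooled_peaks: list[Peak], idr_peaks: list[Peak], fraction_F: float = 0.5
) -> list[Peak]:
    """Retain pooled peaks covering >= ``fraction_F`` of some IDR peak's length.

    Mirrors ``bedtools intersect -F`` semantics: the fraction is of the IDR
    (B-file) feature, and the bound is inclusive.
    """
    if not (0 < fraction_F <= 1):
        raise ValueError("fraction_F must be in (0, 1]")
    if not idr_peaks:
        warnings.warn("empty IDR peak set: consensus is empty", RuntimeWarning)
        return []
    by_chrom: dict[str, list[Peak]] = {}
    for p in idr_peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    kept = []
    for pooled in pooled_peaks:
        for ip in by_chrom.get(pooled.chrom, []):
            ov = pooled.interval.overlap(ip.interval)
            if ov / len(ip.interval) >= fraction_F:
                kept.append(pooled)
                break
    return sort_peaks(kept)


def consensus_peaks(
    pooled_fragments: list[FragmentSet],
    idr_peaks: list[Peak],
    genome: dict[str, int],
    *,
    alpha: float = 0.05,
    fraction_F: float = 0.5,
    bin_size: int = 100,
) -> list[Peak]:
    """Three-step consensus: pool fragments, call peaks, keep IDR-supported ones."""
    all_frags: list[GenomicInterval] = []
    for fs in pooled_fragments:
        all_frags.extend(fs.fragments)
    tracks = make_coverage(all_frags, bin_size, genome)
    pooled: list[Peak] = []
    for chrom in sorted(tracks):
        pooled.extend(c.peak for c in call_peaks(tracks[chrom], alpha=alpha))
    return filter_by_idr_overlap(pooled, idr_peaks, fraction_F)
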