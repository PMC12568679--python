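"""Peak x sample counting and normalization (TPM + trimmed-mean scaling).

Counts are length-normalized within each sample to TPM (each column sums to
1e6) and then divided by a between-sample trimmed-mean-of-M-values (TMM)
factor so that depth and composition effects cancel.  The TMM scheme is the
standard one: M/A values against a reference column, double trimming on M and
A, precision-weighted mean M, factors rescaled to geometric mean 1.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .genome_io import FragmentSet, GenomicInterval, Peak, sort_peaks

__all__ = [
    "CountMatrix",
    "merge_overlapping",
    "count_in_peaks",
    "tpm_normalize",
    "tmm_factors",
    "normalize_signal",
]


@dataclasses.dataclass
class CountMatrix:
    """Nonnegative integer fragment counts with per-peak lengths in bp."""

    counts: pd.DataFrame  # rows: peak ids, cols: sample ids
    lengths: pd.Series  # bp, indexed like rows

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("counts rows and lengths index differ")
        if (self.lengths <= 0).any():
            raise ValueError("peak lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")


def merge_overlapping(peaks: list[Peak]) -> list[Peak]:
    """Interval-merge overlapping peaks (same chromosome, >= 1 bp overlap).

    The merged peak keeps the summit and score of its highest-scoring member
    and a name derived from the first member.
    """
    merged: list[Peak] = []
    for p in sort_peaks(peaks):
        if merged and merged[-1].chrom == p.chrom and p.start < merged[-1].end:
            prev = merged[-1]
            best = prev if prev.score >= p.score else p
            merged[-1] = Peak(
                GenomicInterval(p.chrom, prev.start, max(prev.end, p.end)),
                summit=best.summit,
                score=best.score,
                name=prev.name,
            )
        else:
            merged.append(p)
    return merged


def count_in_peaks(peaks: list[Peak], fragment_sets: list[FragmentSet]) -> CountMatrix:
    """Count fragments per (merged) peak and sample.

    A fragment counts for a peak when they overlap by >= 1 bp; a fragment
    overlapping two peaks counts once, for the larger overlap (ties go to the
    lower-coordinate peak).
    """
    peaks = merge_overlapping(peaks)
    ids = [p.name for p in peaks]
    if len(set(ids)) != len(ids):  # ensure unique row ids
        ids = [f"{p.name}_{i}" for i, p in enumerate(peaks)]
    lengths = pd.Series([len(p.interval) for p in peaks], index=ids, dtype=int)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in peaks}:
        idx = np.array([i for i, p in enumerate(peaks) if p.chrom == chrom])
        starts = np.array([peaks[i].start for i in idx])
        ends = np.array([peaks[i].end for i in idx])
        by_chrom[chrom] = (starts, ends, idx)

    data = {}
    for fs in fragment_sets:
        col = np.zeros(len(peaks), dtype=np.int64)
        frags_by_chrom: dict[str, list[GenomicInterval]] = {}
        for f in fs.fragments:
            frags_by_chrom.setdefault(f.chrom, []).append(f)
        for chrom, frags in frags_by_chrom.items():
            if chrom not in by_chrom:
                continue
            starts, ends, idx = by_chrom[chrom]
            fs_arr = np.array([f.start for f in frags])
            fe_arr = np.array([f.end for f in frags])
            lo = np.searchsorted(ends, fs_arr, side="right")
            hi = np.searchsorted(starts, fe_arr, side="left") - 1
            for k in range(len(frags)):
                a, b = lo[k], hi[k]
                if b < a:
                    continue
                if b == a:
                    col[idx[a]] += 1
                else:
                    ovs = np.minimum(ends[a : b + 1], fe_arr[k]) - np.maximum(
                        starts[a : b + 1], fs_arr[k]
                    )
                    col[idx[a + int(np.argmax(ovs))]] += 1
        data[fs.sample_id] = col
    counts = pd.DataFrame(data, index=ids)
    return CountMatrix(counts=counts, lengths=lengths)


def tpm_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Length- and depth-normalize: each column of the result sums to 1e6."""
    rate = cm.counts.div(cm.lengths / 1000.0, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"all-zero column(s): {list(zero.index)}")
    return rate.div(colsum, axis=1) * 1e6


def tmm_factors(
    cm: CountMatrix,
    ref_sample: str | None = None,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference column is the one whose 75th percentile of count/library
    size is closest to the mean of those percentiles.  For each sample,
    M = log2 relative abundance vs the reference and A = average log
    abundance are computed over rows nonzero in both; the extreme
    ``trim_M``/``trim_A`` fractions are discarded from each tail and the
    factor is 2 to the precision-weighted mean of the remaining M values.
    """
    if not (0 <= trim_M < 0.5 and 0 <= trim_A < 0.5):
        raise ValueError("trim fractions must be in [0, 0.5)")
    counts = cm.counts.to_numpy(dtype=float)
    samples = list(cm.counts.columns)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    if ref_sample is None:
        f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(len(samples))])
        ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_j = samples.index(ref_sample)

    factors = np.ones(len(samples))
    ref = counts[:, ref_j]
    for j in range(len(samples)):
        if j == ref_j:
            continue
        obs = counts[:, j]
        ok = (obs > 0) & (ref > 0)
        p_o = obs[ok] / lib[j]
        p_r = ref[ok] / lib[ref_j]
        M = np.log2(p_o / p_r)
        A = 0.5 * np.log2(p_o * p_r)
        w = (lib[j] - obs[ok]) / (lib[j] * obs[ok]) + (lib[ref_j] - ref[ok]) / (
            lib[ref_j] * ref[ok]
        )
        n = M.size
        if n < 10:
            warnings.warn(
                f"sample {samples[j]}: <10 usable rows for TMM; factor set to 1",
                RuntimeWarning,
            )
            continue
        rM = pd.Series(M).rank().to_numpy()
        rA = pd.Series(A).rank().to_numpy()
        loM = np.floor(n * trim_M) + 1
        hiM = n + 1 - loM
        loA = np.floor(n * trim_A) + 1
        hiA = n + 1 - loA
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if keep.sum() < 10:
            warnings.warn(
                f"sample {samples[j]}: <10 rows after trimming; factor set to 1",
                RuntimeWarning,
            )
            continue
        with np.errstate(divide="ignore"):
            wm = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[j] = 2.0**wm
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples)


def normalize_signal(cm: CountMatrix) -> pd.DataFrame:
    """Final signal matrix: TPM within sample, divided by the TMM factor."""
    tpm = tpm_normalize(cm)
    factors = tmm_factors(cm)
    return tpm.div(factors, axis=1)
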