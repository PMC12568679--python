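"""Minimal Poisson-window peak caller operating on binned fragment coverage.

The caller models the background as a single Poisson rate taken from the
median bin count (robust to a minority of enriched bins), scores every bin
with a one-sided Poisson upper tail, adjusts across bins with
Benjamini-Hochberg and merges runs of significant bins into peaks.  This is a
deliberately simple, fully specified stand-in for a production caller: no
local-lambda cascade, no fragment-model estimation, no control track.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
from scipy import stats

from .genome_io import FragmentSet, GenomicInterval, Peak

__all__ = ["CoverageTrack", "PeakCall", "make_coverage", "call_peaks", "bh_adjust"]

LAMBDA_FLOOR = 0.1


@dataclasses.dataclass
class CoverageTrack:
    """Per-bin fragment counts tiling one chromosome."""

    chrom: str
    bin_size: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")


@dataclasses.dataclass(frozen=True)
class PeakCall:
    peak: Peak
    pvalue: float
    qvalue: float

    def __post_init__(self) -> None:
        if not (0 < self.pvalue <= 1):
            raise ValueError("pvalue must be in (0, 1]")
        if self.qvalue < self.pvalue - 1e-12:
            raise ValueError("qvalue must be >= pvalue")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def make_coverage(
    fragments: FragmentSet | Iterable[GenomicInterval],
    bin_size: int,
    genome: dict[str, int],
) -> dict[str, CoverageTrack]:
    """Binned coverage per chromosome; a fragment increments every bin it overlaps."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    frags = fragments.fragments if isinstance(fragments, FragmentSet) else list(fragments)
    tracks = {
        chrom: CoverageTrack(chrom, bin_size, np.zeros(-(-length // bin_size), dtype=np.int64))
        for chrom, length in genome.items()
    }
    for f in frags:
        if f.chrom not in tracks:
            raise ValueError(f"fragment on unknown chromosome {f.chrom!r}")
        track = tracks[f.chrom]
        if f.end > genome[f.chrom]:
            raise ValueError(
                f"fragment {f.chrom}:{f.start}-{f.end} outside genome "
                f"(length {genome[f.chrom]})"
            )
        first = f.start // bin_size
        last = (f.end - 1) // bin_size  # end is exclusive
        track.counts[first : last + 1] += 1
    return tracks


def call_peaks(track: CoverageTrack, alpha: float = 0.05) -> list[PeakCall]:
    """Call enriched windows on one coverage track.

    Background rate is the median bin count (floored at 0.1); per-bin p-value
    is the one-sided Poisson upper tail P(X >= count); BH-significant adjacent
    bins are merged.  The summit is the leftmost bp of the highest-count bin in
    the peak; the score is -log10 of the best bin p-value.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    counts = np.asarray(track.counts, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("empty coverage track")
    lam = max(float(np.median(counts)), LAMBDA_FLOOR)
    # P(X >= k | lam) = sf(k - 1); log-scale scores survive underflow
    pvals = stats.poisson.sf(counts - 1, lam)
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    neglog10p = -stats.poisson.logsf(counts - 1, lam) / np.log(10)
    qvals = bh_adjust(pvals)
    sig = qvals <= alpha

    calls: list[PeakCall] = []
    bin_size = track.bin_size
    i = 0
    n = counts.size
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1]:
            j += 1
        best = i + int(np.argmax(neglog10p[i : j + 1]))
        top = i + int(np.argmax(counts[i : j + 1]))
        iv = GenomicInterval(track.chrom, i * bin_size, (j + 1) * bin_size)
        peak = Peak(
            iv,
            summit=top * bin_size,
            score=float(neglog10p[best]),
            name=f"{track.chrom}_peak_{len(calls) + 1}",
        )
        calls.append(PeakCall(peak, pvalue=float(pvals[best]), qvalue=float(qvals[best])))
        i = j + 1
    return calls


def call_peaks_genome(
    tracks: dict[str, CoverageTrack], alpha: float = 0.05
) -> list[Peak]:
    """Convenience: call peaks on every chromosome and return the Peak records."""
    peaks: list[Peak] = []
    for chrom in sorted(tracks):
        peaks.extend(c.peak for c in call_peaks(tracks[chrom], alpha=alpha))
    return peaks
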