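"""Binned coverage, amplified-segment calling and amplified-length arithmetic.

Coverage is summarized in fixed-width bins (default 3 kb, matching the
resolution at which amplicon read-depth profiles are usually drawn); segments
are maximal runs of bins at or above ``min_fold`` times the baseline, with
nearby runs merged and short runs dropped.  The baseline is the read depth of
the non-amplified genome (a few reads per base at ~10x coverage of a
pseudo-diploid genome) and can be estimated as the median bin depth outside
candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import DepthTrack
from .model import Interval

DEFAULT_BIN_SIZE = 3000
DEFAULT_MIN_FOLD = 3.0
DEFAULT_MERGE_GAP = 2  # bins
DEFAULT_MIN_LEN = 2  # bins


@dataclass
class CoverageBins:
    """Per-bin mean depth for one chromosome.

    Bin ``i`` covers 1-based positions ``[i*bin_size+1, (i+1)*bin_size]``;
    bins tile the chromosome without overlap.  ``log2`` is NaN where the mean
    depth is 0.
    """

    chrom: str
    bin_size: int
    mean: np.ndarray
    log2: np.ndarray

    def bin_interval(self, i: int) -> Interval:
        return Interval(
            self.chrom, i * self.bin_size + 1, (i + 1) * self.bin_size
        )


def bin_coverage(
    track: DepthTrack, bin_size: int = DEFAULT_BIN_SIZE
) -> Dict[str, CoverageBins]:
    """Mean per-base depth in non-overlapping bins, per chromosome."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    out: Dict[str, CoverageBins] = {}
    for chrom, arr in track.arrays.items():
        n_bins = int(np.ceil(len(arr) / bin_size))
        if n_bins == 0:
            continue
        padded = np.zeros(n_bins * bin_size)
        padded[: len(arr)] = arr
        sums = padded.reshape(n_bins, bin_size).sum(axis=1)
        # the final partial bin is averaged over its real width
        widths = np.full(n_bins, bin_size, dtype=float)
        widths[-1] = len(arr) - (n_bins - 1) * bin_size
        mean = sums / widths
        with np.errstate(divide="ignore"):
            log2 = np.where(mean > 0, np.log2(np.where(mean > 0, mean, 1.0)), np.nan)
        out[chrom] = CoverageBins(chrom, bin_size, mean, log2)
    return out


@dataclass
class AmplifiedSegment:
    interval: Interval
    mean_depth: float
    fold: float

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def estimate_baseline(
    bins: Dict[str, CoverageBins],
    exclude: Optional[Sequence[Interval]] = None,
) -> float:
    """Median bin depth outside user-declared candidate regions."""
    values: List[np.ndarray] = []
    for chrom, cb in bins.items():
        mask = np.ones(len(cb.mean), dtype=bool)
        if exclude:
            for iv in exclude:
                if iv.chrom != chrom:
                    continue
                lo = (iv.start - 1) // cb.bin_size
                hi = (iv.end - 1) // cb.bin_size
                mask[lo : hi + 1] = False
        values.append(cb.mean[mask])
    pooled = np.concatenate(values) if values else np.array([])
    pooled = pooled[pooled > 0]
    if len(pooled) == 0:
        raise ValueError("no non-zero bins available to estimate a baseline")
    return float(np.median(pooled))


def call_amplified(
    bins: Dict[str, CoverageBins],
    baseline: float,
    min_fold: float = DEFAULT_MIN_FOLD,
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> List[AmplifiedSegment]:
    """Call amplified segments as runs of bins with depth >= min_fold*baseline.

    Runs separated by fewer than ``merge_gap`` low bins are merged; merged
    runs shorter than ``min_len`` bins are dropped.  Defaults keep a ~20 kb
    internal unamplified gap as a hole (2 bins of merging cannot bridge it).
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if min_fold <= 1:
        raise ValueError("min_fold must be > 1")
    segments: List[AmplifiedSegment] = []
    threshold = min_fold * baseline
    for chrom in sorted(bins):
        cb = bins[chrom]
        above = cb.mean >= threshold
        runs = _runs(above)
        runs = _merge_runs(runs, merge_gap)
        for lo, hi in runs:
            if hi - lo < min_len:
                continue
            iv = Interval(chrom, lo * cb.bin_size + 1, hi * cb.bin_size)
            depth = float(cb.mean[lo:hi].mean())
            segments.append(AmplifiedSegment(iv, depth, depth / baseline))
    return segments


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open [lo, hi) index runs of True."""
    runs = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    for lo, hi in zip(idx[::2], idx[1::2]):
        runs.append((int(lo), int(hi)))
    return runs


def _merge_runs(runs: List[Tuple[int, int]], merge_gap: int) -> List[Tuple[int, int]]:
    if not runs:
        return runs
    merged = [runs[0]]
    for lo, hi in runs[1:]:
        plo, phi = merged[-1]
        if lo - phi < merge_gap:
            merged[-1] = (plo, hi)
        else:
            merged.append((lo, hi))
    return merged


def amplified_length_summary(
    segments: Sequence[Interval | AmplifiedSegment],
) -> Dict[str, int]:
    """Total amplified length (bp) per chromosome."""
    totals: Dict[str, int] = {}
    for seg in segments:
        iv = seg.interval if isinstance(seg, AmplifiedSegment) else seg
        totals[iv.chrom] = totals.get(iv.chrom, 0) + iv.length
    return totals


@dataclass
class AmplifiedComparison:
    retained: List[Interval]
    lost: List[Interval]
    fraction_lost: Dict[str, float]  # per chromosome, |A\B| / |A|


def _as_intervals(segments: Sequence[Interval | AmplifiedSegment]) -> List[Interval]:
    return [
        seg.interval if isinstance(seg, AmplifiedSegment) else seg
        for seg in segments
    ]


def compare_amplified(
    segments_a: Sequence[Interval | AmplifiedSegment],
    segments_b: Sequence[Interval | AmplifiedSegment],
) -> AmplifiedComparison:
    """Interval difference and intersection of two amplified-region sets.

    ``retained`` is A ∩ B, ``lost`` is A \\ B; per chromosome,
    ``|retained| + |lost| = |A|`` exactly.
    """
    a_by_chrom: Dict[str, List[Interval]] = {}
    for iv in _as_intervals(segments_a):
        a_by_chrom.setdefault(iv.chrom, []).append(iv)
    b_by_chrom: Dict[str, List[Interval]] = {}
    for iv in _as_intervals(segments_b):
        b_by_chrom.setdefault(iv.chrom, []).append(iv)
    retained: List[Interval] = []
    lost: List[Interval] = []
    fraction: Dict[str, float] = {}
    for chrom, a_ivs in sorted(a_by_chrom.items()):
        b_ivs = sorted(b_by_chrom.get(chrom, []), key=lambda iv: iv.start)
        total_a = 0
        total_lost = 0
        for a in sorted(a_ivs, key=lambda iv: iv.start):
            total_a += a.length
            pieces = _subtract(a, b_ivs)
            kept = _subtract_many(a, pieces)
            for piece in pieces:
                total_lost += piece.length
            lost.extend(pieces)
            retained.extend(kept)
        fraction[chrom] = total_lost / total_a if total_a else float("nan")
    return AmplifiedComparison(retained=retained, lost=lost, fraction_lost=fraction)


def _subtract(a: Interval, bs: Sequence[Interval]) -> List[Interval]:
    """Parts of ``a`` covered by none of ``bs`` (same chromosome assumed)."""
    out = []
    cursor = a.start
    for b in bs:
        if b.end < cursor or b.start > a.end:
            continue
        if b.start > cursor:
            out.append(Interval(a.chrom, cursor, min(b.start - 1, a.end)))
        cursor = max(cursor, b.end + 1)
        if cursor > a.end:
            break
    if cursor <= a.end:
        out.append(Interval(a.chrom, cursor, a.end))
    return out


def _subtract_many(a: Interval, holes: Sequence[Interval]) -> List[Interval]:
    """Complement of ``holes`` within ``a`` (holes are disjoint, sorted)."""
    out = []
    cursor = a.start
    for h in sorted(holes, key=lambda iv: iv.start):
        if h.start > cursor:
            out.append(Interval(a.chrom, cursor, h.start - 1))
        cursor = h.end + 1
    if cursor <= a.end:
        out.append(Interval(a.chrom, cursor, a.end))
    return out
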