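"""Downstream analyses on called genotypes: bulked-segregant window
scans, variety comparison, introgression localization, and transgene
dilution-series detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .genotyping import NO_CALL
from .io import GenomeIndex, Interval
from .ldpanel import BIN_SIZE, bin_index_of


@dataclass
class WindowScan:
    """Per-window differential-marker counts along a genome tiling.

    Windows are 0-based half-open; ``peak`` is the window with the
    largest count (ties to the leftmost in chromosome order).
    """

    window_bp: int
    windows: pd.DataFrame  # columns: chrom, start, end, count
    peak: tuple[str, int, int]
    total_diff: int
    diff_positions: list[tuple[str, int]]
    genome: GenomeIndex

    def count_sum(self) -> int:
        return int(self.windows["count"].sum())


@dataclass
class MixtureSeries:
    """A transgene dilution series: per-ratio replicate signals plus the
    negative-control signal distribution."""

    ratios: list[float]
    signals: dict[float, np.ndarray]
    negatives: np.ndarray


def _align_calls(calls_a: pd.Series | pd.DataFrame, calls_b) -> tuple[pd.Series, pd.Series]:
    if isinstance(calls_a, pd.DataFrame):
        calls_a = calls_a.iloc[:, 0]
    if isinstance(calls_b, pd.DataFrame):
        calls_b = calls_b.iloc[:, 0]
    shared = calls_a.index.intersection(calls_b.index)
    return calls_a.loc[shared], calls_b.loc[shared]


def differential_scan(
    calls_a: pd.Series | pd.DataFrame,
    calls_b: pd.Series | pd.DataFrame,
    positions: pd.DataFrame,
    genome: GenomeIndex,
    window_bp: int = 1_000_000,
) -> WindowScan:
    """Count differing markers per genome window.

    ``positions`` maps marker_id (index) to columns chrom, pos (1-based).
    Markers no-called in either set are excluded.  Symmetric in a/b.
    """
    a, b = _align_calls(calls_a, calls_b)
    called = (a != NO_CALL) & (b != NO_CALL)
    differing = called & (a != b)
    diff_ids = a.index[differing]
    diff_pos = [
        (str(positions.loc[m, "chrom"]), int(positions.loc[m, "pos"])) for m in diff_ids
    ]
    rows = []
    for chrom, length in genome.lengths.items():
        n = -(-length // window_bp)
        for i in range(n):
            rows.append([chrom, i * window_bp, min((i + 1) * window_bp, length), 0])
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    key = {(r.chrom, r.start // window_bp): i for i, r in enumerate(windows.itertuples())}
    for chrom, pos in diff_pos:
        windows.iat[key[(chrom, (pos - 1) // window_bp)], 3] += 1
    peak_row = windows.iloc[int(windows["count"].values.argmax())]
    return WindowScan(
        window_bp=window_bp,
        windows=windows,
        peak=(str(peak_row["chrom"]), int(peak_row["start"]), int(peak_row["end"])),
        total_diff=int(differing.sum()),
        diff_positions=diff_pos,
        genome=genome,
    )


def bulk_consensus(calls: pd.DataFrame) -> pd.Series:
    """Majority genotype per marker across a bulk's individuals.

    No-calls are ignored; a marker with no strict majority among called
    individuals (or no calls at all) is NC.
    """
    out = {}
    for marker, row in calls.iterrows():
        counts = row[row != NO_CALL].value_counts()
        if len(counts) and counts.iloc[0] * 2 > counts.sum():
            out[marker] = counts.index[0]
        else:
            out[marker] = NO_CALL
    return pd.Series(out, name="consensus")


def variety_compare(
    calls_a: pd.Series | pd.DataFrame,
    calls_b: pd.Series | pd.DataFrame,
    positions: pd.DataFrame,
    bin_size: int = BIN_SIZE,
) -> tuple[int, float, int]:
    """Polymorphic loci between two varieties and the genome bins hit.

    Returns (n_polymorphic, fraction over markers called in both, number
    of bins containing at least one difference).
    """
    a, b = _align_calls(calls_a, calls_b)
    called = (a != NO_CALL) & (b != NO_CALL)
    differing = called & (a != b)
    n_poly = int(differing.sum())
    fraction = n_poly / int(called.sum()) if called.sum() else 0.0
    bins_hit = {
        (positions.loc[m, "chrom"], bin_index_of(int(positions.loc[m, "pos"]), bin_size))
        for m in a.index[differing]
    }
    return n_poly, fraction, len(bins_hit)


def gmo_mixture_fraction(d: float) -> float:
    """Percent genetic modification of a d:1 negative:positive mix under
    the positive-relative-to-negative convention: 100 / d (30:1 -> 3.3%)."""
    if d <= 0:
        raise ValueError("ratio must be positive")
    return 100.0 / d


def gmo_detect(
    series: MixtureSeries,
    alpha: float = 0.01,
    min_negatives: int = 8,
) -> dict[float, bool]:
    """Per-ratio detection verdicts for a dilution series.

    A ratio is called positive when the one-sided Mann-Whitney test of
    test-vs-negative signals rejects at ``alpha`` AND the median test
    signal exceeds the negatives' 99th percentile.
    """
    if len(series.negatives) < min_negatives:
        raise ValueError(f"need >= {min_negatives} negative-control replicates")
    guard = np.percentile(series.negatives, 99)
    verdicts: dict[float, bool] = {}
    for d in series.ratios:
        sig = series.signals[d]
        p = mannwhitneyu(sig, series.negatives, alternative="greater").pvalue
        verdicts[d] = bool(p < alpha and np.median(sig) > guard)
    return verdicts


@dataclass
class IntrogressionSummary:
    target: Interval
    windows_overlapping: list[tuple[str, int, int]]
    fraction_inside: float
    n_diff_total: int
    spanned_interval: tuple[str, int, int] | None  # k nearest differing probes


def introgression_report(
    scan: WindowScan,
    target: Interval,
    flank_bp: int = 0,
    k_nearest: int = 4,
) -> IntrogressionSummary:
    """Summarize a differential scan around a target interval.

    Reports the scan windows overlapping the target, the fraction of all
    differing markers inside target +/- flank_bp, and the interval
    spanned by the k differing probes nearest to the target midpoint.
    """
    if target.chrom not in scan.genome.lengths:
        raise ValueError(f"target chromosome {target.chrom!r} not in genome")
    if target.end > scan.genome.lengths[target.chrom]:
        raise ValueError("target interval extends beyond the chromosome")
    overlapping = [
        (str(r.chrom), int(r.start), int(r.end))
        for r in scan.windows.itertuples()
        if r.chrom == target.chrom and r.start < target.end and r.end > target.start
    ]
    lo, hi = target.start - flank_bp, target.end + flank_bp
    inside = [
        (c, p) for c, p in scan.diff_positions
        if c == target.chrom and lo < p <= hi  # pos is 1-based, interval half-open
    ]
    fraction = len(inside) / len(scan.diff_positions) if scan.diff_positions else 0.0
    spanned = None
    on_chrom = [(c, p) for c, p in scan.diff_positions if c == target.chrom]
    if on_chrom:
        mid = (target.start + target.end) / 2.0
        nearest = sorted(on_chrom, key=lambda cp: abs(cp[1] - mid))[:k_nearest]
        positions = [p for _, p in nearest]
        spanned = (target.chrom, min(positions), max(positions))
    return IntrogressionSummary(
        target=target,
        windows_overlapping=overlapping,
        fraction_inside=fraction,
        n_diff_total=scan.total_diff,
        spanned_interval=spanned,
    )
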