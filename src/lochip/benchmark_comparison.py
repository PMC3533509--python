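"""Peak-set comparison against a benchmark dataset.

Sensitivity here is the fraction of benchmark peaks touched (>= 1 bp) by a
sample peak; specificity the fraction of sample peaks that are "on target"
(touch a benchmark peak). Coverage measures how completely each detected
benchmark peak is covered; peak heights are compared as reads-per-million
on matched peaks (Spearman); replicate concordance reports overlap counts
with three candidate denominators (min, max, union of the two peak counts)
because the conventional denominator varies between studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import spearmanr

from .peak_calling import PeakInterval
from .records import UndefinedMetricError


def _as_triples(peaks: Sequence) -> list[tuple[str, int, int]]:
    out = []
    for p in peaks:
        if isinstance(p, PeakInterval):
            out.append((p.chrom, p.start, p.end))
        else:
            chrom, start, end = p[0], int(p[1]), int(p[2])
            out.append((chrom, start, end))
    return out


def merge_peaks(peaks: Sequence) -> list[tuple[str, int, int]]:
    """Sort and merge overlapping or touching intervals per chromosome."""
    triples = sorted(_as_triples(peaks))
    merged: list[tuple[str, int, int]] = []
    for chrom, s, e in triples:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((chrom, s, e))
    return merged


def _trees(peaks: Sequence) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in _as_triples(peaks):
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    return trees


def sensitivity(benchmark: Sequence, sample: Sequence) -> float:
    """Fraction of benchmark peaks overlapped (>= 1 bp) by any sample peak."""
    bench = merge_peaks(benchmark)
    if not bench:
        raise UndefinedMetricError("sensitivity undefined for empty benchmark")
    trees = _trees(merge_peaks(sample))
    hit = sum(
        1
        for chrom, s, e in bench
        if chrom in trees and trees[chrom].overlap(s, e)
    )
    return hit / len(bench)


def specificity(benchmark: Sequence, sample: Sequence) -> float:
    """Fraction of sample peaks overlapped (>= 1 bp) by any benchmark peak."""
    samp = merge_peaks(sample)
    if not samp:
        raise UndefinedMetricError("specificity undefined for empty sample")
    trees = _trees(merge_peaks(benchmark))
    hit = sum(
        1 for chrom, s, e in samp if chrom in trees and trees[chrom].overlap(s, e)
    )
    return hit / len(samp)


@dataclass(frozen=True)
class CoverageResult:
    """Covered-length fractions of the overlapped benchmark peaks, plus the
    full (fraction == 1.0) versus partial split."""

    fractions: list[float]
    n_full: int
    n_partial: int


def benchmark_coverage(benchmark: Sequence, sample: Sequence) -> CoverageResult:
    """Covered fraction of each benchmark peak under the union of sample peaks.

    Only benchmark peaks with >= 1 bp of overlap contribute; a peak whose
    covered fraction is exactly 1.0 counts as fully covered.
    """
    bench = merge_peaks(benchmark)
    trees = _trees(merge_peaks(sample))
    fractions: list[float] = []
    n_full = 0
    for chrom, s, e in bench:
        if chrom not in trees:
            continue
        covered = 0
        for iv in trees[chrom].overlap(s, e):
            covered += min(e, iv.end) - max(s, iv.begin)
        if covered > 0:
            frac = covered / (e - s)
            fractions.append(frac)
            if covered == e - s:
                n_full += 1
    return CoverageResult(
        fractions=fractions, n_full=n_full, n_partial=len(fractions) - n_full
    )


def peak_height_correlation(
    benchmark: Sequence[PeakInterval],
    benchmark_total_usable: int,
    sample: Sequence[PeakInterval],
    sample_total_usable: int,
) -> float:
    """Spearman correlation of normalized peak heights on matched peaks.

    Each sample peak is assigned to the benchmark peak it overlaps most
    (largest intersection wins ties); a benchmark peak matched by several
    sample peaks receives the sum of their read counts. Heights are
    normalized to reads per million usable reads; only benchmark peaks with
    at least one match enter the correlation.
    """
    if benchmark_total_usable < 1 or sample_total_usable < 1:
        raise UndefinedMetricError("usable-read totals must be positive")
    btree: dict[str, IntervalTree] = {}
    for i, p in enumerate(benchmark):
        btree.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, i)
    matched: dict[int, float] = {}
    for p in sample:
        tree = btree.get(p.chrom)
        if tree is None:
            continue
        hits = tree.overlap(p.start, p.end)
        if not hits:
            continue
        best = max(
            hits,
            key=lambda iv: (min(p.end, iv.end) - max(p.start, iv.begin), -iv.begin),
        )
        matched[best.data] = matched.get(best.data, 0.0) + p.read_count
    if len(matched) < 3:
        raise UndefinedMetricError(
            f"only {len(matched)} matched peak pairs; need >= 3"
        )
    b_heights = [
        benchmark[i].read_count * 1e6 / benchmark_total_usable for i in matched
    ]
    s_heights = [c * 1e6 / sample_total_usable for c in matched.values()]
    rho = spearmanr(b_heights, s_heights).statistic
    return float(rho)


@dataclass(frozen=True)
class ConcordanceResult:
    """Replicate overlap counts and candidate concordance percentages."""

    a_overlapping_b: int
    b_overlapping_a: int
    pct_of_min: float
    pct_of_max: float
    pct_of_union: float


def replicate_concordance(
    peaks_a: Sequence, peaks_b: Sequence
) -> ConcordanceResult:
    """Count mutual overlaps and report concordance percentages.

    Percentages use the smaller of the two directional overlap counts in
    the numerator and, respectively, the smaller peak count, the larger
    peak count, and the union of the two sets (n_a + n_b - overlap) as
    denominators.
    """
    a = merge_peaks(peaks_a)
    b = merge_peaks(peaks_b)
    if not a or not b:
        raise UndefinedMetricError("concordance undefined for an empty peak set")
    ta, tb = _trees(a), _trees(b)
    a_in_b = sum(1 for c, s, e in a if c in tb and tb[c].overlap(s, e))
    b_in_a = sum(1 for c, s, e in b if c in ta and ta[c].overlap(s, e))
    n_ov = min(a_in_b, b_in_a)
    return ConcordanceResult(
        a_overlapping_b=a_in_b,
        b_overlapping_a=b_in_a,
        pct_of_min=100.0 * n_ov / min(len(a), len(b)),
        pct_of_max=100.0 * n_ov / max(len(a), len(b)),
        pct_of_union=100.0 * n_ov / (len(a) + len(b) - n_ov),
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Everything a benchmark comparison produces for one sample."""

    n_benchmark: int
    n_sample: int
    sensitivity: float
    specificity: float
    peak_count_ratio: float
    overlap_fractions: list[float] = field(repr=False)
    n_full: int = 0
    n_partial: int = 0
    height_spearman: float | None = None


def compare(
    benchmark: Sequence[PeakInterval],
    sample: Sequence[PeakInterval],
    benchmark_total_usable: int | None = None,
    sample_total_usable: int | None = None,
) -> ComparisonReport:
    """Full comparison of a sample peak set against a benchmark."""
    cov = benchmark_coverage(benchmark, sample)
    rho: float | None = None
    if benchmark_total_usable and sample_total_usable:
        try:
            rho = peak_height_correlation(
                benchmark, benchmark_total_usable, sample, sample_total_usable
            )
        except UndefinedMetricError:
            rho = None
    return ComparisonReport(
        n_benchmark=len(benchmark),
        n_sample=len(sample),
        sensitivity=sensitivity(benchmark, sample),
        specificity=specificity(benchmark, sample),
        peak_count_ratio=len(sample) / len(benchmark),
        overlap_fractions=cov.fractions,
        n_full=cov.n_full,
        n_partial=cov.n_partial,
        height_spearman=rho,
    )
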