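"""Saturation of peak discovery under read subsampling.

Randomly discards usable reads at a grid of retention fractions, re-calls
peaks on each subsample, and reports the peak count per fraction together
with the saturation statistic s = n_peaks(0.5) / n_peaks(1.0). A library
near saturation keeps calling almost all its peaks from half the reads
(s close to 1); a depth-limited library loses peaks roughly in proportion
to the discarded reads (s near 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .peak_calling import PeakCallConfig, call_peaks
from .records import ConfigError, ReadRecord

DEFAULT_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def subsample_reads(
    reads: Sequence[ReadRecord], fraction: float, seed: int
) -> list[ReadRecord]:
    """Keep each read independently with probability ``fraction``.

    Bernoulli thinning: deterministic under the seed, order-preserving
    (a sorted input stays sorted).
    """
    if not (0.0 < fraction <= 1.0):
        raise ConfigError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return list(reads)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < fraction
    return [r for r, k in zip(reads, keep) if k]


@dataclass(frozen=True)
class SaturationResult:
    """Peak counts per retention fraction and the saturation statistic."""

    points: list[tuple[float, int, int]]  # (fraction, kept_reads, n_peaks)
    s: float | None  # n_peaks(0.5) / n_peaks(1.0), None if 0.5 not sampled


def saturation_curve(
    reads: Sequence[ReadRecord],
    fractions: Sequence[float],
    peak_config: PeakCallConfig,
    seed: int,
) -> SaturationResult:
    """Peak counts across a subsampling grid.

    ``fractions`` must be sorted ascending and end at 1.0 (the full
    library). Each fraction uses an independent substream of ``seed``.
    """
    fr = list(fractions)
    if not fr or sorted(fr) != fr or fr[-1] != 1.0:
        raise ConfigError("fractions must be sorted ascending and end at 1.0")
    seeds = np.random.SeedSequence(seed).generate_state(len(fr))
    points: list[tuple[float, int, int]] = []
    n_by_fraction: dict[float, int] = {}
    for f, sub_seed in zip(fr, seeds):
        sub = subsample_reads(reads, f, int(sub_seed % (2**31)))
        n_peaks = len(call_peaks(sub, peak_config)) if sub else 0
        points.append((f, len(sub), n_peaks))
        n_by_fraction[f] = n_peaks
    s = None
    if 0.5 in n_by_fraction and n_by_fraction[1.0] > 0:
        s = n_by_fraction[0.5] / n_by_fraction[1.0]
    return SaturationResult(points=points, s=s)
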