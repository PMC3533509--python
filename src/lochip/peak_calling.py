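"""Poisson-background peak calling.

A deliberately minimal narrow-peak caller in the MACS style: reads are
shifted to their fragment midpoint, piled up in a fixed window, and scored
against a single genome-wide Poisson rate (no dynamic local background --
the workflow this reproduces switched local background estimation off).
An optional control mode raises the local rate where a depth-scaled,
smoothed input track exceeds the genome-wide rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special
from scipy.stats import poisson

from .records import ConfigError, DataError, ReadRecord

logger = logging.getLogger(__name__)

_CONTROL_SMOOTH_WINDOW = 10_000  # bp smoothing of the control pileup


@dataclass(frozen=True)
class PeakCallConfig:
    """Scan parameters.

    ``shift`` is half the library insert size (reads are moved to the
    fragment midpoint); ``window`` the pileup footprint per read;
    ``effective_genome_size`` the mappable length behind the Poisson rate.
    ``chrom_sizes`` (optional) clips pileups to chromosome bounds; when
    absent, bounds are inferred from the data.
    """

    shift: int
    effective_genome_size: int
    window: int = 150
    pvalue_threshold: float = 1e-5
    merge_gap: int = 100
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ConfigError("shift must be >= 0")
        if self.window < 1:
            raise ConfigError("window must be >= 1")
        if not (0.0 < self.pvalue_threshold < 1.0):
            raise ConfigError("pvalue_threshold must be in (0, 1)")
        if self.merge_gap < 0:
            raise ConfigError("merge_gap must be >= 0")
        if self.effective_genome_size <= 0:
            raise ConfigError("effective_genome_size must be positive")


@dataclass(frozen=True)
class PeakInterval:
    """A called peak: 0-based half-open interval with score and summit."""

    chrom: str
    start: int
    end: int
    read_count: int
    score: float  # -log10 of the minimal Poisson tail probability
    summit: int

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise DataError("peak start must precede end")
        if not (self.start <= self.summit < self.end):
            raise DataError("summit must lie inside the peak")
        if self.read_count < 1:
            raise DataError("peak must contain at least one read")


def _shifted_midpoints(
    reads: Sequence[ReadRecord], shift: int
) -> dict[str, np.ndarray]:
    """Strand-corrected fragment midpoints per chromosome, sorted."""
    by_chrom: dict[str, list[int]] = {}
    for r in reads:
        if r.mapping_class == "unmapped":
            raise DataError("peak calling requires mapped, usable reads")
        mid = r.start + shift if r.strand == "+" else r.start - shift
        by_chrom.setdefault(r.chrom, []).append(mid)
    return {
        c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()
    }


def shift_and_pileup(
    reads: Sequence[ReadRecord], config: PeakCallConfig
) -> dict[str, np.ndarray]:
    """Per-chromosome coverage: each read adds 1 over a window around its
    shifted midpoint, clipped to chromosome bounds."""
    if config.chrom_sizes is not None:
        for r in reads:
            size = config.chrom_sizes.get(r.chrom)
            if size is None:
                raise DataError(f"read {r.read_id} on unknown chromosome {r.chrom}")
            if not (0 <= r.start < size):
                raise DataError(
                    f"read {r.read_id} at {r.chrom}:{r.start} is outside "
                    f"the chromosome (length {size})"
                )
    mids = _shifted_midpoints(reads, config.shift)
    out: dict[str, np.ndarray] = {}
    half = config.window // 2
    for chrom, m in mids.items():
        if config.chrom_sizes is not None:
            size = config.chrom_sizes[chrom]
        else:
            size = int(m.max()) + half + 1
        lo = np.clip(m - half, 0, size)
        hi = np.clip(m + config.window - half, 0, size)
        diff = np.zeros(size + 1, dtype=np.int32)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
        out[chrom] = np.cumsum(diff[:-1]).astype(np.int32)
    return out


def _min_significant_count(lam: float, pvalue: float) -> int:
    """Smallest k with P(X >= k; lam) < pvalue."""
    # P(X >= k) = gammainc(k, lam) (regularized lower incomplete gamma)
    k = max(1, int(poisson.isf(pvalue, lam)))
    while k > 1 and special.gammainc(k - 1, lam) < pvalue:
        k -= 1
    while special.gammainc(k, lam) >= pvalue:
        k += 1
    return k


def _neg_log10_sf(k: np.ndarray | int, lam: float | np.ndarray) -> np.ndarray:
    """-log10 P(X >= k; lam) as a 1-d array, stable far into the tail."""
    with np.errstate(divide="ignore"):
        p = special.gammainc(np.atleast_1d(np.asarray(k, dtype=float)), lam)
        out = -np.log10(p)
    bad = ~np.isfinite(out)
    if np.any(bad):
        ks = np.broadcast_to(np.asarray(k), out.shape)[bad]
        ls = np.broadcast_to(np.asarray(lam, dtype=float), out.shape)[bad]
        out[bad] = -poisson.logsf(ks - 1, ls) / np.log(10.0)
    return out


def _runs_from_mask(mask: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Half-open runs of True, merging runs separated by <= merge_gap."""
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def call_peaks(
    reads: Sequence[ReadRecord], config: PeakCallConfig
) -> list[PeakInterval]:
    """Call peaks against the genome-wide Poisson background.

    The background rate is (n_reads * window) / effective_genome_size.
    Positions whose pileup reaches the significance count are merged into
    peaks across gaps of up to ``merge_gap`` bp; each peak reports the
    number of usable reads whose shifted midpoint falls inside it, its
    leftmost-maximum summit, and -log10 of its best tail probability.
    """
    if not reads:
        raise ConfigError("call_peaks requires at least one read")
    lam = len(reads) * config.window / config.effective_genome_size
    kmin = _min_significant_count(lam, config.pvalue_threshold)
    pileup = shift_and_pileup(reads, config)
    mids = _shifted_midpoints(reads, config.shift)
    peaks: list[PeakInterval] = []
    for chrom in sorted(pileup):
        cov = pileup[chrom]
        mask = cov >= kmin
        if not mask.any():
            continue
        for s, e in _runs_from_mask(mask, config.merge_gap):
            seg = cov[s:e]
            summit = s + int(np.argmax(seg))
            kmax = int(seg.max())
            m = mids[chrom]
            count = int(
                np.searchsorted(m, e, side="left")
                - np.searchsorted(m, s, side="left")
            )
            if count == 0:
                continue  # merged run with no midpoint inside (edge effect)
            peaks.append(
                PeakInterval(
                    chrom=chrom,
                    start=int(s),
                    end=int(e),
                    read_count=count,
                    score=float(_neg_log10_sf(kmax, lam)[0]),
                    summit=summit,
                )
            )
    return peaks


def call_peaks_with_control(
    reads: Sequence[ReadRecord],
    control_reads: Sequence[ReadRecord],
    config: PeakCallConfig,
) -> tuple[list[PeakInterval], list[PeakInterval]]:
    """Peak calling with an input-library control track.

    The local rate at each position is the maximum of the genome-wide rate
    and the control pileup smoothed over 10 kb and scaled to the treatment
    depth. Returns (peaks, lost) where ``lost`` are the peaks found by the
    plain genome-wide scan that disappear under control correction.
    """
    baseline = call_peaks(reads, config)
    if not control_reads:
        logger.warning("empty control library: falling back to call_peaks")
        return baseline, []
    lam_bg = len(reads) * config.window / config.effective_genome_size
    scale = len(reads) / len(control_reads)
    pileup = shift_and_pileup(reads, config)
    ctrl = shift_and_pileup(control_reads, config)
    mids = _shifted_midpoints(reads, config.shift)
    kmin_bg = _min_significant_count(lam_bg, config.pvalue_threshold)

    peaks: list[PeakInterval] = []
    for chrom in sorted(pileup):
        cov = pileup[chrom].astype(np.int64)
        n = cov.size
        lam_local = np.full(n, lam_bg)
        if chrom in ctrl:
            c = ctrl[chrom].astype(np.float64)
            if c.size < n:
                c = np.pad(c, (0, n - c.size))
            c = c[:n]
            w = min(_CONTROL_SMOOTH_WINDOW, n)
            cs = np.concatenate([[0.0], np.cumsum(c)])
            half = w // 2
            lo = np.clip(np.arange(n) - half, 0, n)
            hi = np.clip(np.arange(n) + (w - half), 0, n)
            smooth = (cs[hi] - cs[lo]) / np.maximum(hi - lo, 1)
            lam_local = np.maximum(lam_bg, smooth * scale)
        # only positions significant vs the floor rate can be significant
        cand = cov >= kmin_bg
        if not cand.any():
            continue
        sig = np.zeros(n, dtype=bool)
        idx = np.flatnonzero(cand)
        tails = special.gammainc(cov[idx].astype(float), lam_local[idx])
        sig[idx] = tails < config.pvalue_threshold
        if not sig.any():
            continue
        for s, e in _runs_from_mask(sig, config.merge_gap):
            seg = cov[s:e]
            summit = s + int(np.argmax(seg))
            m = mids[chrom]
            count = int(
                np.searchsorted(m, e, side="left")
                - np.searchsorted(m, s, side="left")
            )
            if count == 0:
                continue
            best = float(
                np.max(_neg_log10_sf(seg, lam_local[s:e]))
            )
            peaks.append(
                PeakInterval(
                    chrom=chrom,
                    start=int(s),
                    end=int(e),
                    read_count=count,
                    score=best,
                    summit=summit,
                )
            )

    kept: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        kept.setdefault(p.chrom, []).append((p.start, p.end))
    lost = []
    for p in baseline:
        ivals = kept.get(p.chrom, [])
        if not any(s < p.end and p.start < e for s, e in ivals):
            lost.append(p)
    return peaks, lost
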