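"""Genome-binned tracks, between-sample correlations, and TSS metaprofiles.

Read depth is summarized in non-overlapping bins (10 kb for narrow marks,
50 kb for broad ones in the workflow this supports) and normalized to
reads per bin per million usable reads, which makes libraries of different
depth directly comparable. Pairwise Pearson correlations of these tracks
quantify reproducibility within a mark and mutual exclusivity between
marks. The TSS metaprofile accumulates strand-oriented read offsets around
gene starts, averaged within expression quartiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import ConfigError, GeneAnnotation, GenomeModel, ReadRecord

logger = logging.getLogger(__name__)

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class BinnedTrack:
    """Per-chromosome binned read counts with depth normalization.

    ``counts`` holds raw per-bin read counts; ``normalized`` scales them to
    reads per bin per million usable reads (raw * 1e6 / total_usable).
    """

    bin_size: int
    counts: dict[str, np.ndarray]
    total_usable: int

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ConfigError("bin_size must be >= 1")
        raw = sum(int(v.sum()) for v in self.counts.values())
        if raw > self.total_usable:
            raise ConfigError("binned counts exceed the usable-read total")

    @property
    def normalized(self) -> dict[str, np.ndarray]:
        if self.total_usable == 0:
            logger.warning("zero usable reads: normalization skipped")
            return {c: v.astype(float) for c, v in self.counts.items()}
        f = 1e6 / self.total_usable
        return {c: v * f for c, v in self.counts.items()}

    def values(self) -> np.ndarray:
        """Normalized bin values concatenated over chromosomes (sorted)."""
        norm = self.normalized
        return np.concatenate([norm[c] for c in sorted(norm)])


def bin_counts(
    reads: Sequence[ReadRecord], genome: GenomeModel, bin_size: int
) -> BinnedTrack:
    """Count usable-read 5' positions in non-overlapping bins.

    The last bin of each chromosome may be short; empty chromosomes get
    all-zero vectors.
    """
    if bin_size < 1:
        raise ConfigError("bin_size must be >= 1")
    counts = {
        c: np.zeros(math.ceil(size / bin_size), dtype=np.int64)
        for c, size in genome.chrom_sizes.items()
    }
    for r in reads:
        if r.mapping_class != "unique":
            raise ConfigError("bin_counts expects usable (unique-class) reads")
        counts[r.chrom][r.start // bin_size] += 1
    return BinnedTrack(bin_size=bin_size, counts=counts, total_usable=len(reads))


def pairwise_correlation(
    tracks: Sequence[BinnedTrack],
    log_transform: bool = False,
    drop_all_zero: bool = False,
) -> np.ndarray:
    """Pearson correlation matrix over concatenated normalized bin vectors.

    All tracks must share bin size and genome partition. ``log_transform``
    applies log1p to the normalized values first; ``drop_all_zero``
    excludes bins that are zero in every track.
    """
    if len(tracks) < 2:
        raise ConfigError("need at least two tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if t.bin_size != first.bin_size:
            raise ConfigError("tracks have mismatched bin sizes")
        if set(t.counts) != set(first.counts) or any(
            t.counts[c].size != first.counts[c].size for c in first.counts
        ):
            raise ConfigError("tracks have mismatched genome binning")
    mat = np.vstack([t.values() for t in tracks])
    if drop_all_zero:
        keep = (mat != 0).any(axis=0)
        mat = mat[:, keep]
    if log_transform:
        mat = np.log1p(mat)
    return np.corrcoef(mat)


@dataclass(frozen=True)
class TssProfile:
    """Mean read depth around TSSs per expression quartile.

    ``offsets`` are bin left edges on the strand-oriented axis (negative =
    upstream); ``profile`` rows are quartiles Q1..Q4, in reads per bin per
    million usable reads averaged over the quartile's genes.
    """

    offsets: np.ndarray
    profile: np.ndarray  # shape (4, n_bins)

    def quartile_row(self, quartile: str) -> np.ndarray:
        return self.profile[QUARTILES.index(quartile)]

    def value_at(self, quartile: str, offset: int) -> float:
        """Profile value in the bin containing the given offset."""
        bin_size = int(self.offsets[1] - self.offsets[0])
        i = int((offset - self.offsets[0]) // bin_size)
        return float(self.quartile_row(quartile)[i])

    def footprint_mean(
        self, quartile: str, center: int, half_width: int = 50
    ) -> float:
        """Mean profile value over [center-half_width, center+half_width).

        Aggregating over a nucleosome-scale footprint instead of a single
        fine bin averages out counting noise at sparsely covered positions.
        """
        sel = (self.offsets >= center - half_width) & (
            self.offsets < center + half_width
        )
        return float(self.quartile_row(quartile)[sel].mean())


def tss_profile(
    reads: Sequence[ReadRecord],
    genes: Sequence[GeneAnnotation],
    window: int = 2000,
    bin_size: int = 10,
    chrom_sizes: dict[str, int] | None = None,
) -> TssProfile:
    """Accumulate read 5' ends on a strand-oriented grid around TSSs.

    For each gene, reads within [-window, +window) of the TSS are mapped to
    offsets (sign-flipped for minus-strand genes so +100 always means 100 bp
    downstream of the TSS); counts are averaged over the genes of each
    quartile and normalized to reads per million usable reads.
    """
    if window < bin_size or window % bin_size:
        raise ConfigError("window must be a positive multiple of bin_size")
    n_bins = 2 * window // bin_size
    offsets = np.arange(-window, window, bin_size)
    by_chrom: dict[str, list[int]] = {}
    for r in reads:
        if r.mapping_class == "unmapped":
            continue
        by_chrom.setdefault(r.chrom, []).append(r.start)
    by_chrom = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}

    sums = np.zeros((4, n_bins))
    n_genes = np.zeros(4, dtype=np.int64)
    for g in genes:
        qi = QUARTILES.index(g.quartile)
        n_genes[qi] += 1
        pos = by_chrom.get(g.chrom)
        if chrom_sizes is not None:
            size = chrom_sizes.get(g.chrom)
            if size is not None and (g.tss - window < 0 or g.tss + window > size):
                logger.info(
                    "TSS window of %s truncated at a chromosome end", g.gene_id
                )
        if pos is None:
            continue
        lo = np.searchsorted(pos, g.tss - window, side="left")
        hi = np.searchsorted(pos, g.tss + window, side="left")
        if hi == lo:
            continue
        off = pos[lo:hi] - g.tss
        if g.strand == "-":
            off = -off
        sel = (off >= -window) & (off < window)
        idx = (off[sel] + window) // bin_size
        np.add.at(sums[qi], idx, 1)

    total = len(reads)
    profile = np.zeros_like(sums)
    for qi in range(4):
        if n_genes[qi]:
            profile[qi] = sums[qi] / n_genes[qi]
    if total > 0:
        profile *= 1e6 / total
    return TssProfile(offsets=offsets, profile=profile)


def export_track(track: BinnedTrack, path: str) -> None:
    """Write the normalized track as bedGraph (all bins, zeros included).

    Two comment lines record bin size and the usable-read total so the
    file round-trips through ``read_track``.
    """
    norm = track.normalized
    with open(path, "w") as fh:
        fh.write(f"# bin_size={track.bin_size}\n")
        fh.write(f"# total_usable={track.total_usable}\n")
        fh.write('track type=bedGraph name="lochip binned coverage"\n')
        for chrom in sorted(norm):
            vals = norm[chrom]
            for i, v in enumerate(vals):
                s = i * track.bin_size
                e = s + track.bin_size
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_track(path: str) -> BinnedTrack:
    """Parse a bedGraph written by ``export_track`` back into a BinnedTrack."""
    bin_size = total = None
    data: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# bin_size="):
                bin_size = int(line.split("=", 1)[1])
            elif line.startswith("# total_usable="):
                total = int(line.split("=", 1)[1])
            elif line.startswith(("track", "#")) or not line.strip():
                continue
            else:
                chrom, s, e, v = line.split("\t")
                data.setdefault(chrom, []).append(float(v))
    if bin_size is None or total is None:
        raise ConfigError(f"{path}: missing bin_size/total_usable header")
    counts = {
        c: np.round(np.asarray(v) * total / 1e6).astype(np.int64) if total else
        np.asarray(v, dtype=np.int64)
        for c, v in data.items()
    }
    return BinnedTrack(bin_size=bin_size, counts=counts, total_usable=total)
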