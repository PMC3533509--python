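"""Synthetic low-input ChIP-seq libraries.

Emulates the statistical structure of native ChIP-seq libraries prepared
from decreasing cell numbers: a pool of unique recoverable fragments that
shrinks with input, PCR amplification that inflates duplicates as the pool
shrinks, unmappable artifact reads, promoter-anchored H3K4me3 nucleosomes
scaled by gene expression, and broad H3K27me3 domains over silent genes
that never invade active-promoter nucleosomes.

The simulator emits mapping classes directly (unique / multi-mapping /
unmapped); there is no base-level sequence or alignment stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pysam
from scipy.stats import truncnorm

from .records import (
    READ_LENGTH,
    CapacityError,
    ConfigError,
    FragmentPool,
    GeneAnnotation,
    GenomeModel,
    ReadRecord,
)

logger = logging.getLogger(__name__)

MARKS = ("H3K4me3", "H3K27me3", "input")

# Phased nucleosome centres flanking the TSS (strand-oriented offsets, bp).
NUCLEOSOME_OFFSETS = np.array([-600, -350, 100, 300, 500, 700])
NUCLEOSOME_JITTER_SD = 20.0  # bp positional jitter of each nucleosome
NUCLEOSOME_HALF_WIDTH = 73  # bp, half of the 147 bp nucleosomal footprint
TSS_DEPLETED_HALF_WIDTH = 50  # bp: nucleosome-free region around the TSS
GENE_BODY_LENGTH = 10_000  # bp nominal transcribed unit for broad domains
BROAD_DOMAIN_FLANK = 5_000  # bp either side of the gene body

_REPEAT_BLOCK = 2_000  # bp granularity of synthetic repeat placement
_GENE_SLOT = 10_000  # bp exclusive slot per gene (enforces the capacity limit)
_TSS_MARGIN = 2_500  # bp distance kept from chromosome ends and slot edges


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulated immunoprecipitation + sequencing run.

    cells_per_ip times pool_per_cell sets the number of unique recoverable
    fragments; pcr_cycles/pcr_efficiency_* control amplification (each
    molecule doubles per cycle with its own Bernoulli efficiency, drawn once
    per molecule); artifact_fraction is the unmappable-artifact share of the
    final library and error_unmapped_fraction the genuine reads lost to
    sequencing error. enrichment_fold is the signal:background odds of the
    immunoprecipitation.
    """

    cells_per_ip: int
    pool_per_cell: float = 0.5
    pcr_cycles: int = 18
    pcr_efficiency_mean: float = 0.8
    pcr_efficiency_sd: float = 0.05
    n_reads: int = 1_000_000
    artifact_fraction: float = 0.05
    error_unmapped_fraction: float = 0.02
    fragment_length_mean: float = 147.0
    fragment_length_sd: float = 20.0
    mark: str = "H3K4me3"
    enrichment_fold: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_ip < 1:
            raise ConfigError("cells_per_ip must be >= 1")
        if self.n_reads < 1:
            raise ConfigError("n_reads must be >= 1")
        if self.pcr_cycles < 0:
            raise ConfigError("pcr_cycles must be >= 0")
        if self.pool_per_cell <= 0:
            raise ConfigError("pool_per_cell must be > 0")
        for name in (
            "artifact_fraction",
            "error_unmapped_fraction",
            "pcr_efficiency_mean",
            "pcr_efficiency_sd",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.mark not in MARKS:
            raise ConfigError(f"mark must be one of {MARKS}, got {self.mark!r}")
        if self.enrichment_fold < 0:
            raise ConfigError("enrichment_fold must be >= 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def expected_unique_fraction(U: int, m: int) -> float:
    """Expected fraction of reads that are the first of their molecule.

    Under unbiased sampling of ``m`` reads from ``U`` equally likely unique
    molecules, the expected number of distinct molecules observed is
    U*(1-(1-1/U)**m) (the classical occupancy result), so the expected
    unique-read fraction is that divided by ``m``. Computed via
    expm1/log1p so it is stable for U up to 1e9 and beyond.
    """
    if U < 1 or m < 1:
        raise ConfigError("U and m must be >= 1")
    if U == 1:
        return 1.0 / m
    distinct = -U * math.expm1(m * math.log1p(-1.0 / U))
    return distinct / m


def build_genome_model(
    n_chroms: int,
    chrom_length: int,
    repeat_fraction: float,
    n_genes: int,
    seed: int,
) -> tuple[GenomeModel, list[GeneAnnotation]]:
    """Build a synthetic genome with repeat blocks and annotated genes.

    Repeats are laid as non-overlapping 2 kb blocks covering approximately
    ``repeat_fraction`` of the genome. Genes are placed one per 10 kb slot
    (hence the capacity requirement n_genes * 10 kb <= genome length), with
    the TSS jittered inside the slot, kept clear of repeat blocks and
    chromosome ends. Expression is drawn from a log-normal (long-tailed)
    distribution and genes are ranked into quartiles, Q4 highest.
    """
    if not (0.0 <= repeat_fraction <= 0.5):
        raise ConfigError("repeat_fraction must be in [0, 0.5]")
    if n_chroms < 1 or chrom_length < _GENE_SLOT:
        raise ConfigError("need >= 1 chromosome of at least 10 kb")
    total = n_chroms * chrom_length
    if n_genes * _GENE_SLOT > total:
        raise CapacityError(
            f"cannot place {n_genes} genes at one per {_GENE_SLOT} bp "
            f"in a {total} bp genome"
        )

    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": int(chrom_length) for i in range(n_chroms)}

    # Repeat blocks: exactly round(f * n_blocks) blocks per genome, spread
    # over chromosomes, merged when adjacent.
    repeat_intervals: dict[str, list[tuple[int, int]]] = {}
    blocks_per_chrom = chrom_length // _REPEAT_BLOCK
    n_repeat_blocks = int(round(repeat_fraction * blocks_per_chrom * n_chroms))
    if n_repeat_blocks > 0:
        all_blocks = np.arange(blocks_per_chrom * n_chroms)
        chosen = np.sort(rng.choice(all_blocks, size=n_repeat_blocks, replace=False))
        for chrom_i, name in enumerate(chrom_sizes):
            lo, hi = chrom_i * blocks_per_chrom, (chrom_i + 1) * blocks_per_chrom
            mine = chosen[(chosen >= lo) & (chosen < hi)] - lo
            ivals: list[tuple[int, int]] = []
            for b in mine:
                s, e = int(b) * _REPEAT_BLOCK, (int(b) + 1) * _REPEAT_BLOCK
                if ivals and ivals[-1][1] == s:
                    ivals[-1] = (ivals[-1][0], e)
                else:
                    ivals.append((s, e))
            if ivals:
                repeat_intervals[name] = ivals

    genome = GenomeModel(
        chrom_sizes=chrom_sizes,
        repeat_intervals=repeat_intervals,
        effective_genome_fraction=1.0 - n_repeat_blocks * _REPEAT_BLOCK / total,
    )

    genes = _place_genes(genome, n_genes, rng)
    return genome, genes


def _place_genes(
    genome: GenomeModel, n_genes: int, rng: np.random.Generator
) -> list[GeneAnnotation]:
    chrom_names = genome.chrom_names()
    slots: list[tuple[str, int]] = []
    for name in chrom_names:
        for s in range(0, genome.chrom_sizes[name] - _GENE_SLOT + 1, _GENE_SLOT):
            slots.append((name, s))
    if n_genes > len(slots):
        raise CapacityError(f"only {len(slots)} gene slots for {n_genes} genes")
    slot_order = list(rng.permutation(len(slots)))

    repeat_bounds = {
        c: np.array([b for iv in ivals for b in iv], dtype=np.int64)
        for c, ivals in genome.repeat_intervals.items()
    }

    expression = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    order = np.argsort(expression, kind="stable")
    quartile = np.empty(n_genes, dtype="<U2")
    for rank, gi in enumerate(order):
        quartile[gi] = f"Q{rank * 4 // n_genes + 1}"

    genes: list[GeneAnnotation] = []
    for g in range(n_genes):
        placed = None
        # a slot blocked by repeats is skipped; capacity fails only when
        # every remaining slot is exhausted
        while slot_order and placed is None:
            chrom, slot_start = slots[slot_order.pop()]
            size = genome.chrom_sizes[chrom]
            for _ in range(50):
                tss = slot_start + int(
                    rng.integers(_TSS_MARGIN, _GENE_SLOT - _TSS_MARGIN)
                )
                if not (_TSS_MARGIN <= tss <= size - _TSS_MARGIN):
                    continue
                bounds = repeat_bounds.get(chrom)
                if bounds is not None and bounds.size:
                    # reject a TSS whose promoter neighbourhood touches a repeat
                    lo, hi = tss - 1_000, tss + 1_000
                    i, j = np.searchsorted(bounds, [lo, hi])
                    if i != j or i % 2 == 1:
                        continue
                placed = tss
                break
        if placed is None:
            raise CapacityError(
                f"ran out of repeat-free gene slots after placing {g} of "
                f"{n_genes} genes"
            )
        genes.append(
            GeneAnnotation(
                gene_id=f"gene{g + 1:05d}",
                chrom=chrom,
                tss=placed,
                strand="+" if rng.random() < 0.5 else "-",
                expression=float(expression[g]),
                quartile=str(quartile[g]),
            )
        )
    return genes


def _truncated_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    """Fragment lengths ~ Normal(mean, sd) truncated to [100, 250] bp."""
    if sd <= 0:
        return np.full(n, int(round(mean)), dtype=np.int64)
    a, b = (100.0 - mean) / sd, (250.0 - mean) / sd
    vals = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.round(vals).astype(np.int64)


def _k4_nucleosome_intervals(
    genes: Sequence[GeneAnnotation], quartiles: tuple[str, ...] = ("Q4",)
) -> dict[str, np.ndarray]:
    """Nominal nucleosome footprints of the given quartiles, per chromosome.

    Returns sorted flattened boundary arrays [s1,e1,s2,e2,...] suitable for
    parity tests with searchsorted.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.quartile not in quartiles:
            continue
        sgn = 1 if g.strand == "+" else -1
        for off in NUCLEOSOME_OFFSETS:
            c = g.tss + sgn * int(off)
            per_chrom.setdefault(g.chrom, []).append(
                (c - NUCLEOSOME_HALF_WIDTH, c + NUCLEOSOME_HALF_WIDTH)
            )
    out: dict[str, np.ndarray] = {}
    for chrom, ivals in per_chrom.items():
        ivals.sort()
        merged: list[tuple[int, int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out[chrom] = np.array([b for iv in merged for b in iv], dtype=np.int64)
    return out


def simulate_fragment_pool(
    config: SimulationConfig,
    genome: GenomeModel,
    genes: Sequence[GeneAnnotation],
) -> FragmentPool:
    """Draw the unique-fragment pool and amplify it by PCR.

    Pool size is round(cells_per_ip * pool_per_cell). A fraction
    enrichment_fold/(enrichment_fold+1) of molecules carry mark-specific
    signal: H3K4me3 fragments sit on phased nucleosomes flanking TSSs with
    per-gene weight proportional to expression and a nucleosome-free zone
    at the TSS; H3K27me3 fragments fall uniformly in broad domains over
    lowest-quartile gene bodies (+/- 5 kb), excluded from active-promoter
    nucleosomes; 'input' is entirely uniform. Every molecule is then
    amplified through ``pcr_cycles`` doubling attempts with a per-molecule
    efficiency drawn once from Normal(mean, sd) clipped to [0, 1].
    """
    n_unique = int(round(config.cells_per_ip * config.pool_per_cell))
    if n_unique < 1:
        raise ConfigError(
            "cells_per_ip * pool_per_cell rounds to an empty fragment pool"
        )
    rng = np.random.default_rng(config.seed)
    chrom_names = genome.chrom_names()
    sizes = np.array([genome.chrom_sizes[c] for c in chrom_names], dtype=np.int64)

    if config.mark == "input" or config.enrichment_fold == 0:
        n_signal = 0
    else:
        n_signal = int(
            round(n_unique * config.enrichment_fold / (config.enrichment_fold + 1.0))
        )
    n_bg = n_unique - n_signal

    lengths = _truncated_lengths(
        rng, n_unique, config.fragment_length_mean, config.fragment_length_sd
    )

    chrom_idx = np.empty(n_unique, dtype=np.int32)
    start = np.empty(n_unique, dtype=np.int64)
    is_signal = np.zeros(n_unique, dtype=bool)
    is_signal[:n_signal] = True

    if n_signal:
        sig_len = lengths[:n_signal]
        if config.mark == "H3K4me3":
            c_idx, centers = _draw_k4_signal(rng, genes, chrom_names, n_signal)
        else:
            c_idx, centers = _draw_k27_signal(
                rng, genes, chrom_names, sizes, sig_len
            )
        s = centers - sig_len // 2
        s = np.clip(s, 0, sizes[c_idx] - sig_len)
        chrom_idx[:n_signal] = c_idx
        start[:n_signal] = s

    if n_bg:
        bg_len = lengths[n_signal:]
        c_idx = rng.choice(len(chrom_names), size=n_bg, p=sizes / sizes.sum())
        span = sizes[c_idx] - bg_len
        s = (rng.random(n_bg) * span).astype(np.int64)
        chrom_idx[n_signal:] = c_idx
        start[n_signal:] = s

    strand = np.where(rng.random(n_unique) < 0.5, "+", "-").astype("<U1")
    copy_number = _amplify(rng, n_unique, config)

    return FragmentPool(
        chrom_names=chrom_names,
        chrom_idx=chrom_idx,
        start=start,
        end=start + lengths,
        strand=strand,
        copy_number=copy_number,
        is_signal=is_signal,
    )


def _draw_k4_signal(
    rng: np.random.Generator,
    genes: Sequence[GeneAnnotation],
    chrom_names: list[str],
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    if not genes:
        raise ConfigError("H3K4me3 signal requires a gene annotation")
    name_to_i = {c: i for i, c in enumerate(chrom_names)}
    g_chrom = np.array([name_to_i[g.chrom] for g in genes], dtype=np.int32)
    g_tss = np.array([g.tss for g in genes], dtype=np.int64)
    g_sign = np.array([1 if g.strand == "+" else -1 for g in genes], dtype=np.int64)
    expr = np.array([g.expression for g in genes], dtype=float)
    w = expr / expr.sum()

    gi = rng.choice(len(genes), size=n, p=w)
    off = NUCLEOSOME_OFFSETS[rng.integers(0, len(NUCLEOSOME_OFFSETS), size=n)]
    centers = (
        g_tss[gi]
        + g_sign[gi] * off
        + np.round(rng.normal(0.0, NUCLEOSOME_JITTER_SD, size=n)).astype(np.int64)
    )
    # enforce the nucleosome-free zone at the TSS
    for _ in range(20):
        bad = np.abs(centers - g_tss[gi]) <= TSS_DEPLETED_HALF_WIDTH
        if not bad.any():
            break
        nb = int(bad.sum())
        off_b = NUCLEOSOME_OFFSETS[rng.integers(0, len(NUCLEOSOME_OFFSETS), size=nb)]
        centers[bad] = (
            g_tss[gi[bad]]
            + g_sign[gi[bad]] * off_b
            + np.round(rng.normal(0.0, NUCLEOSOME_JITTER_SD, size=nb)).astype(
                np.int64
            )
        )
    return g_chrom[gi], centers


def _draw_k27_signal(
    rng: np.random.Generator,
    genes: Sequence[GeneAnnotation],
    chrom_names: list[str],
    sizes: np.ndarray,
    frag_lengths: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    n = int(frag_lengths.size)
    q1 = [g for g in genes if g.quartile == "Q1"]
    if not q1:
        raise ConfigError("H3K27me3 signal requires lowest-quartile genes")
    name_to_i = {c: i for i, c in enumerate(chrom_names)}
    dom_chrom, dom_lo, dom_hi = [], [], []
    for g in q1:
        if g.strand == "+":
            lo = g.tss - BROAD_DOMAIN_FLANK
            hi = g.tss + GENE_BODY_LENGTH + BROAD_DOMAIN_FLANK
        else:
            lo = g.tss - GENE_BODY_LENGTH - BROAD_DOMAIN_FLANK
            hi = g.tss + BROAD_DOMAIN_FLANK
        ci = name_to_i[g.chrom]
        dom_chrom.append(ci)
        dom_lo.append(max(0, lo))
        dom_hi.append(min(int(sizes[ci]), hi))
    dom_chrom = np.array(dom_chrom, dtype=np.int32)
    dom_lo = np.array(dom_lo, dtype=np.int64)
    dom_hi = np.array(dom_hi, dtype=np.int64)
    dom_len = (dom_hi - dom_lo).astype(float)

    forbidden = _k4_nucleosome_intervals(genes, quartiles=("Q4",))

    c_idx = np.empty(n, dtype=np.int32)
    centers = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    for _ in range(50):
        if todo.size == 0:
            break
        di = rng.choice(len(dom_len), size=todo.size, p=dom_len / dom_len.sum())
        pos = dom_lo[di] + (rng.random(todo.size) * (dom_hi[di] - dom_lo[di])).astype(
            np.int64
        )
        ci = dom_chrom[di]
        ok = np.ones(todo.size, dtype=bool)
        L = frag_lengths[todo]
        for chrom_i in np.unique(ci):
            bounds = forbidden.get(chrom_names[chrom_i])
            if bounds is None or bounds.size == 0:
                continue
            sel = ci == chrom_i
            # reject any candidate whose full fragment extent touches a
            # forbidden active-promoter nucleosome footprint
            lo = pos[sel] - L[sel] // 2
            hi = lo + L[sel]
            i = np.searchsorted(bounds, lo, side="right")
            j = np.searchsorted(bounds, hi, side="left")
            ok[sel] = (i == j) & (i % 2 == 0)
        done = todo[ok]
        c_idx[done] = ci[ok]
        centers[done] = pos[ok]
        todo = todo[~ok]
    if todo.size:
        raise CapacityError(
            "could not place H3K27me3 fragments outside active-promoter "
            "nucleosomes after bounded retries"
        )
    return c_idx, centers


def _amplify(
    rng: np.random.Generator, n_unique: int, config: SimulationConfig
) -> np.ndarray:
    """Per-molecule branching PCR: copies += Binomial(copies, efficiency)."""
    copies = np.ones(n_unique, dtype=np.int64)
    if config.pcr_cycles == 0:
        return copies
    eff = rng.normal(
        config.pcr_efficiency_mean, config.pcr_efficiency_sd, size=n_unique
    )
    eff = np.clip(eff, 0.0, 1.0)
    for _ in range(config.pcr_cycles):
        copies = copies + rng.binomial(copies, eff)
    return copies


def _sample_without_replacement(
    rng: np.random.Generator, copies: np.ndarray, n: int
) -> np.ndarray:
    """Exact multivariate-hypergeometric draw of n copies from the pool.

    Samples n distinct copy indices uniformly from [0, total) by rejection
    (duplicate indices are redrawn), then maps indices to molecules through
    the cumulative copy-number vector. Equivalent to drawing physical
    molecules without replacement, at O(n log U) cost for any pool depth.
    """
    total = int(copies.sum())
    if n > total:
        raise ConfigError("cannot draw more copies than the pool holds")
    cum = np.cumsum(copies)
    chosen = np.unique(rng.integers(0, total, size=n))
    while chosen.size < n:
        extra = rng.integers(0, total, size=2 * (n - chosen.size) + 16)
        chosen = np.unique(np.concatenate([chosen, extra]))
    if chosen.size > n:
        chosen = rng.choice(chosen, size=n, replace=False)
    mol = np.searchsorted(cum, chosen, side="right")
    return np.bincount(mol, minlength=copies.size).astype(np.int64)


def _repeat_bounds(genome: GenomeModel | None) -> dict[str, np.ndarray]:
    if genome is None:
        return {}
    return {
        c: np.array([b for iv in ivals for b in iv], dtype=np.int64)
        for c, ivals in genome.repeat_intervals.items()
    }


def sequence_library(
    pool: FragmentPool,
    config: SimulationConfig,
    genome: GenomeModel | None = None,
) -> list[ReadRecord]:
    """Sequence ``config.n_reads`` single-end reads from the amplified pool.

    A fraction ``artifact_fraction`` of the library is unmappable artifact
    molecules (no genomic origin); of the genuine draws a further
    ``error_unmapped_fraction`` fail to map through sequencing error.
    Genuine reads sample molecules with probability proportional to PCR
    copy number -- without replacement from the physical copies when the
    amplified pool is at least as deep as the read count, otherwise with
    replacement (a warning is logged). Reads from fragments whose midpoint
    lies in a repeat interval of ``genome`` are multi-mapping. Read
    coordinates are the fragment 5' end on the molecule's strand.
    """
    if pool.n_unique == 0:
        raise ConfigError("cannot sequence an empty fragment pool")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EC]))
    n_reads = config.n_reads
    n_artifact = int(round(config.artifact_fraction * n_reads))
    n_genuine = n_reads - n_artifact
    repeat_bounds = _repeat_bounds(genome)
    chrom_names = pool.chrom_names

    mol = np.empty(0, dtype=np.int64)
    if n_genuine > 0:
        total = pool.total_copies
        if total >= n_genuine:
            counts = _sample_without_replacement(rng, pool.copy_number, n_genuine)
        else:
            logger.warning(
                "amplified pool (%d copies) shallower than requested depth "
                "(%d); sampling with replacement",
                total,
                n_genuine,
            )
            idx = np.searchsorted(
                np.cumsum(pool.copy_number),
                rng.integers(0, total, size=n_genuine),
                side="right",
            )
            counts = np.bincount(idx, minlength=pool.n_unique).astype(np.int64)
        mol = np.repeat(np.arange(pool.n_unique), counts)

    five_prime = np.where(pool.strand[mol] == "+", pool.start[mol], pool.end[mol] - 1)
    midpoint = (pool.start[mol] + pool.end[mol]) // 2
    chrom_i = pool.chrom_idx[mol]
    strands = pool.strand[mol]
    err = rng.random(n_genuine) < config.error_unmapped_fraction

    multi = np.zeros(n_genuine, dtype=bool)
    for ci, name in enumerate(chrom_names):
        bounds = repeat_bounds.get(name)
        if bounds is None or bounds.size == 0:
            continue
        sel = chrom_i == ci
        if sel.any():
            multi[sel] = np.searchsorted(bounds, midpoint[sel], side="right") % 2 == 1

    # one flat table: genuine reads then artifacts, shuffled, then named
    is_artifact = np.zeros(n_reads, dtype=bool)
    is_artifact[n_genuine:] = True
    perm = rng.permutation(n_reads)
    width = max(8, len(str(n_reads)))
    records: list[ReadRecord] = []
    for k, p in enumerate(perm):
        rid = f"read{k:0{width}d}"
        if is_artifact[p]:
            records.append(ReadRecord(rid, "unmapped", None, None, None, None))
        elif err[p]:
            records.append(ReadRecord(rid, "unmapped", None, None, None, int(mol[p])))
        else:
            records.append(
                ReadRecord(
                    rid,
                    "multi" if multi[p] else "unique",
                    chrom_names[chrom_i[p]],
                    int(five_prime[p]),
                    str(strands[p]),
                    int(mol[p]),
                )
            )
    return records


def simulate_library(
    config: SimulationConfig,
    genome: GenomeModel,
    genes: Sequence[GeneAnnotation],
) -> tuple[FragmentPool, list[ReadRecord]]:
    """Convenience: fragment pool + sequenced reads for one condition."""
    pool = simulate_fragment_pool(config, genome, genes)
    reads = sequence_library(pool, config, genome)
    return pool, reads


def write_reads(
    reads: Sequence[ReadRecord], genome: GenomeModel, path: str
) -> None:
    """Write reads as minimal single-end SAM.

    Unmapped reads carry the unmapped flag; multi-mapping reads have MAPQ 0,
    unique reads MAPQ 37. The 0-based internal 5'-end coordinate is
    converted to the SAM leftmost convention (for minus-strand reads the
    leftmost base is 5' end - read length + 1). Molecule provenance, when
    known, is stored in the XM tag. Round-trips losslessly through
    read_accounting.parse_alignments.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": c, "LN": int(genome.chrom_sizes[c])}
            for c in genome.chrom_names()
        ],
    }
    name_to_tid = {c: i for i, c in enumerate(genome.chrom_sizes)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = None
            if r.mapping_class == "unmapped":
                a.is_unmapped = True
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
            else:
                a.reference_id = name_to_tid[r.chrom]
                a.is_reverse = r.strand == "-"
                leftmost = r.start if r.strand == "+" else r.start - READ_LENGTH + 1
                if leftmost < 0 or r.start >= genome.chrom_sizes[r.chrom]:
                    raise ConfigError(
                        f"read {r.read_id} extends beyond {r.chrom} bounds"
                    )
                a.reference_start = leftmost
                a.cigarstring = f"{READ_LENGTH}M"
                a.mapping_quality = 0 if r.mapping_class == "multi" else 37
            if r.molecule_id is not None:
                a.set_tag("XM", int(r.molecule_id))
            out.write(a)
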