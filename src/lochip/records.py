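"""Core domain records shared across the pipeline.

Coordinates are 0-based half-open throughout; SAM round-tripping converts
to/from the format's 1-based convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

READ_LENGTH = 36  # bp, single-end


class LochipError(Exception):
    """Base class for package errors."""


class ConfigError(LochipError):
    """Invalid configuration or parameter value."""


class CapacityError(LochipError):
    """A placement constraint cannot be satisfied."""


class DataError(LochipError):
    """Input data violates a structural requirement."""


class ParseError(LochipError):
    """A file could not be parsed."""


class UndefinedMetricError(LochipError):
    """A metric is undefined for the given input (e.g. empty peak set)."""


@dataclass(frozen=True)
class GenomeModel:
    """A synthetic genome: chromosome sizes plus annotated repeat intervals.

    ``repeat_intervals`` maps chromosome name to a sorted, non-overlapping
    list of 0-based half-open intervals treated as multi-mapping territory.
    ``effective_genome_fraction`` is the mappable (non-repeat) fraction used
    as the Poisson-background denominator.
    """

    chrom_sizes: Mapping[str, int]
    repeat_intervals: Mapping[str, Sequence[tuple[int, int]]] = field(
        default_factory=dict
    )
    effective_genome_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ConfigError("genome must have at least one chromosome")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ConfigError(f"chromosome {chrom} has non-positive length")
        if not (0.0 < self.effective_genome_fraction <= 1.0):
            raise ConfigError("effective_genome_fraction must be in (0, 1]")
        for chrom, ivals in self.repeat_intervals.items():
            if chrom not in self.chrom_sizes:
                raise ConfigError(f"repeat intervals on unknown chromosome {chrom}")
            prev_end = 0
            for start, end in ivals:
                if not (0 <= start < end <= self.chrom_sizes[chrom]):
                    raise ConfigError(
                        f"repeat interval [{start},{end}) outside {chrom}"
                    )
                if start < prev_end:
                    raise ConfigError(f"overlapping repeat intervals on {chrom}")
                prev_end = end

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    @property
    def repeat_length(self) -> int:
        return int(
            sum(e - s for ivals in self.repeat_intervals.values() for s, e in ivals)
        )

    @property
    def effective_genome_size(self) -> int:
        """Mappable length: total minus repeat territory."""
        return self.total_length - self.repeat_length

    def chrom_names(self) -> list[str]:
        return list(self.chrom_sizes)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: TSS position, strand, expression level and its quartile.

    Quartile Q4 holds the highest-expressed genes, Q1 the lowest.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    expression: float
    quartile: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.expression < 0:
            raise ConfigError(f"negative expression for {self.gene_id}")
        if self.quartile not in ("Q1", "Q2", "Q3", "Q4"):
            raise ConfigError(f"bad quartile {self.quartile!r} for {self.gene_id}")


@dataclass
class FragmentPool:
    """Unique immunoprecipitated molecules with post-PCR copy numbers.

    Stored as parallel arrays for efficiency; ``molecules()`` yields the
    per-molecule tuples ``(chrom, start, end, strand, copy_number)``.
    """

    chrom_names: list[str]
    chrom_idx: np.ndarray  # int32 index into chrom_names
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    strand: np.ndarray  # '+'/'-' as '<U1'
    copy_number: np.ndarray  # int64, >= 1 unless dropped out in PCR
    is_signal: np.ndarray | None = None  # provenance: enriched vs background

    @property
    def n_unique(self) -> int:
        return int(self.start.size)

    @property
    def total_copies(self) -> int:
        return int(self.copy_number.sum())

    def molecules(self) -> Iterator[tuple[str, int, int, str, int]]:
        for i in range(self.n_unique):
            yield (
                self.chrom_names[self.chrom_idx[i]],
                int(self.start[i]),
                int(self.end[i]),
                str(self.strand[i]),
                int(self.copy_number[i]),
            )


@dataclass(frozen=True)
class ReadRecord:
    """A sequenced single-end read.

    ``start`` is the 5' end of the read on ``strand`` (for a minus-strand
    read this is the rightmost aligned base). ``molecule_id`` records which
    pool molecule the read came from (simulator truth); it is None for
    unmappable artifact reads and unknown for externally parsed data unless
    an XM tag was present.
    """

    read_id: str
    mapping_class: str  # 'unique' | 'multi' | 'unmapped'
    chrom: str | None
    start: int | None
    strand: str | None
    molecule_id: int | None = None

    def __post_init__(self) -> None:
        if self.mapping_class not in ("unique", "multi", "unmapped"):
            raise DataError(f"bad mapping_class {self.mapping_class!r}")
        if (self.mapping_class == "unmapped") != (self.chrom is None):
            raise DataError("unmapped reads and only unmapped reads lack a chrom")


def reads_to_arrays(
    reads: Sequence[ReadRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mapped-read fields as arrays (chrom, 5' start, strand).

    Unmapped reads are excluded. Returns object/int64/'<U1' arrays.
    """
    mapped = [r for r in reads if r.mapping_class != "unmapped"]
    chrom = np.array([r.chrom for r in mapped], dtype=object)
    start = np.fromiter((r.start for r in mapped), dtype=np.int64, count=len(mapped))
    strand = np.array([r.strand for r in mapped], dtype="<U1")
    return chrom, start, strand
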