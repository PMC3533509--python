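"""Read classification and duplicate accounting.

Breaks a single-end library into unmapped / multi-mapping / uniquely
mapping reads, splits the mapped classes into single-copy reads versus
duplicate groups (reads sharing chromosome, 5' position and strand), and
extracts the usable set -- uniquely mapping, non-duplicate reads -- that
every downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pysam

from .records import READ_LENGTH, ParseError, ReadRecord


@dataclass(frozen=True)
class ReadClassSummary:
    """Library breakdown: three mapping classes, duplicate split for mapped.

    ``multi_duplicate`` / ``unique_duplicate`` count every member of a
    duplicate group (two or more identical copies), including the group's
    representative; ``usable`` keeps one representative per unique-class
    duplicate group plus all unique-class single copies.
    """

    total: int
    unmapped: int
    multi_unique_copy: int
    multi_duplicate: int
    unique_single_copy: int
    unique_duplicate: int
    usable: int

    def __post_init__(self) -> None:
        parts = (
            self.unmapped
            + self.multi_unique_copy
            + self.multi_duplicate
            + self.unique_single_copy
            + self.unique_duplicate
        )
        if parts != self.total:
            raise ValueError("class counts do not partition the total")
        if min(
            self.total,
            self.unmapped,
            self.multi_unique_copy,
            self.multi_duplicate,
            self.unique_single_copy,
            self.unique_duplicate,
            self.usable,
        ) < 0:
            raise ValueError("negative class count")
        if self.usable > self.unique_single_copy + self.unique_duplicate:
            raise ValueError("usable exceeds unique-class reads")


def render_count(n: int) -> str:
    """Human-readable count with space-separated thousands (e.g. 13 402 262)."""
    return f"{n:,}".replace(",", " ")


def parse_alignments(path: str) -> list[ReadRecord]:
    """Read a single-end SAM file into ReadRecords.

    Mapping class comes from the flags and mapping quality: the unmapped
    flag wins, MAPQ 0 means multi-mapping, anything else uniquely mapping.
    Coordinates are converted to the internal 0-based 5'-end convention
    (reference_end - 1 for minus-strand reads). The XM tag, when present,
    restores molecule provenance.
    """
    try:
        sam = pysam.AlignmentFile(path, "r", check_sq=False)
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: cannot open as SAM: {exc}") from exc
    records: list[ReadRecord] = []
    with sam:
        if not sam.header.get("SQ"):
            raise ParseError(f"{path}: SAM header has no @SQ lines")
        for i, aln in enumerate(sam, start=1):
            try:
                mol = aln.get_tag("XM") if aln.has_tag("XM") else None
                if aln.is_unmapped:
                    records.append(
                        ReadRecord(aln.query_name, "unmapped", None, None, None, mol)
                    )
                    continue
                strand = "-" if aln.is_reverse else "+"
                if aln.is_reverse:
                    end = aln.reference_end
                    if end is None:  # no CIGAR: fall back to fixed read length
                        end = aln.reference_start + READ_LENGTH
                    five_prime = end - 1
                else:
                    five_prime = aln.reference_start
                cls = "multi" if aln.mapping_quality == 0 else "unique"
                records.append(
                    ReadRecord(
                        aln.query_name,
                        cls,
                        aln.reference_name,
                        int(five_prime),
                        strand,
                        mol,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ParseError(
                    f"{path}: malformed record at alignment line {i}: {exc}"
                ) from exc
    return records


def mark_duplicates(
    reads: Sequence[ReadRecord],
) -> list[tuple[ReadRecord, bool]]:
    """Flag duplicate reads; one representative per group survives.

    Reads of the same mapping class sharing (chrom, 5' position, strand)
    form a duplicate group; the lexicographically first read_id in each
    group is the non-duplicate representative. Unmapped reads are never
    flagged. Input order is preserved.
    """
    best: dict[tuple, str] = {}
    for r in reads:
        if r.mapping_class == "unmapped":
            continue
        key = (r.mapping_class, r.chrom, r.start, r.strand)
        cur = best.get(key)
        if cur is None or r.read_id < cur:
            best[key] = r.read_id
    out: list[tuple[ReadRecord, bool]] = []
    for r in reads:
        if r.mapping_class == "unmapped":
            out.append((r, False))
        else:
            key = (r.mapping_class, r.chrom, r.start, r.strand)
            out.append((r, best[key] != r.read_id))
    return out


def summarize_classes(
    flagged: Sequence[tuple[ReadRecord, bool]],
) -> ReadClassSummary:
    """Count reads per mapping class and duplicate status."""
    group_size: dict[tuple, int] = {}
    for r, _ in flagged:
        if r.mapping_class == "unmapped":
            continue
        key = (r.mapping_class, r.chrom, r.start, r.strand)
        group_size[key] = group_size.get(key, 0) + 1

    unmapped = multi_uc = multi_dup = uniq_sc = uniq_dup = 0
    usable = 0
    for r, is_dup in flagged:
        if r.mapping_class == "unmapped":
            unmapped += 1
            continue
        key = (r.mapping_class, r.chrom, r.start, r.strand)
        in_dup_group = group_size[key] >= 2
        if r.mapping_class == "multi":
            if in_dup_group:
                multi_dup += 1
            else:
                multi_uc += 1
        else:
            if in_dup_group:
                uniq_dup += 1
            else:
                uniq_sc += 1
            if not is_dup:
                usable += 1
    return ReadClassSummary(
        total=len(flagged),
        unmapped=unmapped,
        multi_unique_copy=multi_uc,
        multi_duplicate=multi_dup,
        unique_single_copy=uniq_sc,
        unique_duplicate=uniq_dup,
        usable=usable,
    )


def filter_usable_reads(
    flagged: Sequence[tuple[ReadRecord, bool]],
) -> list[ReadRecord]:
    """Uniquely mapping, non-duplicate reads, sorted deterministically."""
    usable = [
        r for r, is_dup in flagged if r.mapping_class == "unique" and not is_dup
    ]
    usable.sort(key=lambda r: (r.chrom, r.start, r.strand, r.read_id))
    return usable


def account(reads: Sequence[ReadRecord]) -> tuple[ReadClassSummary, list[ReadRecord]]:
    """Mark duplicates, summarize classes, and return the usable set."""
    flagged = mark_duplicates(reads)
    return summarize_classes(flagged), filter_usable_reads(flagged)
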