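"""Plain-text format plumbing: BED6 reads/peaks, annotation TSV, YAML config."""

from __future__ import annotations

from typing import Sequence

import pandas as pd
import yaml

from .peak_calling import PeakInterval
from .records import GeneAnnotation, ParseError, ReadRecord
from .sim_chipseq import SimulationConfig


def write_reads_bed(reads: Sequence[ReadRecord], path: str) -> None:
    """Usable reads as BED6: one 1 bp feature at the 5' end, score 0."""
    with open(path, "w") as fh:
        for r in reads:
            if r.mapping_class == "unmapped":
                raise ParseError("cannot write unmapped reads to BED")
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.start + 1}\t{r.read_id}\t0\t{r.strand}\n"
            )


def read_reads_bed(path: str) -> list[ReadRecord]:
    reads: list[ReadRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{ln}: expected 6 BED columns")
            chrom, start, _end, name, _score, strand = parts[:6]
            reads.append(
                ReadRecord(name, "unique", chrom, int(start), strand, None)
            )
    return reads


def write_peaks_bed(peaks: Sequence[PeakInterval], path: str) -> None:
    """Peaks as BED6+: name, score=-log10 p, strand '.', summit offset,
    read count in columns 7-8."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, start=1):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t{p.score:.4g}\t.\t"
                f"{p.summit - p.start}\t{p.read_count}\n"
            )


def read_peaks_bed(path: str) -> list[PeakInterval]:
    peaks: list[PeakInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            score = float(parts[4]) if len(parts) > 4 else 0.0
            summit_off = int(parts[6]) if len(parts) > 6 else (end - start) // 2
            count = int(parts[7]) if len(parts) > 7 else 1
            peaks.append(
                PeakInterval(
                    chrom=chrom,
                    start=start,
                    end=end,
                    read_count=max(count, 1),
                    score=score,
                    summit=start + summit_off,
                )
            )
    return peaks


def write_annotation_tsv(genes: Sequence[GeneAnnotation], path: str) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
            "expression": [g.expression for g in genes],
            "quartile": [g.quartile for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand", "expression"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if "quartile" not in df.columns:
        # derive quartiles from expression ranks, Q4 highest
        order = df["expression"].rank(method="first").astype(int) - 1
        df["quartile"] = [f"Q{r * 4 // len(df) + 1}" for r in order]
    return [
        GeneAnnotation(
            gene_id=str(row.gene_id),
            chrom=str(row.chrom),
            tss=int(row.tss),
            strand=str(row.strand),
            expression=float(row.expression),
            quartile=str(row.quartile),
        )
        for row in df.itertuples()
    ]


def load_sim_config(path: str) -> SimulationConfig:
    """SimulationConfig from a YAML mapping of its field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a YAML mapping")
    try:
        return SimulationConfig(**data)
    except TypeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
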