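"""Genomic coordinate primitives.

All coordinates are 0-based, half-open (BED convention): an interval with
``start=0, end=500`` covers the first 500 bases of a chromosome. These two
classes are the coordinate currency of the whole package; every module
accepts and returns them (or plain DataFrames carrying chrom/start/end
columns that round-trip through them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware transcription start / end boundaries.

    ``tss`` and ``tes`` are boundary coordinates: on the + strand the TSS is
    the interval start and the TES its end; on the - strand the TSS is the
    interval end and the TES its start. Promoters and downstream regions are
    derived from these boundaries by the annotation module.
    """

    gene_id: str
    interval: GenomicInterval
    tss: int = field(init=False)
    tes: int = field(init=False)

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.interval.strand == "+":
            object.__setattr__(self, "tss", self.interval.start)
            object.__setattr__(self, "tes", self.interval.end)
        else:
            object.__setattr__(self, "tss", self.interval.end)
            object.__setattr__(self, "tes", self.interval.start)

    @property
    def strand(self) -> str:
        return self.interval.strand


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is <= ``max_gap`` (touching merges at 0).

    Strand information is discarded; output is sorted and pairwise disjoint.
    """
    ivs = sort_intervals(intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= max_gap:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def subtract_intervals(
    intervals: Sequence[GenomicInterval], mask: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Remove every base covered by ``mask`` from ``intervals``."""
    mask_sorted = merge_intervals(mask)
    out: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        pieces = [(iv.start, iv.end)]
        for m in mask_sorted:
            if m.chrom != iv.chrom or m.end <= iv.start:
                continue
            if m.start >= iv.end:
                break
            nxt: list[tuple[int, int]] = []
            for s, e in pieces:
                if m.end <= s or m.start >= e:
                    nxt.append((s, e))
                    continue
                if m.start > s:
                    nxt.append((s, m.start))
                if m.end < e:
                    nxt.append((m.end, e))
            pieces = nxt
        out.extend(GenomicInterval(iv.chrom, s, e) for s, e in pieces)
    return sort_intervals(out)
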