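"""Fixed-width genome binning and per-bin content/read aggregation.

The genome is tiled into 500 bp bins (the unit at which differential
methylation is tested). For each bin we count CpG dinucleotides (the signal
carrier for MeDIP enrichment) and methylation-sensitive restriction enzyme
(MRE) recognition sites (the signal carrier for MRE-seq), and aggregate read
5' positions into per-bin counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

DEFAULT_BIN_WIDTH = 500

#: HpaII / Hin6I / AciI style recognition sites. The assay's enzyme panel is
#: a protocol choice, so the set is a parameter everywhere it is used.
DEFAULT_MRE_MOTIFS = frozenset({"CCGG", "GCGC", "CCGC"})


@dataclass(frozen=True)
class BinRecord:
    """One genomic bin with its sequence content and per-sample counts."""

    interval: GenomicInterval
    cpg_count: int
    mre_site_count: int
    medip_counts: tuple[int, ...]
    mre_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.cpg_count < 0 or self.mre_site_count < 0:
            raise ValueError("negative content counts")
        if any(c < 0 for c in self.medip_counts) or any(c < 0 for c in self.mre_counts):
            raise ValueError("negative read counts")


def make_bins(
    genome_lengths: Mapping[str, int], width: int = DEFAULT_BIN_WIDTH
) -> list[GenomicInterval]:
    """Tile each chromosome from offset 0 in steps of ``width``.

    The terminal bin of a chromosome is truncated at the chromosome end.
    Output is sorted by (chrom, start).
    """
    if width < 1:
        raise ValueError(f"bin width must be >= 1, got {width}")
    bins: list[GenomicInterval] = []
    for chrom in sorted(genome_lengths):
        length = genome_lengths[chrom]
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}: {length}")
        for start in range(0, length, width):
            bins.append(GenomicInterval(chrom, start, min(start + width, length)))
    return bins


def count_overlapping(sequence: str, motif: str) -> int:
    """Occurrences of ``motif`` in ``sequence``, overlaps counted."""
    if not motif:
        raise ValueError("empty motif string")
    return len(re.findall(f"(?={re.escape(motif)})", sequence))


def bin_content(
    sequence: str, mre_motifs: Iterable[str] = DEFAULT_MRE_MOTIFS
) -> tuple[int, int]:
    """CpG and MRE-site counts for one bin's sequence.

    CpG count is the number of CG dinucleotides. MRE-site count is the total
    number of occurrences of any motif; overlapping occurrences of distinct
    motifs are each counted. N bases never match.
    """
    motifs = list(mre_motifs)
    if not motifs or any(not m for m in motifs):
        raise ValueError("MRE motif set must be non-empty strings")
    seq = sequence.upper()
    cpg = count_overlapping(seq, "CG") if seq else 0
    mre = sum(count_overlapping(seq, m.upper()) for m in motifs)
    return cpg, mre


def bin_content_table(
    genome: Mapping[str, str],
    bins: Sequence[GenomicInterval],
    mre_motifs: Iterable[str] = DEFAULT_MRE_MOTIFS,
) -> pd.DataFrame:
    """Per-bin content for all bins; CpGs spanning a bin boundary count left.

    A CG whose C is the last base of a bin belongs to that (left) bin, so
    content is computed on ``sequence[start : end + 1]`` for the CpG count
    while MRE motifs are similarly allowed to start inside the bin.
    """
    motifs = [m.upper() for m in mre_motifs]
    if not motifs or any(not m for m in motifs):
        raise ValueError("MRE motif set must be non-empty strings")
    max_len = max(len(m) for m in motifs)
    rows = []
    for b in bins:
        seq = genome[b.chrom].upper()
        # extend so dinucleotides/motifs *starting* in the bin are counted here
        ext = seq[b.start : min(b.end + max(1, max_len - 1), len(seq))]
        core_len = b.end - b.start
        cpg = sum(
            1 for i in range(min(core_len, len(ext) - 1)) if ext[i : i + 2] == "CG"
        )
        mre = 0
        for m in motifs:
            mre += sum(
                1 for i in range(min(core_len, len(ext) - len(m) + 1))
                if ext[i : i + len(m)] == m
            )
        rows.append((b.chrom, b.start, b.end, cpg, mre))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cpg_count", "mre_site_count"])


def _check_bins_sorted(bins: Sequence[GenomicInterval]) -> None:
    for prev, cur in zip(bins, bins[1:]):
        if cur.chrom == prev.chrom and cur.start < prev.end:
            raise ValueError(f"bins unsorted or overlapping at {prev} / {cur}")
        if cur.chrom < prev.chrom:
            raise ValueError("bins not sorted by chromosome")


def assign_reads(
    read_intervals: Sequence[GenomicInterval],
    bins: Sequence[GenomicInterval],
    rule: str = "five_prime",
) -> tuple[np.ndarray, int]:
    """Assign each read to exactly one bin by a single representative base.

    ``rule='five_prime'`` uses the 5'-most base (start for +/unstranded
    reads, end-1 for - strand reads); ``rule='midpoint'`` uses the midpoint.
    Returns (per-bin counts aligned with ``bins``, number of dropped reads).
    Single-base assignment guarantees assigned + dropped == total.
    """
    if rule not in ("five_prime", "midpoint"):
        raise ValueError(f"unknown assignment rule: {rule}")
    _check_bins_sorted(bins)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {b.chrom for b in bins}:
        idx = np.array([i for i, b in enumerate(bins) if b.chrom == chrom])
        starts = np.array([bins[i].start for i in idx])
        ends = np.array([bins[i].end for i in idx])
        by_chrom[chrom] = (idx, starts, ends)

    counts = np.zeros(len(bins), dtype=np.int64)
    dropped = 0
    for r in read_intervals:
        if rule == "five_prime":
            pos = r.end - 1 if r.strand == "-" else r.start
        else:
            pos = (r.start + r.end) // 2
        entry = by_chrom.get(r.chrom)
        if entry is None:
            dropped += 1
            continue
        idx, starts, ends = entry
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        if j < 0 or pos >= ends[j]:
            dropped += 1
            continue
        counts[idx[j]] += 1
    return counts, dropped
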