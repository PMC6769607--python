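"""Linking intergenic DMRs to genes through chromatin domains (TADs).

The procedure mirrors how distal regulatory candidates are assigned target
genes when contact maps exist only for another species: (1) keep DMRs whose
mean per-base conservation over the bin exceeds 0.5 (strict), (2) map the
DMR to the assembly carrying the contact map through an offset-preserving
block table, (3) find the TAD containing the mapped DMR within a +/- 1 Mb
search window (smallest domain if nested), and (4) take every gene whose
body overlaps that TAD as an in-contact gene. Contact genes then feed the
enrichment module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval

DEFAULT_CONSERVATION_THRESHOLD = 0.5
DEFAULT_TAD_WINDOW = 1_000_000


@dataclass(frozen=True)
class MappingBlock:
    """One colinear source->target block of a coordinate mapping table."""

    src: GenomicInterval
    tgt_chrom: str
    tgt_start: int

    def map_pos(self, pos: int) -> int:
        return self.tgt_start + (pos - self.src.start)


@dataclass(frozen=True)
class TadLink:
    dmr: GenomicInterval
    mean_score: float
    mapped: GenomicInterval | None
    tad: GenomicInterval | None
    contact_genes: tuple[str, ...]


class ConservationTrack:
    """Per-base conservation scores in [0, 1] per chromosome."""

    def __init__(self, scores: Mapping[str, np.ndarray]):
        self.scores = {}
        for chrom, arr in scores.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                raise ValueError(f"{chrom}: conservation scores outside [0, 1]")
            self.scores[chrom] = arr

    def extent(self, chrom: str) -> int:
        return len(self.scores[chrom])


def mean_conservation(
    interval: GenomicInterval,
    track: ConservationTrack | Mapping[str, np.ndarray],
    threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
) -> tuple[float, bool]:
    """Mean score over every base of the interval; passes iff mean > threshold.

    Bases without a score would contribute 0, but the interval must start
    inside the track's extent.
    """
    if not isinstance(track, ConservationTrack):
        track = ConservationTrack(track)
    if interval.chrom not in track.scores:
        raise ValueError(f"no conservation track for {interval.chrom}")
    arr = track.scores[interval.chrom]
    if interval.start >= len(arr):
        raise ValueError(f"interval {interval} outside track extent {len(arr)}")
    scored = arr[interval.start : min(interval.end, len(arr))]
    mean = float(scored.sum() / interval.width)  # missing tail bases count 0
    return mean, mean > threshold


def read_mapping_blocks(rows) -> list[MappingBlock]:
    """Build mapping blocks from (src_chrom, src_start, src_end, tgt_chrom,
    tgt_start) tuples or a DataFrame with those columns; blocks must be
    non-overlapping in source coordinates."""
    if isinstance(rows, pd.DataFrame):
        rows = rows[["src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start"]].itertuples(index=False)
    blocks = []
    for src_chrom, src_start, src_end, tgt_chrom, tgt_start in rows:
        if src_end <= src_start or src_start < 0 or tgt_start < 0:
            raise ValueError("malformed mapping block")
        blocks.append(
            MappingBlock(GenomicInterval(src_chrom, int(src_start), int(src_end)),
                         str(tgt_chrom), int(tgt_start))
        )
    blocks.sort(key=lambda b: (b.src.chrom, b.src.start))
    for a, b in zip(blocks, blocks[1:]):
        if a.src.chrom == b.src.chrom and b.src.start < a.src.end:
            raise ValueError("mapping blocks overlap in source coordinates")
    return blocks


def map_interval(
    interval: GenomicInterval,
    mapping: Sequence[MappingBlock] | None,
    min_coverage: float = 1.0,
) -> GenomicInterval | None:
    """Translate an interval through the block covering it (offset-preserving).

    ``mapping=None`` is the identity (single-assembly synthetic runs).
    Returns None when no single block covers at least ``min_coverage`` of
    the interval; the mapped interval is the image of the covered part.
    """
    if mapping is None:
        return interval
    best = None
    best_cov = 0.0
    for block in mapping:
        ov = block.src.overlap_len(interval)
        if ov > best_cov:
            best_cov = ov
            best = block
    if best is None or best_cov / interval.width < min_coverage:
        return None
    s = max(interval.start, best.src.start)
    e = min(interval.end, best.src.end)
    return GenomicInterval(best.tgt_chrom, best.map_pos(s), best.map_pos(e))


def link_dmr_to_genes(
    dmr: GenomicInterval,
    tads: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_TAD_WINDOW,
    mapping: Sequence[MappingBlock] | None = None,
    conservation: ConservationTrack | Mapping[str, np.ndarray] | None = None,
    threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
) -> TadLink:
    """Full linkage for one DMR; deterministic and TAD-order invariant.

    When a conservation track is supplied the DMR must pass the mean-score
    filter, otherwise no link is attempted. The containing TAD must include
    the whole (mapped) DMR; the smallest containing domain wins if domains
    nest; DMRs spanning a domain boundary yield no link.
    """
    mean_score = float("nan")
    if conservation is not None:
        mean_score, passes = mean_conservation(dmr, conservation, threshold)
        if not passes:
            return TadLink(dmr, mean_score, None, None, ())
    mapped = map_interval(dmr, mapping)
    if mapped is None:
        return TadLink(dmr, mean_score, None, None, ())
    search = GenomicInterval(
        mapped.chrom, max(0, mapped.start - window), mapped.end + window
    )
    containing = [
        t for t in tads if t.overlaps(search) and t.contains(mapped)
    ]
    if not containing:
        return TadLink(dmr, mean_score, mapped, None, ())
    tad = min(containing, key=lambda t: (t.width, t.start))
    contact = tuple(sorted(g.gene_id for g in genes if g.interval.overlaps(tad)))
    return TadLink(dmr, mean_score, mapped, tad, contact)


def link_dmrs(
    dmrs: Sequence[GenomicInterval],
    tads: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    conservation: ConservationTrack | Mapping[str, np.ndarray],
    window: int = DEFAULT_TAD_WINDOW,
    mapping: Sequence[MappingBlock] | None = None,
    threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
) -> list[TadLink]:
    """Conservation-filtered TAD linkage over a DMR list."""
    return [
        link_dmr_to_genes(d, tads, genes, window, mapping, conservation, threshold)
        for d in dmrs
    ]
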