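"""CpG island / shore detection and DMR context annotation.

A CpG island is a maximal sequence segment satisfying the three classical
criteria: length > 200 bp, GC fraction > 0.5, and observed-to-expected CpG
ratio > 0.6, with O/E computed in the Gardiner-Garden convention
O/E = (N_CpG * L) / (N_C * N_G). Detection follows a Takai–Jones style scan:
200 bp seed windows at 1 bp step, merging of nearby seeds (gap < 100 bp),
then trimming until the merged segment itself satisfies all criteria. Every
emitted island re-verifies the criteria; this is asserted, not assumed.

Shores are the 2,000 bp regions flanking each island on either side (island
bases subtracted, overlapping fragments merged). Each DMR receives exactly
one label per axis:

* island context: island > shore > open (any-overlap, stated precedence)
* gene context: promoter > intragenic > downstream > intergenic, with
  strand-aware 1,500 bp promoter (upstream of TSS) and downstream (past the
  TES) flanks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import GeneModel, GenomicInterval, merge_intervals, sort_intervals, subtract_intervals
from .mnm import round_half_up

MIN_ISLAND_LEN = 201  # "greater than 200 bp", read strictly
MIN_ISLAND_GC = 0.5
MIN_ISLAND_OE = 0.6
SHORE_FLANK = 2000
PROMOTER_FLANK = 1500
DOWNSTREAM_FLANK = 1500

ISLAND_CONTEXTS = ("island", "shore", "open")
GENE_CONTEXTS = ("promoter", "intragenic", "downstream", "intergenic")


@dataclass(frozen=True)
class IslandAnnotation:
    islands: tuple[GenomicInterval, ...]
    shores: tuple[GenomicInterval, ...]


class _SeqStats:
    """O(1) GC / C / G / CpG counts over arbitrary subintervals via cumsums."""

    def __init__(self, seq: str):
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        is_cpg = np.zeros(len(arr), dtype=bool)
        if len(arr) > 1:
            is_cpg[:-1] = is_c[:-1] & is_g[1:]
        self.c = np.concatenate([[0], np.cumsum(is_c)])
        self.g = np.concatenate([[0], np.cumsum(is_g)])
        self.cpg = np.concatenate([[0], np.cumsum(is_cpg)])
        self.n = len(arr)

    def counts(self, start: int, end: int) -> tuple[int, int, int]:
        """(N_C, N_G, N_CpG) in [start, end); CpGs fully inside only."""
        nc = int(self.c[end] - self.c[start])
        ng = int(self.g[end] - self.g[start])
        ncpg = int(self.cpg[max(end - 1, start)] - self.cpg[start])
        return nc, ng, ncpg


def island_criteria(
    seq_or_stats,
    start: int = 0,
    end: int | None = None,
    min_len: int = MIN_ISLAND_LEN,
    min_gc: float = MIN_ISLAND_GC,
    min_oe: float = MIN_ISLAND_OE,
) -> bool:
    """Do the three island criteria all hold on the given segment?"""
    st = seq_or_stats if isinstance(seq_or_stats, _SeqStats) else _SeqStats(seq_or_stats)
    if end is None:
        end = st.n
    length = end - start
    if length < min_len:
        return False
    nc, ng, ncpg = st.counts(start, end)
    if (nc + ng) / length <= min_gc:
        return False
    if nc == 0 or ng == 0:
        return False
    oe = ncpg * length / (nc * ng)
    return oe > min_oe


def _gc_oe(st: _SeqStats, start: int, end: int) -> tuple[float, float]:
    nc, ng, ncpg = st.counts(start, end)
    length = end - start
    gc = (nc + ng) / length if length else 0.0
    oe = ncpg * length / (nc * ng) if nc and ng else 0.0
    return gc, oe


def find_cpg_islands(
    sequence: str,
    min_len: int = MIN_ISLAND_LEN,
    min_gc: float = MIN_ISLAND_GC,
    min_oe: float = MIN_ISLAND_OE,
    seed_window: int = 200,
    merge_gap: int = 100,
) -> list[tuple[int, int]]:
    """Detect CpG islands in one sequence; returns (start, end) pairs.

    Sequences shorter than the seed window (or all-N) yield no islands.
    Every returned segment satisfies all three criteria (hard postcondition).
    """
    st = _SeqStats(sequence)
    n = st.n
    if n < seed_window:
        return []
    starts = np.arange(0, n - seed_window + 1)
    nc = st.c[starts + seed_window] - st.c[starts]
    ng = st.g[starts + seed_window] - st.g[starts]
    ncpg = st.cpg[starts + seed_window - 1] - st.cpg[starts]
    gc_ok = (nc + ng) / seed_window > min_gc
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((nc > 0) & (ng > 0), ncpg * seed_window / (nc * ng), 0.0)
    passing = gc_ok & (oe > min_oe)
    if not passing.any():
        return []

    # runs of consecutive passing seed starts -> candidate segments
    idx = np.flatnonzero(passing)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]])
    candidates = [(int(s), int(e) + seed_window) for s, e in zip(run_starts, run_ends)]

    # merge candidates separated by < merge_gap
    merged: list[list[int]] = []
    for s, e in candidates:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    islands: list[tuple[int, int]] = []
    for s, e in merged:
        trimmed = _trim_to_criteria(st, s, e, min_len, min_gc, min_oe)
        if trimmed is not None:
            islands.append(trimmed)

    for s, e in islands:  # hard postcondition
        assert island_criteria(st, s, e, min_len, min_gc, min_oe), (s, e)
    return islands


def _trim_to_criteria(st, s, e, min_len, min_gc, min_oe):
    """Shrink [s, e) one base at a time until all criteria hold (or give up).

    At each step the end whose removal scores better on (GC, capped O/E) is
    dropped; ties go left. Greedy, but candidates come from passing seed
    windows so only short non-conforming fringes ever need removal.
    """
    while e - s >= min_len:
        if island_criteria(st, s, e, min_len, min_gc, min_oe):
            return (s, e)
        gc_l, oe_l = _gc_oe(st, s + 1, e)
        gc_r, oe_r = _gc_oe(st, s, e - 1)
        score_l = gc_l + min(oe_l, 1.0)
        score_r = gc_r + min(oe_r, 1.0)
        if score_l >= score_r:
            s += 1
        else:
            e -= 1
    return None


def find_cpg_islands_genome(
    genome: Mapping[str, str], **kwargs
) -> list[GenomicInterval]:
    """Run the island detector per chromosome; sorted interval list."""
    out = []
    for chrom in sorted(genome):
        for s, e in find_cpg_islands(genome[chrom], **kwargs):
            out.append(GenomicInterval(chrom, s, e))
    return out


def derive_shores(
    islands: Sequence[GenomicInterval],
    genome_lengths: Mapping[str, int],
    flank: int = SHORE_FLANK,
) -> list[GenomicInterval]:
    """2,000 bp flanks of each island, clipped, island-subtracted, merged."""
    raw: list[GenomicInterval] = []
    for iv in islands:
        limit = genome_lengths[iv.chrom]
        left_start = max(0, iv.start - flank)
        if left_start < iv.start:
            raw.append(GenomicInterval(iv.chrom, left_start, iv.start))
        right_end = min(limit, iv.end + flank)
        if iv.end < right_end:
            raw.append(GenomicInterval(iv.chrom, iv.end, right_end))
    if not raw:
        return []
    merged = merge_intervals(raw)
    return subtract_intervals(merged, list(islands))


def _tree(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


class GenomeAnnotator:
    """Pre-indexed island/shore/gene features for fast DMR classification."""

    def __init__(
        self,
        islands: Sequence[GenomicInterval],
        shores: Sequence[GenomicInterval],
        genes: Sequence[GeneModel],
        genome_lengths: Mapping[str, int] | None = None,
        promoter_flank: int = PROMOTER_FLANK,
        downstream_flank: int = DOWNSTREAM_FLANK,
    ):
        self._islands = _tree(islands)
        self._shores = _tree(shores)
        promoters, bodies, downstreams = [], [], []
        for g in genes:
            limit = genome_lengths[g.interval.chrom] if genome_lengths else None
            bodies.append(g.interval)
            if g.strand == "+":
                pr = (g.tss - promoter_flank, g.tss)
                dn = (g.tes, g.tes + downstream_flank)
            else:
                pr = (g.tss, g.tss + promoter_flank)
                dn = (g.tes - downstream_flank, g.tes)
            for target, (s, e) in ((promoters, pr), (downstreams, dn)):
                s = max(0, s)
                if limit is not None:
                    e = min(limit, e)
                if s < e:
                    target.append(GenomicInterval(g.interval.chrom, s, e))
        self._promoters = _tree(promoters)
        self._bodies = _tree(bodies)
        self._downstreams = _tree(downstreams)

    def _hits(self, trees: dict[str, IntervalTree], dmr: GenomicInterval) -> bool:
        tree = trees.get(dmr.chrom)
        return bool(tree and tree.overlap(dmr.start, dmr.end))

    def annotate(self, dmr: GenomicInterval) -> tuple[str, str]:
        """(island_context, gene_context) for one DMR; any-overlap with the
        precedences island > shore and promoter > intragenic > downstream."""
        if self._hits(self._islands, dmr):
            island_context = "island"
        elif self._hits(self._shores, dmr):
            island_context = "shore"
        else:
            island_context = "open"
        if self._hits(self._promoters, dmr):
            gene_context = "promoter"
        elif self._hits(self._bodies, dmr):
            gene_context = "intragenic"
        elif self._hits(self._downstreams, dmr):
            gene_context = "downstream"
        else:
            gene_context = "intergenic"
        return island_context, gene_context

    def overlapping_genes(self, region: GenomicInterval, genes: Sequence[GeneModel]) -> list[str]:
        return [g.gene_id for g in genes if g.interval.overlaps(region)]


def annotate_dmr(
    dmr: GenomicInterval,
    islands: Sequence[GenomicInterval],
    shores: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_flank: int = PROMOTER_FLANK,
    downstream_flank: int = DOWNSTREAM_FLANK,
    genome_lengths: Mapping[str, int] | None = None,
) -> tuple[str, str]:
    """One-shot annotation of a single DMR (builds a throwaway index)."""
    ann = GenomeAnnotator(
        islands, shores, genes, genome_lengths, promoter_flank, downstream_flank
    )
    return ann.annotate(dmr)


def summarize_contexts(
    counts: Mapping[str, int], total: int | None = None
) -> dict:
    """Category counts with one-decimal percentages (round half up).

    ``total`` defaults to the sum of counts; pass it explicitly when
    categories are not exhaustive (or overlap) and percentages should be
    taken over the full DMR set.
    """
    total = int(total) if total is not None else int(sum(counts.values()))
    out: dict = {"total": total, "counts": dict(counts), "percentages": {}}
    if total == 0:
        warnings.warn("empty DMR set; percentages reported as 0")
        out["percentages"] = {k: 0.0 for k in counts}
        return out
    out["percentages"] = {
        k: round_half_up(100.0 * v / total) for k, v in counts.items()
    }
    return out


def summarize_annotated(labels: Sequence[tuple[str, str]]) -> dict:
    """Fig-2C/2D style summary from per-DMR (island_context, gene_context)."""
    island_counts = {k: 0 for k in ISLAND_CONTEXTS}
    gene_counts = {k: 0 for k in GENE_CONTEXTS}
    for island_context, gene_context in labels:
        island_counts[island_context] += 1
        gene_counts[gene_context] += 1
    return {
        "island_axis": summarize_contexts(island_counts),
        "gene_axis": summarize_contexts(gene_counts),
    }
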