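"""Synthetic two-group MeDIP/MRE data with known ground truth.

Everything the pipeline consumes can be generated here: a genome with
planted CpG islands over a CpG-depleted background, gene models, TADs, a
conservation track with high-scoring blocks, per-bin methylation levels
with planted DMRs, Poisson read counts for both assays, gene sets, and
MSP / qPCR-style validation measurements. All generators are deterministic
for a fixed seed.

Design of the sequence background: GC is fixed at 40% with strong CpG
depletion (O/E ~ 0.2), mirroring vertebrate genome statistics, so planted
islands (GC > 50%, O/E > 0.6) are unambiguous to the detector. MRE
recognition sites are planted motif occurrences; a CpG inside a planted
motif counts toward both the CpG and the MRE-site content of its bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import find_cpg_islands, island_criteria
from .binning import DEFAULT_BIN_WIDTH, DEFAULT_MRE_MOTIFS, bin_content_table, make_bins
from .intervals import GeneModel, GenomicInterval

BACKGROUND_GC = 0.40
BACKGROUND_OE = 0.20


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset (filled incrementally)."""

    genome: dict[str, str] = field(default_factory=dict)
    true_islands: list[GenomicInterval] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    tads: list[GenomicInterval] = field(default_factory=list)
    conservation: dict[str, np.ndarray] = field(default_factory=dict)
    true_methylation: np.ndarray | None = None  # (n_bins, 2) in [0, 1]
    true_dmr_bins: dict[int, str] = field(default_factory=dict)  # index -> up/down
    library_sizes: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def genome_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


# ---------------------------------------------------------------------------
# sequence generation


def _random_sequence(rng: np.random.Generator, length: int, gc: float, oe: float) -> str:
    """Sequence with target GC fraction and CpG observed/expected ratio.

    CG dinucleotides are planted explicitly at the density implied by
    (gc, oe); remaining positions are filled from a base multiset matching
    the GC target while avoiding accidental CG formation.
    """
    n_cpg = int(round(oe * (gc / 2.0) ** 2 * length))
    seq = np.full(length, b"", dtype="S1")
    planted = np.zeros(length, dtype=bool)
    if n_cpg > 0 and length >= 2:
        slots = np.arange(0, length - 1, 2)
        pos = rng.choice(slots, size=min(n_cpg, len(slots)), replace=False)
        seq[pos] = b"C"
        seq[pos + 1] = b"G"
        planted[pos] = True
        planted[pos + 1] = True
        n_cpg = len(pos)
    n_fill = length - 2 * n_cpg
    n_c = max(0, int(round(gc * length / 2.0)) - n_cpg)
    n_g = max(0, int(round(gc * length / 2.0)) - n_cpg)
    n_c, n_g = min(n_c, n_fill), min(n_g, n_fill)
    if n_c + n_g > n_fill:
        n_g = n_fill - n_c
    n_at = n_fill - n_c - n_g
    fill = np.array(
        [b"C"] * n_c + [b"G"] * n_g
        + [b"A"] * (n_at // 2) + [b"T"] * (n_at - n_at // 2),
        dtype="S1",
    )
    rng.shuffle(fill)
    fill_list = fill.tolist()
    out = seq.tolist()
    prev = b""
    qi = 0
    for i in range(length):
        if planted[i]:
            prev = out[i]
            continue
        ch = fill_list[qi]
        if prev == b"C" and ch == b"G":
            # pull the next non-G forward to avoid an accidental CpG
            for j in range(qi + 1, len(fill_list)):
                if fill_list[j] != b"G":
                    fill_list[qi], fill_list[j] = fill_list[j], fill_list[qi]
                    ch = fill_list[qi]
                    break
        out[i] = ch
        prev = ch
        qi += 1
    return b"".join(out).decode("ascii")


def gen_genome(
    n_chrom: int,
    chrom_len: int,
    island_spec: Mapping | None,
    seed: int,
    bin_width: int = DEFAULT_BIN_WIDTH,
    mre_sites_per_kb: float = 4.0,
    mre_motifs: Sequence[str] = tuple(sorted(DEFAULT_MRE_MOTIFS)),
) -> SyntheticTruth:
    """Genome with planted CpG islands and planted MRE recognition sites.

    ``island_spec`` carries count, length, gc, oe for the planted islands
    (None or count=0 plants none). Island parameters violating the island
    criteria are rejected up front, naming the violated criterion.
    """
    if chrom_len < 10 * bin_width:
        raise ValueError(f"chrom_len must be >= {10 * bin_width}")
    spec = dict(island_spec or {"count": 0, "length": 300, "gc": 0.6, "oe": 0.75})
    if spec["length"] <= 200:
        raise ValueError("island length must be greater than 200 bp (criterion i)")
    if spec["gc"] <= 0.5:
        raise ValueError("island GC must be greater than 0.5 (criterion ii)")
    if spec["oe"] <= 0.6:
        raise ValueError("island O/E must be greater than 0.6 (criterion iii)")

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        seq = list(_random_sequence(rng, chrom_len, BACKGROUND_GC, BACKGROUND_OE))
        islands: list[GenomicInterval] = []
        count = int(spec.get("count", 0))
        if count > 0:
            length = int(spec["length"])
            slot = chrom_len // count
            if slot < length + 1200:
                raise ValueError("too many islands for chromosome length")
            for k in range(count):
                lo = k * slot + 600
                hi = (k + 1) * slot - length - 600
                start = int(rng.integers(lo, max(lo + 1, hi)))
                for _ in range(25):
                    island_seq = _random_sequence(rng, length, spec["gc"], spec["oe"])
                    if island_criteria(island_seq):
                        break
                else:  # pragma: no cover - parameters guarantee success
                    raise RuntimeError("could not realize island parameters")
                seq[start : start + length] = list(island_seq)
                islands.append(GenomicInterval(chrom, start, start + length))

        # plant MRE recognition sites on a jittered grid (the motifs are
        # GC/CpG-rich, so enforced spacing keeps the background below the
        # island detector's thresholds), skipping island neighborhoods
        n_sites = int(round(mre_sites_per_kb * chrom_len / 1000.0))
        slots = np.arange(0, chrom_len - 60, 100)
        chosen = rng.choice(slots, size=min(n_sites, len(slots)), replace=False)
        jitter = rng.integers(0, 50, size=len(chosen))
        motif_idx = rng.integers(0, len(mre_motifs), size=len(chosen))
        for pos, off, mi in zip(chosen, jitter, motif_idx):
            pos = int(pos + off)
            if any(iv.start - 4 < pos < iv.end for iv in islands):
                continue
            seq[pos : pos + 4] = list(mre_motifs[mi])
        _break_spurious_islands(seq, islands)
        seq_str = "".join(seq)
        for iv in islands:
            assert island_criteria(seq_str[iv.start : iv.end]), iv
        truth.genome[chrom] = seq_str
        truth.true_islands.extend(islands)
    return truth


def _break_spurious_islands(seq: list[str], planted, max_passes: int = 4) -> None:
    """Demote CpGs inside any detector hit that misses every planted island.

    Random fluctuation plus planted motifs can, rarely, push a background
    window over the island thresholds; converting its CG dinucleotides to CT
    (in place) restores the contract that background regions contain no
    detectable islands. Deterministic; a no-op for clean backgrounds.
    """
    for _ in range(max_passes):
        seq_str = "".join(seq)
        spurious = [
            (s, e)
            for s, e in find_cpg_islands(seq_str)
            if not any(min(e, iv.end) - max(s, iv.start) > 0 for iv in planted)
        ]
        if not spurious:
            return
        for s, e in spurious:
            for i in range(max(0, s - 1), e):
                if seq[i] == "C" and i + 1 < len(seq) and seq[i + 1] == "G":
                    seq[i + 1] = "T"


# ---------------------------------------------------------------------------
# annotation truth (genes, TADs, conservation)


def gen_annotation_truth(
    truth: SyntheticTruth,
    n_genes: int,
    n_tads: int,
    seed: int,
    gene_length: tuple[int, int] = (2000, 8000),
    tad_coverage: float = 0.8,
    conserved_block_len: int = 500,
    conserved_blocks_per_chrom: int | None = None,
    flank: int = 1500,
) -> SyntheticTruth:
    """Fill genes, TADs and a conservation track into an existing truth.

    Genes are placed non-overlapping with random strand; TADs tile
    ``tad_coverage`` of each chromosome as disjoint blocks; conservation is
    low-score background (uniform 0-0.2) with high-score blocks (0.8-1.0)
    placed outside gene neighborhoods so that conserved intergenic bins
    exist by construction.
    """
    if n_tads < 0 or n_genes < 0:
        raise ValueError("n_genes and n_tads must be non-negative")
    rng = np.random.default_rng(seed)
    chroms = sorted(truth.genome)
    lengths = truth.genome_lengths

    # genes round-robin over chromosomes, each inside its own slot so that
    # bodies plus their 1.5 kb flanks never collide
    per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for gi in range(n_genes):
        per_chrom[chroms[gi % len(chroms)]] += 1
    gi = 0
    for chrom in chroms:
        k = per_chrom[chrom]
        if k == 0:
            continue
        slot = lengths[chrom] // k
        margin = flank + 100
        max_len = min(gene_length[1], slot - 2 * margin)
        if max_len < 500:
            raise ValueError(
                f"chromosome {chrom} too short for {k} genes with {flank} bp flanks"
            )
        for j in range(k):
            length = int(rng.integers(min(gene_length[0], max_len), max_len + 1))
            if length > lengths[chrom]:
                raise ValueError(f"gene longer than chromosome {chrom}")
            lo = j * slot + margin
            start = lo + int(rng.integers(0, slot - length - 2 * margin + 1))
            iv = GenomicInterval(
                chrom, start, start + length, "+" if rng.random() < 0.5 else "-"
            )
            gi += 1
            truth.genes.append(GeneModel(f"gene{gi:04d}", iv))

    tad_id = 0
    for chrom in chroms:
        per_chrom = n_tads // len(chroms) + (1 if chroms.index(chrom) < n_tads % len(chroms) else 0)
        if per_chrom == 0:
            continue
        covered = int(tad_coverage * lengths[chrom])
        widths = np.full(per_chrom, covered // per_chrom)
        gap_total = lengths[chrom] - int(widths.sum())
        gaps = np.sort(rng.integers(0, max(1, gap_total), size=per_chrom + 1))
        gaps = np.diff(np.concatenate([[0], gaps, [gap_total]]))[: per_chrom + 1]
        pos = 0
        for w, g in zip(widths, gaps):
            pos += int(g)
            truth.tads.append(GenomicInterval(chrom, pos, pos + int(w)))
            tad_id += 1
            pos += int(w)

    for chrom in chroms:
        track = rng.uniform(0.0, 0.2, size=lengths[chrom])
        n_blocks = (
            conserved_blocks_per_chrom
            if conserved_blocks_per_chrom is not None
            else max(1, lengths[chrom] // 25000)
        )
        gene_mask = np.zeros(lengths[chrom], dtype=bool)
        for g in truth.genes:
            if g.interval.chrom == chrom:
                gene_mask[max(0, g.interval.start - flank) : g.interval.end + flank] = True
        starts = np.flatnonzero(~gene_mask[: lengths[chrom] - conserved_block_len])
        bin_aligned = starts[starts % conserved_block_len == 0]
        if len(bin_aligned) > 0:
            chosen = rng.choice(bin_aligned, size=min(n_blocks, len(bin_aligned)), replace=False)
            for s in chosen:
                track[s : s + conserved_block_len] = rng.uniform(
                    0.8, 1.0, size=conserved_block_len
                )
        truth.conservation[chrom] = track
    return truth


# ---------------------------------------------------------------------------
# methylation levels and counts


def gen_methylome(
    n_bins: int,
    dmr_frac: float,
    delta: float,
    base_m: float,
    seed: int,
) -> tuple[np.ndarray, dict[int, str]]:
    """Per-bin two-group methylation with planted DMRs.

    Exactly ``round(dmr_frac * n_bins)`` bins differ between groups by
    ``delta`` (direction up/down assigned Bernoulli(0.5)); all other bins
    are identical across groups. "up" means group 2 higher.
    """
    if not (0.0 <= dmr_frac <= 1.0):
        raise ValueError("dmr_frac must lie in [0, 1]")
    if not (0.0 < delta <= 1.0):
        raise ValueError("delta must lie in (0, 1]")
    if not (0.0 < base_m < 1.0):
        raise ValueError("base_m must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    m = np.full((n_bins, 2), base_m, dtype=float)
    n_dmr = int(round(dmr_frac * n_bins))
    idx = rng.choice(n_bins, size=n_dmr, replace=False)
    up = rng.random(n_dmr) < 0.5
    m[idx, 1] = np.clip(base_m + np.where(up, delta, -delta), 0.0, 1.0)
    dmr_bins = {int(i): ("up" if u else "down") for i, u in zip(idx, up)}
    return m, dmr_bins


def gen_library_sizes(
    seed: int, low: float = 1.0, high: float = 1.3
) -> dict[str, tuple[float, float]]:
    """Per-sample, per-assay relative depths (default mild 1.0-1.3x imbalance)."""
    rng = np.random.default_rng(seed)
    return {
        "medip": tuple(rng.uniform(low, high, size=2)),
        "mre": tuple(rng.uniform(low, high, size=2)),
    }


def gen_counts(
    true_methylation: np.ndarray,
    content: pd.DataFrame,
    library_sizes: Mapping[str, tuple[float, float]],
    mean_depth: float,
    seed: int,
) -> pd.DataFrame:
    """Poisson read counts for both assays of both samples.

    MeDIP count for sample i in bin b ~ Poisson(s_i * c_b * m_bi * kappa);
    MRE count ~ Poisson(s_i * r_b * (1 - m_bi) * kappa). A single kappa is
    shared by both assays (so that the normalized-coverage ratio estimates
    methylation without bias) and is chosen so the mean per-bin count,
    averaged over assays and samples at unit library size, equals
    ``mean_depth``.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    m = np.asarray(true_methylation, dtype=float)
    if m.ndim != 2 or m.shape[1] != 2:
        raise ValueError("true_methylation must have shape (n_bins, 2)")
    c = content["cpg_count"].to_numpy(dtype=float)
    r = content["mre_site_count"].to_numpy(dtype=float)
    if len(c) != len(m):
        raise ValueError("content and methylation tables differ in length")
    rng = np.random.default_rng(seed)
    mu_medip = float((c[:, None] * m).mean())
    mu_mre = float((r[:, None] * (1.0 - m)).mean())
    kappa = 2.0 * mean_depth / (mu_medip + mu_mre) if (mu_medip + mu_mre) > 0 else 0.0
    s_medip = library_sizes["medip"]
    s_mre = library_sizes["mre"]
    out = content[["chrom", "start", "end", "cpg_count", "mre_site_count"]].copy()
    for i in (0, 1):
        out[f"medip_{i + 1}"] = rng.poisson(kappa * s_medip[i] * c * m[:, i])
    for i in (0, 1):
        out[f"mre_{i + 1}"] = rng.poisson(kappa * s_mre[i] * r * (1.0 - m[:, i]))
    return out


def gen_bin_content(
    n_bins: int,
    seed: int,
    mean_cpg: float = 5.0,
    mean_mre: float = 3.0,
    width: int = DEFAULT_BIN_WIDTH,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Sequence-free bin content sampler for large statistical simulations.

    Draws cpg_count ~ 1 + Poisson(mean_cpg - 1) and similarly for MRE sites,
    so every bin is informative; use gen_genome + bin_content_table when the
    sequence itself matters.
    """
    rng = np.random.default_rng(seed)
    starts = np.arange(n_bins) * width
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + width,
            "cpg_count": 1 + rng.poisson(max(mean_cpg - 1, 0), n_bins),
            "mre_site_count": 1 + rng.poisson(max(mean_mre - 1, 0), n_bins),
        }
    )


# ---------------------------------------------------------------------------
# gene sets and validation measurements


def gen_gene_sets(
    gene_ids: Sequence[str],
    n_terms: int,
    seed: int,
    size_range: tuple[int, int] = (5, 30),
    planted: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, tuple[str, set[str]]]:
    """Random GMT-style gene sets, plus optional planted terms with fixed
    membership (used to verify that enrichment recovers known signal)."""
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    sets: dict[str, tuple[str, set[str]]] = {}
    for t in range(n_terms):
        size = int(rng.integers(size_range[0], min(size_range[1], len(gene_ids)) + 1))
        members = set(rng.choice(gene_ids, size=size, replace=False).tolist())
        sets[f"TERM{t + 1:04d}"] = (f"random term {t + 1}", members)
    for name, members in (planted or {}).items():
        sets[name] = (name, set(members))
    return sets


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-sigma * sigma / 2.0, sigma, size)


def gen_validation_data(
    site_methylation: np.ndarray,
    expression_fold_changes: Mapping[str, float],
    n_animals: int,
    noise: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MSP-style and qPCR-style validation measurements for two groups.

    ``site_methylation`` is (n_sites, 2): true methylation per group. The
    MSP table carries methylated/unmethylated quantities whose ratio centers
    on the true methylation; the expression table carries a target quantity
    (group-2 mean multiplied by the gene's fold change) plus three
    housekeeping quantities. ``noise`` is a coefficient of variation.
    """
    if n_animals < 2:
        raise ValueError("n_animals must be >= 2 (t-tests need replication)")
    m = np.atleast_2d(np.asarray(site_methylation, dtype=float))
    if m.shape[1] != 2:
        raise ValueError("site_methylation must have shape (n_sites, 2)")
    rng = np.random.default_rng(seed)

    msp_rows = []
    for s in range(m.shape[0]):
        for g in (0, 1):
            noise_m = _lognormal_factor(rng, noise, n_animals)
            noise_u = _lognormal_factor(rng, noise, n_animals)
            for a in range(n_animals):
                msp_rows.append(
                    {
                        "site_id": f"site{s + 1}",
                        "group": g + 1,
                        "animal_id": f"g{g + 1}a{a + 1}",
                        "methylated_quantity": m[s, g] * noise_m[a],
                        "unmethylated_quantity": (1.0 - m[s, g]) * noise_u[a],
                    }
                )
    msp = pd.DataFrame(msp_rows)

    expr_rows = []
    for gene, fc in expression_fold_changes.items():
        for g in (0, 1):
            mean = 1.0 if g == 0 else float(fc)
            tq = mean * _lognormal_factor(rng, noise, n_animals)
            hk = _lognormal_factor(rng, noise, (n_animals, 3))
            for a in range(n_animals):
                expr_rows.append(
                    {
                        "gene_id": gene,
                        "group": g + 1,
                        "animal_id": f"g{g + 1}a{a + 1}",
                        "target_quantity": tq[a],
                        "hk1": hk[a, 0],
                        "hk2": hk[a, 1],
                        "hk3": hk[a, 2],
                    }
                )
    expression = pd.DataFrame(expr_rows)
    return msp, expression


# ---------------------------------------------------------------------------
# one-call dataset


def simulate_dataset(
    seed: int,
    n_chrom: int = 1,
    chrom_len: int = 100_000,
    n_islands: int = 5,
    island_length: int = 300,
    n_genes: int = 6,
    n_tads: int = 3,
    dmr_frac: float = 0.1,
    delta: float = 0.5,
    base_m: float = 0.5,
    mean_depth: float = 30.0,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> tuple[SyntheticTruth, pd.DataFrame]:
    """Full synthetic study: genome, annotation truth, counts. Returns
    (truth, bin count table ready for the MnM test)."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)
    truth = gen_genome(
        n_chrom,
        chrom_len,
        {"count": n_islands, "length": island_length, "gc": 0.6, "oe": 0.75},
        int(seeds[0]),
        bin_width=bin_width,
    )
    gen_annotation_truth(truth, n_genes, n_tads, int(seeds[1]))
    bins = make_bins(truth.genome_lengths, bin_width)
    content = bin_content_table(truth.genome, bins)
    m, dmr_bins = gen_methylome(len(bins), dmr_frac, delta, base_m, int(seeds[2]))
    truth.true_methylation = m
    truth.true_dmr_bins = dmr_bins
    truth.library_sizes = gen_library_sizes(int(seeds[3]))
    counts = gen_counts(m, content, truth.library_sizes, mean_depth, int(seeds[4]))
    return truth, counts
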