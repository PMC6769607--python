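"""End-to-end orchestration: generate/load -> bin -> test -> annotate ->
enrich -> link -> report.

A run is fully described by a :class:`RunConfig`. When ``counts_tsv`` is
given the pipeline starts from user-supplied files; otherwise it generates
a synthetic study (with ground truth written alongside the results). Reruns
of the same config produce byte-identical output bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    GenomeAnnotator,
    derive_shores,
    find_cpg_islands_genome,
    summarize_annotated,
)
from .binning import DEFAULT_BIN_WIDTH, DEFAULT_MRE_MOTIFS, bin_content_table, make_bins
from .enrichment import cluster_terms, enrich_terms
from .intervals import GenomicInterval
from . import io as mio
from .mnm import call_dmrs, size_factors, summarize_directions, test_bins
from .simulate import (
    gen_gene_sets,
    gen_validation_data,
    simulate_dataset,
)
from .tads import ConservationTrack, link_dmrs, read_mapping_blocks
from .validation import expression_group_tests, msp_group_tests


class ConfigError(ValueError):
    exit_code = 2


class ParseError(ValueError):
    exit_code = 3


class StageError(RuntimeError):
    exit_code = 4

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; the seed governs all randomness."""

    outdir: str = "medipmre_run"
    seed: int = 0
    # input files (all optional; absent -> synthetic generation)
    genome_fasta: str | None = None
    counts_tsv: str | None = None
    genes_tsv: str | None = None
    tads_bed: str | None = None
    conservation_bedgraph: str | None = None
    gene_sets_gmt: str | None = None
    mapping_tsv: str | None = None
    # synthetic-study conditions
    n_chrom: int = 1
    chrom_len: int = 100_000
    n_islands: int = 5
    island_length: int = 300
    n_genes: int = 6
    n_tads: int = 3
    dmr_frac: float = 0.1
    delta: float = 0.5
    base_m: float = 0.5
    mean_depth: float = 30.0
    n_animals: int = 6
    validation_noise: float = 0.2
    # analysis parameters
    bin_width: int = DEFAULT_BIN_WIDTH
    mre_motifs: tuple[str, ...] = tuple(sorted(DEFAULT_MRE_MOTIFS))
    alpha: float = 0.05
    promoter_flank: int = 1500
    downstream_flank: int = 1500
    shore_flank: int = 2000
    conservation_threshold: float = 0.5
    tad_window: int = 1_000_000
    enrich_min_count: int = 2
    enrich_min_fold: float = 1.5
    merge_adjacent: bool = False

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.bin_width < 1:
            raise ConfigError("bin_width must be >= 1")
        if not (0 <= self.conservation_threshold <= 1):
            raise ConfigError("conservation_threshold must lie in [0, 1]")
        if self.tad_window < 0 or self.shore_flank < 0:
            raise ConfigError("window/flank parameters must be non-negative")
        if not (0 <= self.dmr_frac <= 1):
            raise ConfigError("dmr_frac must lie in [0, 1]")


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the result bundle (also written
    under ``config.outdir``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = rng.integers(0, 2**31 - 1, size=4)
    bundle: dict = {}

    # -- inputs -------------------------------------------------------------
    truth = None
    try:
        if config.counts_tsv is None:
            truth, counts = simulate_dataset(
                seed=int(stage_seeds[0]),
                n_chrom=config.n_chrom,
                chrom_len=config.chrom_len,
                n_islands=config.n_islands,
                island_length=config.island_length,
                n_genes=config.n_genes,
                n_tads=config.n_tads,
                dmr_frac=config.dmr_frac,
                delta=config.delta,
                base_m=config.base_m,
                mean_depth=config.mean_depth,
                bin_width=config.bin_width,
            )
            genome = truth.genome
            genes = truth.genes
            tads = truth.tads
            conservation = ConservationTrack(truth.conservation)
            genome_lengths = truth.genome_lengths
            mio.write_fasta(genome, outdir / "genome.fa")
            mio.write_counts(counts, outdir / "counts.tsv")
            mio.write_genes(genes, outdir / "genes.tsv")
            mio.write_bed(tads, outdir / "tads.bed")
            mio.write_bedgraph(truth.conservation, outdir / "conservation.bedGraph")
            mio.write_truth_json(truth, outdir / "truth.json")
        else:
            try:
                counts = mio.read_counts(config.counts_tsv)
                genome = (
                    mio.read_fasta(config.genome_fasta) if config.genome_fasta else None
                )
                genes = mio.read_genes(config.genes_tsv) if config.genes_tsv else []
                tads = mio.read_bed(config.tads_bed) if config.tads_bed else []
                if genome is not None:
                    genome_lengths = {c: len(s) for c, s in genome.items()}
                else:
                    genome_lengths = (
                        counts.groupby("chrom")["end"].max().astype(int).to_dict()
                    )
                conservation = (
                    ConservationTrack(
                        mio.read_bedgraph(config.conservation_bedgraph, genome_lengths)
                    )
                    if config.conservation_bedgraph
                    else None
                )
            except (OSError, ValueError, KeyError) as exc:
                raise ParseError(str(exc)) from exc
    except (ConfigError, ParseError):
        raise
    except Exception as exc:
        raise StageError("input", str(exc)) from exc

    # -- test ---------------------------------------------------------------
    try:
        factors = size_factors(counts)
        results = test_bins(counts, factors)
        dmrs, direction_summary = call_dmrs(
            results, alpha=config.alpha, merge_adjacent=config.merge_adjacent
        )
    except Exception as exc:
        raise StageError("test", str(exc)) from exc

    dmr_intervals = [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in dmrs.itertuples(index=False)
    ]
    qv = dmrs["q_value"].to_numpy(dtype=float) if len(dmrs) else np.array([])
    scores = -np.log10(np.clip(qv, 1e-300, 1.0)) if len(dmrs) else []
    mio.write_bed(
        dmr_intervals,
        outdir / "dmrs.bed",
        names=list(dmrs["direction"]) if len(dmrs) else [],
        scores=[round(s, 3) for s in scores],
    )
    _fmt(results, outdir / "mnm_results.tsv")

    # -- annotate -----------------------------------------------------------
    try:
        if genome is not None:
            islands = find_cpg_islands_genome(genome)
        else:
            islands = []
        shores = derive_shores(islands, genome_lengths, flank=config.shore_flank)
        annotator = GenomeAnnotator(
            islands, shores, genes, genome_lengths,
            config.promoter_flank, config.downstream_flank,
        )
        labels = [annotator.annotate(iv) for iv in dmr_intervals]
        context_summary = summarize_annotated(labels)
    except Exception as exc:
        raise StageError("annotate", str(exc)) from exc

    ann = dmrs.copy()
    ann["island_context"] = [l[0] for l in labels]
    ann["gene_context"] = [l[1] for l in labels]
    _fmt(ann, outdir / "dmr_annotation.tsv")
    mio.write_bed(islands, outdir / "cpg_islands.bed")

    # -- link ---------------------------------------------------------------
    try:
        intergenic = [
            iv for iv, (_, gc) in zip(dmr_intervals, labels) if gc == "intergenic"
        ]
        mapping = None
        if config.mapping_tsv:
            mapping = read_mapping_blocks(mio.read_mapping_table(config.mapping_tsv))
        if conservation is not None:
            links = link_dmrs(
                intergenic, tads, genes, conservation,
                window=config.tad_window, mapping=mapping,
                threshold=config.conservation_threshold,
            )
        else:
            links = []
    except Exception as exc:
        raise StageError("link", str(exc)) from exc

    link_rows = [
        {
            "chrom": l.dmr.chrom, "start": l.dmr.start, "end": l.dmr.end,
            "mean_conservation": round(l.mean_score, 6),
            "tad": str(l.tad) if l.tad else ".",
            "contact_genes": ",".join(l.contact_genes) if l.contact_genes else ".",
        }
        for l in links
    ]
    _fmt(pd.DataFrame(link_rows, columns=[
        "chrom", "start", "end", "mean_conservation", "tad", "contact_genes"
    ]), outdir / "tad_links.tsv")

    # -- enrich -------------------------------------------------------------
    try:
        gene_ids = [g.gene_id for g in genes]
        dmg = sorted(
            {
                g.gene_id
                for g in genes
                for iv, (_, gc) in zip(dmr_intervals, labels)
                if gc != "intergenic" and _gene_touches(g, iv, config)
            }
        )
        contact_genes = sorted({gid for l in links for gid in l.contact_genes})
        query = sorted(set(dmg) | set(contact_genes))
        if config.gene_sets_gmt:
            gene_sets = mio.read_gmt(config.gene_sets_gmt)
        elif gene_ids:
            planted = {"PLANTED_CONTACT": contact_genes} if contact_genes else None
            gene_sets = gen_gene_sets(
                gene_ids, n_terms=8, seed=int(stage_seeds[1]),
                size_range=(2, max(3, len(gene_ids) // 2)), planted=planted,
            )
        else:
            gene_sets = {}
        enrichment = (
            enrich_terms(
                query, gene_sets, gene_ids,
                min_count=config.enrich_min_count, min_fold=config.enrich_min_fold,
            )
            if query and gene_sets
            else []
        )
        clusters = cluster_terms(enrichment, query) if enrichment else []
    except Exception as exc:
        raise StageError("enrich", str(exc)) from exc

    enr_df = pd.DataFrame(
        [
            {
                "term_id": r.term_id, "term_name": r.term_name,
                "dmg_count": r.dmg_count, "term_size": r.term_size,
                "fold_enrichment": round(r.fold_enrichment, 4),
                "p_value": r.p_value, "q_value": r.q_value,
                "genes": ",".join(r.genes),
            }
            for r in enrichment
        ],
        columns=["term_id", "term_name", "dmg_count", "term_size",
                 "fold_enrichment", "p_value", "q_value", "genes"],
    )
    _fmt(enr_df, outdir / "enrichment.tsv")

    # -- validation stats ---------------------------------------------------
    try:
        if truth is not None and truth.true_dmr_bins:
            bin_idx = sorted(truth.true_dmr_bins)[:4]
            site_m = truth.true_methylation[bin_idx]
            fold_changes = {gid: 1.5 for gid in (query or gene_ids)[:4]}
            msp, expression = gen_validation_data(
                site_m, fold_changes, config.n_animals,
                config.validation_noise, int(stage_seeds[2]),
            )
            val = pd.concat(
                [
                    msp_group_tests(msp).assign(kind="msp"),
                    expression_group_tests(expression)
                    .rename(columns={"gene_id": "site_id"})
                    .assign(kind="expression"),
                ],
                ignore_index=True,
            )
        else:
            val = pd.DataFrame(
                columns=["site_id", "t", "p_value", "mean_group1", "mean_group2", "kind"]
            )
        _fmt(val, outdir / "validation_stats.tsv")
    except Exception as exc:
        raise StageError("validation", str(exc)) from exc

    # -- summary + manifest ---------------------------------------------------
    summary = {
        "n_bins": int(len(counts)),
        "n_tested": int(results["tested"].sum()),
        "directions": direction_summary,
        "contexts": context_summary,
        "n_intergenic_dmrs": len(intergenic),
        "n_conserved_intergenic_dmrs": int(
            sum(1 for l in links if l.mean_score > config.conservation_threshold)
        ),
        "n_tad_linked": int(sum(1 for l in links if l.tad is not None)),
        "n_enriched_terms": len(enrichment),
        "n_clusters": len(clusters),
    }
    if truth is not None:
        truth_idx = set(truth.true_dmr_bins)
        called_idx = {
            int(counts.index[(counts["chrom"] == r.chrom) & (counts["start"] == r.start)][0])
            for r in dmrs.itertuples(index=False)
        } if len(dmrs) else set()
        tp = len(truth_idx & called_idx)
        summary["truth"] = {
            "n_true_dmr_bins": len(truth_idx),
            "sensitivity": round(tp / len(truth_idx), 4) if truth_idx else None,
            "fdr": round(1 - tp / len(called_idx), 4) if called_idx else None,
        }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    config_dict = asdict(config)
    config_dict["mre_motifs"] = list(config.mre_motifs)
    config_json = json.dumps(config_dict, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    bundle.update(
        results=results, dmrs=dmrs, annotation=ann, summary=summary,
        enrichment=enrichment, clusters=clusters, links=links, truth=truth,
    )
    return bundle


def _gene_touches(gene, dmr: GenomicInterval, config: RunConfig) -> bool:
    """Does the DMR overlap the gene body or its promoter/downstream flank?"""
    iv = gene.interval
    pad_start = iv.start - (config.promoter_flank if gene.strand == "+" else config.downstream_flank)
    pad_end = iv.end + (config.downstream_flank if gene.strand == "+" else config.promoter_flank)
    return dmr.chrom == iv.chrom and dmr.start < pad_end and pad_start < dmr.end
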