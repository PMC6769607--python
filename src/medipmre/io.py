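"""Readers and writers for the standard formats the pipeline touches.

All interval formats follow the BED convention (0-based half-open). FASTA
goes through Biopython; the tabular formats are plain TSV so that every
artifact the pipeline writes is inspectable text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModel, GenomicInterval

COUNT_COLUMNS = [
    "chrom", "start", "end", "cpg_count", "mre_site_count",
    "medip_1", "medip_2", "mre_1", "mre_2",
]


# -- FASTA -------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sorted(genome.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- BED ---------------------------------------------------------------------

def write_bed(intervals: Sequence[GenomicInterval], path, names=None, scores=None) -> None:
    """BED3, or BED6 when names/scores are given (strand from intervals)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None:
                name = names[i] if names is not None else "."
                score = scores[i] if scores is not None else 0
                fields += [str(name), f"{score:g}", iv.strand]
            fh.write("\t".join(fields) + "\n")


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


# -- bedGraph (per-base conservation) ---------------------------------------

def write_bedgraph(track: Mapping[str, np.ndarray], path, decimals: int = 4) -> None:
    """Run-length encode a per-base score track as bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            vals = np.round(np.asarray(track[chrom], dtype=float), decimals)
            if vals.size == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vals.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{vals[s]:.{decimals}f}\n")


def read_bedgraph(path, chrom_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    track = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            track[chrom][int(s):int(e)] = float(v)
    return track


# -- gene models -------------------------------------------------------------

def write_genes(genes: Sequence[GeneModel], path) -> None:
    rows = [
        (g.gene_id, g.interval.chrom, g.interval.start, g.interval.end, g.strand)
        for g in genes
    ]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False
    )


def read_genes(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(r.gene_id, GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand))
        for r in df.itertuples(index=False)
    ]


# -- counts ------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path) -> None:
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    return df


# -- GMT gene sets -----------------------------------------------------------

def write_gmt(gene_sets: Mapping[str, tuple[str, set]], path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(gene_sets):
            name, members = gene_sets[term_id]
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")


def read_gmt(path) -> dict[str, tuple[str, set]]:
    out: dict[str, tuple[str, set]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            out[f[0]] = (f[1], set(f[2:]))
    return out


# -- mapping blocks ----------------------------------------------------------

def read_mapping_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = ["src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"mapping table missing columns: {missing}")
    return df


# -- truth JSON --------------------------------------------------------------

def write_truth_json(truth, path) -> None:
    """Planted parameters of a synthetic dataset (not the bulky tracks)."""
    payload = {
        "chrom_lengths": truth.genome_lengths,
        "true_islands": [
            [iv.chrom, iv.start, iv.end] for iv in truth.true_islands
        ],
        "genes": [
            [g.gene_id, g.interval.chrom, g.interval.start, g.interval.end, g.strand]
            for g in truth.genes
        ],
        "tads": [[t.chrom, t.start, t.end] for t in truth.tads],
        "true_dmr_bins": {str(k): v for k, v in truth.true_dmr_bins.items()},
        "library_sizes": {k: list(v) for k, v in truth.library_sizes.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
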