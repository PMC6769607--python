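"""CpG island detection, shores and DMR context classification."""

import numpy as np
import pytest

from medipmre.annotation import (
    GenomeAnnotator,
    annotate_dmr,
    derive_shores,
    find_cpg_islands,
    island_criteria,
    summarize_annotated,
    summarize_contexts,
)
from medipmre.intervals import GeneModel, GenomicInterval


class TestFindCpgIslands:
    def test_cg_repeat_is_one_island(self):
        islands = find_cpg_islands("CG" * 250)
        assert len(islands) == 1
        s, e = islands[0]
        assert e - s >= 480  # nearly the whole 500-mer

    def test_poly_a_has_no_islands(self):
        assert find_cpg_islands("A" * 1000) == []

    def test_all_n_sequence_empty_result(self):
        assert find_cpg_islands("N" * 1000) == []

    def test_every_emitted_island_satisfies_criteria(self):
        rng = np.random.default_rng(0)
        # patchy sequence: random GC-rich and AT-rich stretches
        parts = []
        for _ in range(40):
            if rng.random() < 0.3:
                parts.append("".join(rng.choice(list("GCGCAT"), size=300)))
            else:
                parts.append("".join(rng.choice(list("ATATGC"), size=300)))
        seq = "".join(parts)
        for s, e in find_cpg_islands(seq):
            sub = seq[s:e]
            assert len(sub) >= 201
            gc = (sub.count("G") + sub.count("C")) / len(sub)
            ncpg = sum(1 for i in range(len(sub) - 1) if sub[i : i + 2] == "CG")
            oe = ncpg * len(sub) / (sub.count("C") * sub.count("G"))
            assert gc > 0.5 and oe > 0.6

    def test_nearby_seed_clusters_merge(self):
        island = "CG" * 150  # 300 bp, strong island
        seq = "AT" * 200 + island + "AT" * 30 + island + "AT" * 200
        islands = find_cpg_islands(seq)
        assert len(islands) == 1  # gap 60 < 100 merges


class TestDeriveShores:
    LENGTHS = {"chr1": 1_000_000}

    def test_flank_arithmetic(self):
        shores = derive_shores([GenomicInterval("chr1", 10_000, 10_300)], self.LENGTHS)
        assert [(s.start, s.end) for s in shores] == [(8_000, 10_000), (10_300, 12_300)]

    def test_island_at_chromosome_start_clipped(self):
        shores = derive_shores([GenomicInterval("chr1", 0, 250)], self.LENGTHS)
        assert [(s.start, s.end) for s in shores] == [(250, 2250)]

    def test_close_islands_merge_gap_shore(self):
        islands = [
            GenomicInterval("chr1", 10_000, 10_300),
            GenomicInterval("chr1", 11_800, 12_100),
        ]
        shores = derive_shores(islands, self.LENGTHS)
        assert GenomicInterval("chr1", 10_300, 11_800) in shores
        for s in shores:
            for i in islands:
                assert not s.overlaps(i)

    def test_matches_boolean_mask_oracle(self):
        rng = np.random.default_rng(4)
        lengths = {"chr1": 50_000}
        starts = np.sort(rng.choice(np.arange(0, 49_000, 700), size=12, replace=False))
        islands = [GenomicInterval("chr1", int(s), int(s) + 300) for s in starts]
        # drop overlapping islands (they must be disjoint on input)
        disjoint = []
        for iv in islands:
            if not disjoint or iv.start >= disjoint[-1].end:
                disjoint.append(iv)
        shores = derive_shores(disjoint, lengths)
        mask = np.zeros(50_000, dtype=bool)
        island_mask = np.zeros(50_000, dtype=bool)
        for iv in disjoint:
            island_mask[iv.start : iv.end] = True
            mask[max(0, iv.start - 2000) : iv.start] = True
            mask[iv.end : min(50_000, iv.end + 2000)] = True
        mask &= ~island_mask
        shore_mask = np.zeros(50_000, dtype=bool)
        for s in shores:
            assert not shore_mask[s.start : s.end].any()  # fragments disjoint
            shore_mask[s.start : s.end] = True
        assert np.array_equal(shore_mask, mask)


class TestAnnotateDmr:
    LENGTHS = {"chr1": 100_000}

    def _gene(self, start, end, strand="+", gid="g1"):
        return GeneModel(gid, GenomicInterval("chr1", start, end, strand))

    def test_intragenic(self):
        ctx = annotate_dmr(
            GenomicInterval("chr1", 20_000, 20_500), [], [], [self._gene(18_000, 25_000)],
            genome_lengths=self.LENGTHS,
        )
        assert ctx == ("open", "intragenic")

    def test_promoter_upstream_of_plus_strand_tss(self):
        dmr = GenomicInterval("chr1", 17_000, 17_500)  # TSS-1000..TSS-500
        ctx = annotate_dmr(dmr, [], [], [self._gene(18_000, 25_000)],
                           genome_lengths=self.LENGTHS)
        assert ctx[1] == "promoter"

    def test_promoter_on_minus_strand_is_right_of_gene(self):
        dmr = GenomicInterval("chr1", 25_500, 26_000)
        ctx = annotate_dmr(dmr, [], [], [self._gene(18_000, 25_000, "-")],
                           genome_lengths=self.LENGTHS)
        assert ctx[1] == "promoter"

    def test_promoter_beats_downstream_on_tie(self):
        gene_a = self._gene(10_000, 20_000, "+", "a")  # downstream 20000..21500
        gene_b = self._gene(22_000, 30_000, "+", "b")  # promoter 20500..22000
        dmr = GenomicInterval("chr1", 20_600, 21_100)  # in both flanks
        ctx = annotate_dmr(dmr, [], [], [gene_a, gene_b], genome_lengths=self.LENGTHS)
        assert ctx[1] == "promoter"

    def test_island_beats_shore(self):
        island = [GenomicInterval("chr1", 30_000, 30_400)]
        shores = derive_shores(island, self.LENGTHS)
        dmr = GenomicInterval("chr1", 30_300, 30_800)  # overlaps island + shore
        ctx = annotate_dmr(dmr, island, shores, [], genome_lengths=self.LENGTHS)
        assert ctx[0] == "island"

    def test_intergenic_far_from_everything(self):
        ctx = annotate_dmr(GenomicInterval("chr1", 90_000, 90_500), [], [],
                           [self._gene(10_000, 20_000)], genome_lengths=self.LENGTHS)
        assert ctx == ("open", "intergenic")

    def test_strand_flip_swaps_promoter_and_downstream(self):
        for strand, flipped in (("+", "-"), ("-", "+")):
            g = self._gene(40_000, 50_000, strand)
            g_flip = self._gene(40_000, 50_000, flipped)
            left = GenomicInterval("chr1", 39_000, 39_500)
            right = GenomicInterval("chr1", 50_500, 51_000)
            ctx_left = annotate_dmr(left, [], [], [g], genome_lengths=self.LENGTHS)[1]
            ctx_right = annotate_dmr(right, [], [], [g], genome_lengths=self.LENGTHS)[1]
            flip_left = annotate_dmr(left, [], [], [g_flip], genome_lengths=self.LENGTHS)[1]
            flip_right = annotate_dmr(right, [], [], [g_flip], genome_lengths=self.LENGTHS)[1]
            assert {ctx_left, ctx_right} == {"promoter", "downstream"}
            assert ctx_left == {"promoter": "downstream", "downstream": "promoter"}[flip_left]
            assert ctx_right == {"promoter": "downstream", "downstream": "promoter"}[flip_right]

    def test_exhaustive_against_label_enumeration(self):
        """Random DMRs against a brute-force reimplementation of the
        precedence rules."""
        rng = np.random.default_rng(11)
        genes = []
        pos = 5_000
        for i in range(6):
            length = int(rng.integers(2_000, 6_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(self._gene(pos, pos + length, strand, f"g{i}"))
            pos += length + int(rng.integers(2_000, 5_000))
        islands = [GenomicInterval("chr1", int(s), int(s) + 300)
                   for s in range(6_000, 60_000, 9_000)]
        shores = derive_shores(islands, self.LENGTHS)
        ann = GenomeAnnotator(islands, shores, genes, self.LENGTHS)

        def overlap(a_start, a_end, b_start, b_end):
            return a_start < b_end and b_start < a_end

        for _ in range(150):
            start = int(rng.integers(0, 99_500))
            dmr = GenomicInterval("chr1", start, start + 500)
            island_ctx, gene_ctx = ann.annotate(dmr)
            in_island = any(overlap(dmr.start, dmr.end, i.start, i.end) for i in islands)
            in_shore = any(overlap(dmr.start, dmr.end, s.start, s.end) for s in shores)
            assert island_ctx == ("island" if in_island else "shore" if in_shore else "open")
            in_prom = in_body = in_down = False
            for g in genes:
                iv = g.interval
                if g.strand == "+":
                    prom = (iv.start - 1500, iv.start)
                    down = (iv.end, iv.end + 1500)
                else:
                    prom = (iv.end, iv.end + 1500)
                    down = (iv.start - 1500, iv.start)
                in_prom |= overlap(dmr.start, dmr.end, *prom)
                in_body |= overlap(dmr.start, dmr.end, iv.start, iv.end)
                in_down |= overlap(dmr.start, dmr.end, *down)
            expected = (
                "promoter" if in_prom
                else "intragenic" if in_body
                else "downstream" if in_down
                else "intergenic"
            )
            assert gene_ctx == expected


class TestSummaries:
    def test_published_gene_axis_percentages(self):
        out = summarize_contexts(
            {"intergenic": 827, "intragenic": 524, "promoter": 48, "downstream": 45},
            total=1419,
        )
        assert out["percentages"] == {
            "intergenic": 58.3, "intragenic": 36.9, "promoter": 3.4, "downstream": 3.2,
        }

    def test_published_island_axis_percentages(self):
        out = summarize_contexts({"shore": 435, "island": 177}, total=1419)
        assert out["percentages"] == {"shore": 30.7, "island": 12.5}

    def test_empty_set_warns_and_reports_zero(self):
        with pytest.warns(UserWarning):
            out = summarize_contexts({"island": 0, "shore": 0})
        assert out["percentages"] == {"island": 0.0, "shore": 0.0}

    def test_exclusive_labels_sum_to_hundred(self):
        rng = np.random.default_rng(3)
        labels = [
            (str(rng.choice(["island", "shore", "open"])),
             str(rng.choice(["promoter", "intragenic", "downstream", "intergenic"])))
            for _ in range(997)
        ]
        out = summarize_annotated(labels)
        for axis in ("island_axis", "gene_axis"):
            assert sum(out[axis]["percentages"].values()) == pytest.approx(100.0, abs=0.2)


def test_island_criteria_boundary_length():
    assert not island_criteria("CG" * 100)   # 200 bp is not > 200
    assert island_criteria("CG" * 100 + "C")  # 201 bp
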