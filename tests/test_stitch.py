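"""The lncRNA 5'-boundary audit: stitching and junction-read evidence."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zipperplot.peakdb import CAGE, build_index
from zipperplot.stitch import (
    Junction,
    StitchCandidate,
    TranscriptModel,
    bin_support,
    intron_length_percentile,
    junction_support,
    overlap_fraction_stats,
    read_bed12_transcripts,
    read_gtf_transcripts,
    read_junctions_bed12,
    select_unsupported,
    stitch_candidates,
)

from conftest import make_peak


def tmodel(tid, exons, strand="+", biotype="lncRNA", chrom="chr1"):
    return TranscriptModel(tid, tid, biotype, chrom, strand, tuple(exons))


class TestIntronPercentile:
    def test_nearest_rank_example(self):
        genes = [tmodel("g", [(0, 10), (110, 120), (320, 330), (630, 640),
                              (1040, 1050), (1550, 1560)], biotype="protein_coding")]
        # introns: 100, 200, 300, 400, 500 -> 80th percentile (nearest rank) = 400
        assert intron_length_percentile(genes, 80) == 400

    def test_all_equal(self):
        genes = [tmodel("g", [(0, 10), (60, 70), (120, 130)], biotype="protein_coding")]
        for q in (10, 50, 80, 100):
            assert intron_length_percentile(genes, q) == 50

    def test_single_intron(self):
        genes = [tmodel("g", [(0, 10), (47, 60)], biotype="protein_coding")]
        assert intron_length_percentile(genes, 80) == 37

    def test_no_introns_is_error(self):
        with pytest.raises(ValueError, match="intron"):
            intron_length_percentile([tmodel("g", [(0, 10)], biotype="protein_coding")])


class TestSelectUnsupported:
    sizes = {"chr1": 100_000}

    def make_cage_index(self, peaks):
        index = build_index(peaks, self.sizes, assay=CAGE)
        index.add_sample("s1")
        return index

    def lnc_at(self, tss0, strand="+"):
        if strand == "+":
            return tmodel("lnc", [(tss0, tss0 + 400)])
        return tmodel("lnc", [(tss0 - 399, tss0 + 1)], strand="-")

    def test_nearby_same_strand_peak_excludes(self):
        # lnc TSS (1-based) 10001; peak 200 nt downstream
        index = self.make_cage_index(
            [make_peak(start=10_200, end=10_250, assay=CAGE, strand="+")])
        assert select_unsupported([self.lnc_at(10_000)], index, 500) == []

    def test_peak_just_outside_radius_includes(self):
        index = self.make_cage_index(
            [make_peak(start=10_501, end=10_550, assay=CAGE, strand="+")])
        lnc = self.lnc_at(10_000)
        assert select_unsupported([lnc], index, 500) == [lnc]

    def test_boundary_is_inclusive(self):
        index = self.make_cage_index(
            [make_peak(start=10_500, end=10_550, assay=CAGE, strand="+")])
        assert select_unsupported([self.lnc_at(10_000)], index, 500) == []

    def test_opposite_strand_peak_does_not_support(self):
        index = self.make_cage_index(
            [make_peak(start=10_000, end=10_050, assay=CAGE, strand="-")])
        lnc = self.lnc_at(10_000)
        assert select_unsupported([lnc], index, 500) == [lnc]

    def test_no_peaks_on_chromosome_includes(self):
        index = self.make_cage_index([])
        lnc = self.lnc_at(10_000)
        assert select_unsupported([lnc], index, 500) == [lnc]


class TestStitchCandidates:
    def gene_ending_at(self, end3, strand="+", chrom="chr1"):
        if strand == "+":
            exons = [(end3 - 2000, end3 - 1500), (end3 - 1000, end3)]
        else:
            exons = [(end3 - 1, end3 + 999), (end3 + 1500, end3 + 2000)]
        return tmodel("pcg", exons, strand=strand, biotype="protein_coding", chrom=chrom)

    def lnc_with_tss(self, tss, strand="+", chrom="chr1"):
        if strand == "+":
            return tmodel("lnc", [(tss - 1, tss + 399)], chrom=chrom)
        return tmodel("lnc", [(tss - 400, tss)], strand="-", chrom=chrom)

    def test_gap_arithmetic(self):
        cands = stitch_candidates([self.lnc_with_tss(12_000)],
                                  [self.gene_ending_at(10_000)])
        assert len(cands) == 1 and cands[0].gap == 2000

    def test_minus_strand_gap(self):
        cands = stitch_candidates([self.lnc_with_tss(10_000, "-")],
                                  [self.gene_ending_at(12_000, "-")])
        assert len(cands) == 1 and cands[0].gap == 2000

    def test_opposite_strands_never_pair(self):
        assert stitch_candidates([self.lnc_with_tss(12_000)],
                                 [self.gene_ending_at(10_000, "-")]) == []

    def test_gap_beyond_maximum_excluded(self):
        assert stitch_candidates([self.lnc_with_tss(16_001)],
                                 [self.gene_ending_at(10_000)], max_gap=5827) == []
        assert len(stitch_candidates([self.lnc_with_tss(15_827)],
                                     [self.gene_ending_at(10_000)], max_gap=5827)) == 1

    def test_downstream_gene_excluded(self):
        # gene 3' end past the lncRNA TSS: negative gap, never stitched
        assert stitch_candidates([self.lnc_with_tss(9_000)],
                                 [self.gene_ending_at(10_000)]) == []

    def test_every_qualifying_gene_pairs(self):
        genes = [self.gene_ending_at(10_000), self.gene_ending_at(11_000)]
        genes[1] = TranscriptModel("pcg2", "pcg2", "protein_coding", "chr1", "+",
                                   genes[1].exons)
        cands = stitch_candidates([self.lnc_with_tss(12_000)], genes)
        assert sorted(c.gene.transcript_id for c in cands) == ["pcg", "pcg2"]
        assert all(0 <= c.gap <= 5827 for c in cands)


def plus_pair(gap=2000):
    gene = tmodel("pcg", [(1000, 1400), (2000, 3000)], biotype="protein_coding")
    tss0 = 3000 + gap - 1
    lnc = tmodel("lnc", [(tss0, tss0 + 500)])
    return StitchCandidate(lnc, gene, gap)


def junction_for(cand, gene_ov=8, lnc_ov=8, reads=5):
    """A junction whose flanks sit inside the pair's exons by the given nt."""
    gene_end0 = cand.gene.exons[-1][1]
    tss0 = cand.lncrna.exons[0][0]
    return Junction("chr1", donor_end=gene_end0 - 4, acceptor_start=tss0 + 3,
                    strand="+", flank5_len=gene_ov, flank3_len=lnc_ov, read_count=reads)


class TestJunctionSupport:
    def test_full_overlap_retained(self):
        cand = plus_pair()
        out = junction_support(cand, [junction_for(cand)], [cand.lncrna])
        assert len(out.supporting_junctions) == 1
        assert out.total_junction_reads == 5

    def test_one_nt_lncrna_overlap_discarded(self):
        cand = plus_pair()
        out = junction_support(cand, [junction_for(cand, lnc_ov=1)], [cand.lncrna])
        assert out.supporting_junctions == []

    def test_one_nt_gene_overlap_discarded(self):
        cand = plus_pair()
        out = junction_support(cand, [junction_for(cand, gene_ov=1)], [cand.lncrna])
        assert out.supporting_junctions == []

    def test_two_nt_overlap_is_enough(self):
        cand = plus_pair()
        out = junction_support(cand, [junction_for(cand, gene_ov=2, lnc_ov=2)],
                               [cand.lncrna])
        assert len(out.supporting_junctions) == 1

    def test_ambiguous_flank_discarded(self):
        cand = plus_pair()
        # decoy lncRNA exon covering the gene-side flank region
        decoy = tmodel("decoy", [(2500, 3000)])
        out = junction_support(cand, [junction_for(cand)], [cand.lncrna, decoy])
        assert out.supporting_junctions == []

    def test_wrong_strand_or_chrom_ignored(self):
        cand = plus_pair()
        j = junction_for(cand)
        flipped = Junction(j.chrom, j.donor_end, j.acceptor_start, "-",
                           j.flank5_len, j.flank3_len, j.read_count)
        elsewhere = Junction("chr9", j.donor_end, j.acceptor_start, "+",
                             j.flank5_len, j.flank3_len, j.read_count)
        out = junction_support(cand, [flipped, elsewhere], [cand.lncrna])
        assert out.supporting_junctions == []

    def test_reads_summed_over_junctions(self):
        cand = plus_pair()
        j1 = junction_for(cand, reads=3)
        j2 = Junction("chr1", j1.donor_end - 2, j1.acceptor_start + 2, "+", 8, 8, 4)
        out = junction_support(cand, [j1, j2], [cand.lncrna])
        assert out.total_junction_reads == 7

    @given(st.integers(1, 8), st.integers(1, 8), st.integers(1, 10))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_min_overlap(self, go, lo, m1):
        cand = plus_pair()
        junctions = [junction_for(cand, gene_ov=go, lnc_ov=lo)]
        kept_strict = junction_support(cand, junctions, [cand.lncrna],
                                       min_overlap=m1 + 1).supporting_junctions
        kept_loose = junction_support(cand, junctions, [cand.lncrna],
                                      min_overlap=m1).supporting_junctions
        assert set(kept_strict) <= set(kept_loose)


class TestBinSupport:
    def supported(self, tid, reads, mono=True):
        exons = [(10_000, 10_500)] if mono else [(10_000, 10_200), (10_400, 10_500)]
        lnc = tmodel(tid, exons)
        gene = tmodel(f"g_{tid}", [(1000, 3000)], biotype="protein_coding")
        return StitchCandidate(lnc, gene, 100, [], reads)

    def test_one_per_bin(self):
        cands = [self.supported(f"l{i}", r) for i, r in enumerate([3, 50, 200, 0])]
        table = bin_support(cands)
        assert table.loc["mono-exonic"].tolist() == [1, 1, 1, 3]
        assert table.loc["multi-exonic"].tolist() == [0, 0, 0, 0]

    @pytest.mark.parametrize("reads,bin_name", [
        (1, "1<=JR<=10"), (10, "1<=JR<=10"),
        (11, "11<=JR<=100"), (100, "11<=JR<=100"),
        (101, "JR>100"), (250, "JR>100"),
    ])
    def test_printed_bin_boundaries(self, reads, bin_name):
        table = bin_support([self.supported("l", reads)])
        assert table.loc["mono-exonic", bin_name] == 1
        assert table.loc["mono-exonic", "total"] == 1

    def test_zero_support_gives_empty_rows(self):
        table = bin_support([self.supported("l", 0)])
        assert table.values.sum() == 0

    def test_bins_partition(self):
        for reads in range(1, 260, 13):
            table = bin_support([self.supported("l", reads)])
            assert table.loc["mono-exonic"].tolist()[:3].count(1) == 1

    def test_lncrna_counted_once_with_max_support(self):
        lnc = tmodel("l1", [(10_000, 10_500)])
        g1 = tmodel("g1", [(1000, 3000)], biotype="protein_coding")
        g2 = tmodel("g2", [(4000, 6000)], biotype="protein_coding")
        cands = [StitchCandidate(lnc, g1, 10, [], 4),
                 StitchCandidate(lnc, g2, 10, [], 120)]
        table = bin_support(cands)
        assert table.loc["mono-exonic"].tolist() == [0, 0, 1, 1]

    def test_multi_exonic_classified_separately(self):
        table = bin_support([self.supported("l", 5, mono=False)])
        assert table.loc["multi-exonic", "1<=JR<=10"] == 1


class TestOverlapFractions:
    def test_partial_fraction(self):
        cand = plus_pair()
        fully = [junction_for(cand) for _ in range(3)]
        # flank5 16 nt but only 12 inside the gene exon (extends past its end)
        gene_end0 = cand.gene.exons[-1][1]
        partial = Junction("chr1", gene_end0 + 3, cand.lncrna.exons[0][0] + 3,
                           strand="+", flank5_len=16, flank3_len=8)
        cand.supporting_junctions = fully + [partial]
        frac_gene, frac_lnc = overlap_fraction_stats([cand])
        assert frac_gene == 0.75
        assert frac_lnc == 1.0

    def test_all_contained(self):
        cand = plus_pair()
        cand.supporting_junctions = [junction_for(cand)]
        assert overlap_fraction_stats([cand]) == (1.0, 1.0)

    def test_no_junctions_is_error(self):
        with pytest.raises(ValueError):
            overlap_fraction_stats([plus_pair()])


class TestParsers:
    def test_bed12_round_trip(self, tmp_path):
        from zipperplot.synthetic import _bed12_line

        t = tmodel("tx1", [(100, 200), (500, 700)], strand="-")
        path = tmp_path / "m.bed"
        path.write_text(_bed12_line(t) + "\n")
        back = read_bed12_transcripts(path, "lncRNA")
        assert back == [t]

    def test_gtf_exons_grouped(self, tmp_path):
        gtf = tmp_path / "m.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; '
            'gene_biotype "protein_coding";\n'
            'chr1\tsrc\texon\t501\t700\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; '
            'gene_biotype "protein_coding";\n'
        )
        models = read_gtf_transcripts(gtf)
        assert models[0].exons == ((100, 200), (500, 700))
        assert models[0].gene_id == "g1" and models[0].biotype == "protein_coding"

    def test_junction_bed12_dialect(self, tmp_path):
        bed = tmp_path / "j.bed"
        bed.write_text("chr1\t1000\t2000\tjunc\t7\t+\t1000\t2000\t0\t2\t40,60\t0,940\n")
        j = read_junctions_bed12(bed)[0]
        assert j.left_flank == (1000, 1040)
        assert j.right_flank == (1940, 2000)
        assert j.read_count == 7 and j.flank5_len == 40 and j.flank3_len == 60
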