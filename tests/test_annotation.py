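"""Annotation parsing and the exon universe."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reda import GenomicInterval, build_exon_universe, parse_annotation
from reda.annotation import AnnotationError, ExonRecord

from _oracles import mask_merge_oracle


def _gtf_exon(chrom, start1, end1, gene="G1", name=None, tx="t1"):
    name = name or gene
    return (
        f"{chrom}\tt\texon\t{start1}\t{end1}\t.\t+\t.\t"
        f'gene_id "{gene}"; transcript_id "{tx}"; gene_name "{name}";'
    )


class TestParseAnnotation:
    def test_coordinates_convert_to_zero_based_half_open(self):
        recs = parse_annotation(_gtf_exon("chr1", 101, 200) + "\n")
        assert recs == [
            ExonRecord(GenomicInterval("chr1", 100, 200), "G1", "G1", "", "+")
        ]
        assert recs[0].interval.length == 100

    def test_shared_exon_of_two_transcripts_yields_two_records(self):
        text = (
            _gtf_exon("chr1", 101, 200, tx="t1")
            + "\n"
            + _gtf_exon("chr1", 101, 200, tx="t2")
            + "\n"
        )
        recs = parse_annotation(text)
        assert len(recs) == 2
        assert recs[0].interval == recs[1].interval
        assert recs[0].gene_id == recs[1].gene_id == "G1"

    def test_exon_feature_count_is_preserved(self):
        lines = [
            _gtf_exon("chr1", 1, 100, gene="G1", tx="t1"),
            _gtf_exon("chr1", 201, 300, gene="G1", tx="t1"),
            _gtf_exon("chr1", 401, 500, gene="G1", tx="t2"),
            _gtf_exon("chr2", 1, 100, gene="G2", tx="t3"),
            _gtf_exon("chr2", 201, 250, gene="G2", tx="t3"),
            # a gene line must not add an exon record
            'chr2\tt\tgene\t1\t250\t.\t+\t.\tgene_id "G2";',
        ]
        assert len(parse_annotation("\n".join(lines) + "\n")) == 5

    def test_noncoding_transcript_without_exons_becomes_one_exon(self):
        text = (
            'chr1\tt\ttranscript\t501\t900\t.\t-\t.\tgene_id "NC"; '
            'transcript_id "NC.1"; gene_name "LINC1"; gene_biotype "lincRNA";\n'
        )
        recs = parse_annotation(text)
        assert len(recs) == 1
        assert recs[0].interval == GenomicInterval("chr1", 500, 900)
        assert recs[0].feature_biotype == "lincRNA"

    def test_transcript_with_exon_children_is_not_duplicated(self):
        text = (
            'chr1\tt\ttranscript\t101\t300\t.\t+\t.\tgene_id "G1"; transcript_id "t1";\n'
            + _gtf_exon("chr1", 101, 300)
            + "\n"
        )
        assert len(parse_annotation(text)) == 1

    def test_malformed_line_names_line_number(self):
        text = _gtf_exon("chr1", 1, 100) + "\nchr1\tonly\tthree\n"
        with pytest.raises(AnnotationError, match="line 2"):
            parse_annotation(text)

    def test_missing_gene_id_is_an_error(self):
        text = 'chr1\tt\texon\t1\t100\t.\t+\t.\ttranscript_id "t1";\n'
        with pytest.raises(AnnotationError, match="gene_id"):
            parse_annotation(text)


class TestBuildExonUniverse:
    def test_overlapping_exons_merge(self):
        recs = [
            ExonRecord(GenomicInterval("chr1", 100, 200), "G1", "A"),
            ExonRecord(GenomicInterval("chr1", 150, 300), "G2", "B"),
        ]
        uni = build_exon_universe(recs)
        assert uni.exonic_intervals() == [GenomicInterval("chr1", 100, 300)]
        assert uni.exonic["chr1"].gene_names[0] == frozenset({"A", "B"})

    def test_intron_is_the_complement_within_the_gene(self):
        recs = [
            ExonRecord(GenomicInterval("chr1", 0, 100), "G1", "A"),
            ExonRecord(GenomicInterval("chr1", 200, 300), "G1", "A"),
        ]
        uni = build_exon_universe(recs)
        assert uni.intron_intervals() == [GenomicInterval("chr1", 100, 200)]

    def test_exon_of_other_gene_splits_the_intron(self):
        # gene B's exon sits inside gene A's intron: exon precedence
        recs = [
            ExonRecord(GenomicInterval("chr1", 0, 100), "G1", "A"),
            ExonRecord(GenomicInterval("chr1", 900, 1000), "G1", "A"),
            ExonRecord(GenomicInterval("chr1", 400, 500), "G2", "B"),
        ]
        uni = build_exon_universe(recs)
        assert GenomicInterval("chr1", 100, 400) in uni.intron_intervals()
        assert GenomicInterval("chr1", 500, 900) in uni.intron_intervals()
        assert not uni.in_intron("chr1", 450, 460)

    def test_random_exons_match_per_base_mask_oracle(self, rng):
        for _ in range(30):
            recs = []
            for g in range(3):
                for _ in range(10):
                    s = int(rng.integers(0, 9_000))
                    recs.append(
                        ExonRecord(
                            GenomicInterval("chr1", s, s + int(rng.integers(50, 500))),
                            f"G{g}",
                            f"N{g}",
                        )
                    )
            uni = build_exon_universe(recs)
            expected = mask_merge_oracle([r.interval for r in recs], 10_000)
            assert uni.exonic_intervals() == expected

    def test_merging_is_idempotent(self, rng):
        recs = [
            ExonRecord(
                GenomicInterval("chr1", s := int(rng.integers(0, 5_000)), s + 100),
                "G1",
                "A",
            )
            for _ in range(50)
        ]
        uni = build_exon_universe(recs)
        again = build_exon_universe(
            [ExonRecord(iv, "G1", "A") for iv in uni.exonic_intervals()]
        )
        assert again.exonic_intervals() == uni.exonic_intervals()

    def test_no_intron_intersects_an_exon(self, rng):
        recs = []
        for g in range(4):
            for _ in range(8):
                s = int(rng.integers(0, 20_000))
                recs.append(
                    ExonRecord(
                        GenomicInterval("chr1", s, s + int(rng.integers(100, 800))),
                        f"G{g}",
                        f"N{g}",
                    )
                )
        uni = build_exon_universe(recs)
        for intron in uni.intron_intervals():
            assert not uni.overlaps_exon(intron.chrom, intron.start, intron.end)

    def test_bed_output_is_sorted_bed6(self, toy_universe):
        buf = io.StringIO()
        toy_universe.to_bed(buf)
        lines = [l.split("\t") for l in buf.getvalue().strip().split("\n")]
        assert [l[0:3] for l in lines] == [
            ["chr1", "1000", "1300"],
            ["chr1", "3000", "3500"],
            ["chr1", "30000", "30400"],
        ]
        assert all(len(l) == 6 for l in lines)

    def test_empty_input_yields_empty_universe(self):
        uni = build_exon_universe([])
        assert uni.exonic_intervals() == []
        assert uni.intron_intervals() == []


class TestUniverseQueries:
    def test_overlap_query(self, toy_universe):
        assert toy_universe.overlaps_exon("chr1", 1299, 1301)
        assert not toy_universe.overlaps_exon("chr1", 1300, 3000)
        assert not toy_universe.overlaps_exon("chr2", 0, 10**6)

    def test_min_gap_query(self, toy_universe):
        assert toy_universe.min_exon_gap("chr1", 1400, 1500) == 100
        assert toy_universe.min_exon_gap("chr1", 3600, 3700) == 100
        assert toy_universe.min_exon_gap("chr1", 1000, 1100) == 0
        assert toy_universe.min_exon_gap("chr2", 0, 10) == float("inf")

    def test_intron_containment(self, toy_universe):
        assert toy_universe.in_intron("chr1", 1400, 2000)
        assert not toy_universe.in_intron("chr1", 1200, 2000)  # straddles exon
        assert not toy_universe.in_intron("chr1", 5000, 6000)  # intergenic
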