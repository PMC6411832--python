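"""The discovery core: bin calling, merging, classification, extension."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reda import (
    DiscoveryConfig,
    GenomicInterval,
    ReClass,
    RNAElement,
    bin_coverage,
    call_expressed_bins,
    classify_re,
    discover,
    extend_exonic,
    merge_across_samples,
    merge_bins,
    read_coverage,
    rpm_to_depth,
)

from _oracles import gap_merge_oracle


def _bins(*pairs, chrom="chr1"):
    return [GenomicInterval(chrom, s, e) for s, e in pairs]


class TestCallExpressedBins:
    def _binned(self, depth, span=(5000, 5010)):
        text = f"chr1\t{span[0]}\t{span[1]}\t{depth}\n"
        return bin_coverage(read_coverage(text, 20_000_000), 10)

    def test_strictly_above_threshold_is_retained(self, toy_universe):
        thr = rpm_to_depth(2.5, 20_000_000)  # absolute depth 50
        bins = call_expressed_bins(self._binned(51), thr, toy_universe)
        assert bins == _bins((5000, 5010))

    def test_exactly_at_threshold_is_excluded(self, toy_universe):
        thr = rpm_to_depth(2.5, 20_000_000)
        assert call_expressed_bins(self._binned(50), thr, toy_universe) == []
        # non-strict mode keeps the boundary bin
        assert (
            call_expressed_bins(self._binned(50), thr, toy_universe, strict=False)
            == _bins((5000, 5010))
        )

    def test_bin_overlapping_exon_by_one_base_is_excluded(self, toy_universe):
        # exon ends at 1300: bin [1290, 1300) overlaps it, [1300, 1310) not
        thr = rpm_to_depth(2.5, 20_000_000)
        binned = bin_coverage(read_coverage("chr1\t1290\t1320\t99\n", 20_000_000), 10)
        bins = call_expressed_bins(binned, thr, toy_universe)
        assert bins == _bins((1300, 1310), (1310, 1320))


class TestMergeBins:
    def test_gap_of_exactly_merge_gap_fuses(self):
        assert merge_bins(_bins((0, 10), (160, 170)), 150) == _bins((0, 170))

    def test_gap_one_past_merge_gap_stays_split(self):
        assert merge_bins(_bins((0, 10), (161, 171)), 150) == _bins(
            (0, 10), (161, 171)
        )

    def test_random_bins_match_fixpoint_oracle(self, rng):
        for _ in range(10):
            idx = rng.choice(5_000, size=200, replace=False)
            bins = _bins(*[(int(i) * 10, int(i) * 10 + 10) for i in idx])
            assert merge_bins(bins, 150) == gap_merge_oracle(bins, 150)

    def test_idempotent_and_order_independent(self, rng):
        idx = rng.choice(2_000, size=100, replace=False)
        bins = _bins(*[(int(i) * 10, int(i) * 10 + 10) for i in idx])
        merged = merge_bins(bins, 150)
        assert merge_bins(merged, 150) == merged
        perm = [bins[i] for i in rng.permutation(len(bins))]
        assert merge_bins(perm, 150) == merged

    def test_output_gaps_exceed_merge_gap(self, rng):
        idx = rng.choice(3_000, size=150, replace=False)
        merged = merge_bins(
            _bins(*[(int(i) * 10, int(i) * 10 + 10) for i in idx]), 150
        )
        for a, b in zip(merged, merged[1:]):
            assert b.start - a.end > 150

    def test_empty_input(self):
        assert merge_bins([], 150) == []


class TestClassifyRe:
    def test_intronic_takes_precedence_over_near_exon(self, toy_universe):
        # inside gene A's intron, 200 bp from the flanking exons
        iv = GenomicInterval("chr1", 1500, 2800)
        assert classify_re(iv, toy_universe) is ReClass.INTRONIC

    def test_near_exon_boundary_inclusive_at_10kb(self, toy_universe):
        # ends exactly 10,000 bp before gene B's exon start at 30,000
        iv = GenomicInterval("chr1", 19_500, 20_000)
        assert classify_re(iv, toy_universe) is ReClass.NEAR_EXON

    def test_orphan_beyond_10kb(self, toy_universe):
        iv = GenomicInterval("chr1", 60_000, 60_500)
        # nearest exon ends at 30,400 -> gap 29,600
        assert classify_re(iv, toy_universe) is ReClass.ORPHAN

    def test_gap_of_10001_is_orphan(self):
        from reda import build_exon_universe, parse_annotation

        uni = build_exon_universe(
            parse_annotation(
                'chr1\tt\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "t";\n'
            )
        )
        assert classify_re(GenomicInterval("chr1", 10_100, 10_200), uni) is ReClass.NEAR_EXON
        assert classify_re(GenomicInterval("chr1", 10_101, 10_200), uni) is ReClass.ORPHAN

    def test_exon_overlap_violates_contract(self, toy_universe):
        with pytest.raises(ValueError, match="overlaps"):
            classify_re(GenomicInterval("chr1", 1290, 1400), toy_universe)

    def test_straddling_intron_boundary_is_not_intronic(self, toy_universe):
        # extends past gene A's span into intergenic space
        iv = GenomicInterval("chr1", 2900, 3000)  # intron ends at 3000
        assert classify_re(iv, toy_universe) is ReClass.INTRONIC
        iv2 = GenomicInterval("chr1", 3500, 4000)  # right of gene A entirely
        assert classify_re(iv2, toy_universe) is ReClass.NEAR_EXON


def _el(chrom, start, end, cls, sources):
    iv = GenomicInterval(chrom, start, end)
    return RNAElement(
        id=RNAElement.make_id(iv),
        interval=iv,
        re_class=cls,
        source_samples=frozenset(sources),
    )


class TestMergeAcrossSamples:
    def test_cross_sample_gap_of_100_fuses_with_union_of_sources(self, toy_universe):
        per_sample = {
            "A": [_el("chr1", 5000, 5200, ReClass.NEAR_EXON, {"A"})],
            "B": [_el("chr1", 5300, 5400, ReClass.NEAR_EXON, {"B"})],
        }
        out = merge_across_samples(per_sample, toy_universe)
        novel = [el for el in out if el.re_class is not ReClass.EXONIC]
        assert len(novel) == 1
        assert novel[0].interval == GenomicInterval("chr1", 5000, 5400)
        assert novel[0].source_samples == frozenset({"A", "B"})

    def test_identical_element_in_three_samples(self, toy_universe):
        per_sample = {
            s: [_el("chr1", 5000, 5200, ReClass.NEAR_EXON, {s})] for s in "ABC"
        }
        out = merge_across_samples(per_sample, toy_universe)
        novel = [el for el in out if el.re_class is not ReClass.EXONIC]
        assert len(novel) == 1
        assert novel[0].source_samples == frozenset("ABC")

    def test_exonic_elements_are_appended_unchanged(self, toy_universe):
        out = merge_across_samples({}, toy_universe)
        assert [el.interval for el in out] == toy_universe.exonic_intervals()
        assert all(el.re_class is ReClass.EXONIC for el in out)

    def test_pooled_merge_matches_oracle(self, toy_universe, rng):
        per_sample = {}
        pooled = []
        for s in range(4):
            els = []
            for _ in range(15):
                start = 31_000 + int(rng.integers(0, 40_000))
                iv = GenomicInterval("chr1", start, start + int(rng.integers(10, 400)))
                els.append(
                    RNAElement(
                        id=RNAElement.make_id(iv),
                        interval=iv,
                        re_class=ReClass.NEAR_EXON,
                        source_samples=frozenset({f"S{s}"}),
                    )
                )
                pooled.append(iv)
            per_sample[f"S{s}"] = els
        out = merge_across_samples(per_sample, toy_universe)
        novel = [el.interval for el in out if el.re_class is not ReClass.EXONIC]
        assert novel == gap_merge_oracle(pooled, 150)
        for el in out:
            if el.re_class is not ReClass.EXONIC:
                assert el.re_class is classify_re(el.interval, toy_universe)


class TestExtendExonic:
    def _pair(self, gap, toy_universe):
        ex = RNAElement(
            id="x",
            interval=GenomicInterval("chr1", 3000, 3500),
            re_class=ReClass.EXONIC,
            gene_names=frozenset({"A"}),
        )
        nov = _el("chr1", 3500 + gap, 3800 + gap, ReClass.NEAR_EXON, {"S1"})
        return ex, nov

    def test_boundary_gap_and_coverage(self, toy_universe):
        ex, nov = self._pair(50, toy_universe)
        out = extend_exonic(ex, nov, 100.0, 60.0)  # rel diff 0.4
        assert out is not None
        assert out.interval == GenomicInterval("chr1", 3000, 3850)
        assert out.re_class is ReClass.EXONIC
        assert out.gene_names == frozenset({"A"})
        assert out.source_samples == frozenset({"S1"})

    def test_relative_difference_of_half_fails(self, toy_universe):
        ex, nov = self._pair(40, toy_universe)
        assert extend_exonic(ex, nov, 100.0, 50.0) is None

    def test_gap_51_fails(self, toy_universe):
        ex, nov = self._pair(51, toy_universe)
        assert extend_exonic(ex, nov, 80.0, 80.0) is None

    def test_both_depths_zero_fails(self, toy_universe):
        ex, nov = self._pair(10, toy_universe)
        assert extend_exonic(ex, nov, 0.0, 0.0) is None


class TestDiscover:
    def test_planted_orphan_recovered(self, toy_universe):
        # orphan at 60 kb, depth 60, library 1M: mu=5 -> threshold 5
        text = "chr1\t60000\t60990\t60\n"
        track = read_coverage(text, 1_000_000, "S1")
        res = discover([track], toy_universe, DiscoveryConfig(mu=5.0))
        novel = [el for el in res if el.re_class is not ReClass.EXONIC]
        assert len(novel) == 1
        assert novel[0].re_class is ReClass.ORPHAN
        assert abs(novel[0].interval.start - 60_000) <= 10
        assert abs(novel[0].interval.end - 60_990) <= 10

    def test_no_expressed_bins_returns_exons_only(self, toy_universe):
        track = read_coverage("chr1\t5000\t5100\t1\n", 20_000_000, "S1")
        res = discover([track], toy_universe)
        assert [el.interval for el in res] == toy_universe.exonic_intervals()

    def test_two_active_samples_merge_into_one_novel_element(self, toy_universe):
        """Four samples, two sub-threshold; the two active samples carry
        signal separated by 150 bp and fuse into one element."""
        lib = {"S1": 2_000_000, "S2": 1_000_000, "S3": 4_000_000, "S4": 800_000}
        # thresholds at mu 2.5: S1 5.0, S2 2.5, S3 10.0, S4 2.0
        tracks = [
            read_coverage("chr1\t5000\t5200\t40\n", lib["S1"], "S1"),
            read_coverage("chr1\t5000\t5200\t2\n", lib["S2"], "S2"),
            read_coverage("chr1\t5350\t5500\t55\n", lib["S3"], "S3"),
            read_coverage("chr1\t5300\t5600\t1\n", lib["S4"], "S4"),
        ]
        res = discover(tracks, toy_universe, DiscoveryConfig(mu=2.5))
        novel = [el for el in res if el.re_class is not ReClass.EXONIC]
        assert len(novel) == 1
        assert novel[0].source_samples == frozenset({"S1", "S3"})
        assert novel[0].interval == GenomicInterval("chr1", 5000, 5500)

    def test_raising_mu_shrinks_the_expressed_bin_set(self, toy_universe, rng):
        steps = []
        pos = 31_000
        for _ in range(60):
            pos += int(rng.integers(0, 400))
            ln = int(rng.integers(20, 300))
            steps.append(f"chr1\t{pos}\t{pos + ln}\t{int(rng.integers(1, 120))}")
            pos += ln
        track = read_coverage("\n".join(steps) + "\n", 1_000_000, "S1")
        binned = bin_coverage(track, 10)
        prev = None
        for mu in [1.0, 2.5, 5.0, 10.0, 50.0]:
            thr = rpm_to_depth(mu, track.library_size)
            bins = set(call_expressed_bins(binned, thr, toy_universe))
            if prev is not None:
                assert bins <= prev
            prev = bins

    def test_novel_elements_never_overlap_exons(self, toy_universe, rng):
        steps = []
        pos = 500
        for _ in range(80):
            pos += int(rng.integers(0, 300))
            ln = int(rng.integers(20, 200))
            steps.append(f"chr1\t{pos}\t{pos + ln}\t{int(rng.integers(1, 90))}")
            pos += ln
        track = read_coverage("\n".join(steps) + "\n", 1_000_000, "S1")
        cfg = DiscoveryConfig(mu=2.5, extension_gap=1)  # suppress extension
        res = discover([track], toy_universe, cfg)
        exons = toy_universe.exonic_intervals()
        for el in res:
            if el.re_class is ReClass.EXONIC:
                continue
            assert not any(el.interval.overlaps(ex) for ex in exons)

    def test_discover_requires_a_sample(self, toy_universe):
        with pytest.raises(ValueError):
            discover([], toy_universe)

    def test_extension_absorbs_matching_neighbour(self, toy_universe):
        # exon [3000, 3500) at depth 60; novel signal 30 bp downstream at
        # depth 40 (rel diff 1/3) -> exon extends over it
        text = "chr1\t3000\t3500\t60\nchr1\t3530\t3800\t40\n"
        track = read_coverage(text, 1_000_000, "S1")
        res = discover([track], toy_universe, DiscoveryConfig(mu=2.5))
        spans = {el.interval: el for el in res}
        extended = [
            el
            for el in res
            if el.re_class is ReClass.EXONIC and el.interval.start == 3000
        ]
        assert len(extended) == 1
        assert extended[0].interval.end == 3800
        assert extended[0].gene_names == frozenset({"A"})
        assert all(
            el.re_class is ReClass.EXONIC or el.interval.start >= 3800
            for el in res
            if el.interval.chrom == "chr1" and el.interval.start >= 3000
        )
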