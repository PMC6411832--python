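"""The RNA-element discovery core.

Per sample: convert mu to an absolute depth, average coverage over 10 bp
bins, keep non-exonic bins surpassing the threshold, fuse bins separated by
at most 150 bp into novel elements.  Across samples: pool and re-fuse novel
elements with the same gap rule, re-classify, and append the exonic
elements.  Finally, exonic elements may absorb an adjacent near-exon
element when the two are within 50 bp and their read coverage differs by
less than 50%.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .annotation import ExonUniverse
from .coverage import (
    BinnedCoverage,
    CoverageTrack,
    DepthThreshold,
    bin_coverage,
    rpm_to_depth,
)
from .intervals import GenomicInterval, merge_with_gap

__all__ = [
    "ReClass",
    "RNAElement",
    "DiscoveryConfig",
    "call_expressed_bins",
    "merge_bins",
    "classify_re",
    "merge_across_samples",
    "extend_exonic",
    "discover",
]


class ReClass(str, enum.Enum):
    """Position of an element relative to the annotated exons."""

    EXONIC = "Exonic"
    INTRONIC = "Intronic"
    NEAR_EXON = "NearExon"
    ORPHAN = "Orphan"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class RNAElement:
    """A contiguous transcribed genomic region with its annotation class."""

    id: str
    interval: GenomicInterval
    re_class: ReClass
    gene_names: frozenset[str] = frozenset()
    source_samples: frozenset[str] = frozenset()

    @staticmethod
    def make_id(interval: GenomicInterval) -> str:
        return f"{interval.chrom}_{interval.start}_{interval.end}"


@dataclass(frozen=True)
class DiscoveryConfig:
    """Tunable parameters of the discovery workflow.

    mu : reads per million; bins whose mean depth surpasses
        ``mu * library_size / 1e6`` are expressed (default 2.5 RPM).
    bin_size : width of the fixed coverage grid, bp (default 10).
    merge_gap : maximum empty space between fused expressed bins, and
        between pooled cross-sample elements, bp (default 150).
    near_exon_distance : non-intronic elements at most this far from an
        exon are NearExon, farther are Orphan, bp (default 10000).
    extension_gap : maximum exon-to-element gap for exon extension, bp
        (default 50).
    extension_max_coverage_diff : exon extension requires the relative
        coverage difference to be strictly below this fraction (default 0.5).
    strict_threshold : if True (default), a bin must strictly exceed the
        absolute depth; if False, equality passes.
    """

    mu: float = 2.5
    bin_size: int = 10
    merge_gap: int = 150
    near_exon_distance: int = 10_000
    extension_gap: int = 50
    extension_max_coverage_diff: float = 0.5
    strict_threshold: bool = True

    def __post_init__(self) -> None:
        for name in ("mu", "bin_size", "merge_gap", "near_exon_distance", "extension_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.extension_max_coverage_diff <= 1):
            raise ValueError("extension_max_coverage_diff must be in (0, 1]")


def call_expressed_bins(
    binned: BinnedCoverage,
    threshold: DepthThreshold,
    universe: ExonUniverse,
    strict: bool = True,
) -> list[GenomicInterval]:
    """Bins whose mean depth surpasses the threshold, outside all exons.

    A bin is excluded if it overlaps any exonic RE by one or more bases.
    With ``strict`` (the default) the comparison is ``mean > depth``;
    equality is excluded.
    """
    b = binned.bin_size
    out: list[GenomicInterval] = []
    for chrom in sorted(binned.means):
        arr = binned.means[chrom]
        if strict:
            hits = np.nonzero(arr > threshold.absolute_depth)[0]
        else:
            hits = np.nonzero(arr >= threshold.absolute_depth)[0]
        if hits.size == 0:
            continue
        exonic = np.zeros(arr.size, dtype=bool)
        c = universe.exonic.get(chrom)
        if c is not None:
            for s, e in zip(c.starts, c.ends):
                b0 = int(s) // b
                b1 = min(arr.size, -(-int(e) // b))
                if b1 > b0:
                    exonic[b0:b1] = True
        for i in hits:
            if not exonic[i]:
                out.append(GenomicInterval(chrom, int(i) * b, (int(i) + 1) * b))
    return out


def merge_bins(
    bins: "list[GenomicInterval] | set[GenomicInterval]", merge_gap: int = 150
) -> list[GenomicInterval]:
    """Fuse expressed bins separated by at most ``merge_gap`` bases.

    Book-ended or overlapping bins always fuse; the output is sorted with
    pairwise gaps strictly greater than ``merge_gap``.
    """
    if not bins:
        return []
    return merge_with_gap(bins, max_gap=merge_gap)


def classify_re(
    interval: GenomicInterval,
    universe: ExonUniverse,
    near_exon_distance: int = 10_000,
) -> ReClass:
    """Assign a novel element its class relative to the annotation.

    Intronic if wholly inside a gene's intron (checked first: an intron is
    always within reach of its flanking exons); otherwise NearExon when the
    minimum gap to any exon is at most ``near_exon_distance``; otherwise
    Orphan.  The interval must not overlap an exon.
    """
    if universe.overlaps_exon(interval.chrom, interval.start, interval.end):
        raise ValueError(f"{interval} overlaps an exonic RE; not a novel element")
    if universe.in_intron(interval.chrom, interval.start, interval.end):
        return ReClass.INTRONIC
    if universe.min_exon_gap(interval.chrom, interval.start, interval.end) <= near_exon_distance:
        return ReClass.NEAR_EXON
    return ReClass.ORPHAN


def _exonic_elements(universe: ExonUniverse) -> list[RNAElement]:
    out = []
    for chrom in sorted(universe.exonic):
        c = universe.exonic[chrom]
        for s, e, names in zip(c.starts, c.ends, c.gene_names):
            iv = GenomicInterval(chrom, int(s), int(e))
            out.append(
                RNAElement(
                    id=RNAElement.make_id(iv),
                    interval=iv,
                    re_class=ReClass.EXONIC,
                    gene_names=names,
                )
            )
    return out


def merge_across_samples(
    per_sample_novel: dict[str, list[RNAElement]],
    universe: ExonUniverse,
    config: DiscoveryConfig = DiscoveryConfig(),
) -> list[RNAElement]:
    """Pool per-sample novel elements into the collective element set.

    Novel elements from all samples separated by at most ``merge_gap`` are
    fused, re-classified, and given the union of contributing sample ids;
    the exonic elements are appended unchanged (they take no part in the
    merge).
    """
    pooled: list[RNAElement] = [
        el for els in per_sample_novel.values() for el in els
    ]
    merged = merge_bins([el.interval for el in pooled], config.merge_gap)
    out: list[RNAElement] = []
    for iv in merged:
        sources: set[str] = set()
        for el in pooled:
            if el.interval.overlaps(iv):
                sources.update(el.source_samples)
        out.append(
            RNAElement(
                id=RNAElement.make_id(iv),
                interval=iv,
                re_class=classify_re(iv, universe, config.near_exon_distance),
                source_samples=frozenset(sources),
            )
        )
    out.extend(_exonic_elements(universe))
    out.sort(key=lambda el: (el.interval.chrom, el.interval.start, el.interval.end))
    return out


def extend_exonic(
    exonic: RNAElement,
    novel: RNAElement,
    exonic_mean_depth: float,
    novel_mean_depth: float,
    config: DiscoveryConfig = DiscoveryConfig(),
) -> RNAElement | None:
    """Extend an exonic element into an adjacent near-exon element.

    The fusion happens when the two are within ``extension_gap`` bases and
    the relative coverage difference ``|d_e - d_n| / max(d_e, d_n)`` is
    strictly below ``extension_max_coverage_diff``; the result spans both,
    keeps class Exonic and the exon's gene names, and unions the sample
    provenance.  Returns None when the rule does not fire (including when
    both depths are zero, where the relative difference is undefined).
    """
    if novel.re_class is not ReClass.NEAR_EXON:
        raise ValueError(f"extension requires a NearExon element, got {novel.re_class}")
    if exonic.interval.chrom != novel.interval.chrom:
        return None
    gap = max(
        0,
        max(exonic.interval.start, novel.interval.start)
        - min(exonic.interval.end, novel.interval.end),
    )
    if gap > config.extension_gap:
        return None
    hi = max(exonic_mean_depth, novel_mean_depth)
    if hi <= 0:
        return None
    if abs(exonic_mean_depth - novel_mean_depth) / hi >= config.extension_max_coverage_diff:
        return None
    iv = GenomicInterval(
        exonic.interval.chrom,
        min(exonic.interval.start, novel.interval.start),
        max(exonic.interval.end, novel.interval.end),
    )
    return RNAElement(
        id=RNAElement.make_id(iv),
        interval=iv,
        re_class=ReClass.EXONIC,
        gene_names=exonic.gene_names,
        source_samples=exonic.source_samples | novel.source_samples,
    )


def _novel_for_sample(
    track: CoverageTrack,
    universe: ExonUniverse,
    config: DiscoveryConfig,
    chrom_sizes: dict[str, int] | None = None,
) -> list[RNAElement]:
    threshold = rpm_to_depth(config.mu, track.library_size)
    binned = bin_coverage(track, config.bin_size, chrom_sizes)
    bins = call_expressed_bins(binned, threshold, universe, config.strict_threshold)
    out = []
    for iv in merge_bins(bins, config.merge_gap):
        out.append(
            RNAElement(
                id=RNAElement.make_id(iv),
                interval=iv,
                re_class=classify_re(iv, universe, config.near_exon_distance),
                source_samples=frozenset({track.sample_id}),
            )
        )
    return out


def _mean_rpm_depth(
    samples: list[CoverageTrack], iv: GenomicInterval
) -> float:
    """Across-sample mean of per-sample RPM-normalised mean depth."""
    vals = [
        t.mean_depth(iv.chrom, iv.start, iv.end) * 1e6 / t.library_size
        for t in samples
    ]
    return float(np.mean(vals)) if vals else 0.0


def discover(
    samples: list[CoverageTrack],
    universe: ExonUniverse,
    config: DiscoveryConfig = DiscoveryConfig(),
    chrom_sizes: dict[str, int] | None = None,
) -> list[RNAElement]:
    """Run the full discovery workflow over a set of samples.

    Per-sample expressed-bin calling and merging, cross-sample pooling, and
    a final exon-extension pass over adjacent exonic/near-exon pairs.
    Element ids are coordinate-derived (``chrom_start_end``) and therefore
    stable across runs.
    """
    if not samples:
        raise ValueError("discover requires at least one sample")
    per_sample = {
        t.sample_id or f"sample{i}": _novel_for_sample(t, universe, config, chrom_sizes)
        for i, t in enumerate(samples)
    }
    collective = merge_across_samples(per_sample, universe, config)

    # exon-extension pass: each near-exon element may be absorbed by its
    # nearest qualifying exonic neighbour (no iterative chaining)
    exonic = [el for el in collective if el.re_class is ReClass.EXONIC]
    others = [el for el in collective if el.re_class is not ReClass.EXONIC]
    absorbed: set[str] = set()
    for novel in [el for el in others if el.re_class is ReClass.NEAR_EXON]:
        candidates = []
        for j, ex in enumerate(exonic):
            if ex.interval.chrom != novel.interval.chrom:
                continue
            gap = max(
                0,
                max(ex.interval.start, novel.interval.start)
                - min(ex.interval.end, novel.interval.end),
            )
            if gap <= config.extension_gap:
                candidates.append((gap, j))
        if not candidates:
            continue
        _, j = min(candidates)
        ex = exonic[j]
        d_e = _mean_rpm_depth(samples, ex.interval)
        d_n = _mean_rpm_depth(samples, novel.interval)
        extended = extend_exonic(ex, novel, d_e, d_n, config)
        if extended is not None:
            exonic[j] = extended
            absorbed.add(novel.id)
    out = exonic + [el for el in others if el.id not in absorbed]
    out.sort(key=lambda el: (el.interval.chrom, el.interval.start, el.interval.end))
    return out
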