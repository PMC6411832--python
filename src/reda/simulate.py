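"""Synthetic fixtures: toy genomes, annotations, repeats and coverage.

The generator builds a small genome with multi-exon genes, plants
expressed regions of each annotation class (exonic, intronic, near-exon,
orphan) into otherwise sub-threshold noisy coverage, and emits standard
GTF / BED / bedGraph text plus the planted ground truth, so that the whole
discovery workflow can be exercised and scored without any external data.

Noise is an over-dispersed (gamma-Poisson) count process per coverage bin,
clipped below the reference depth threshold so that background alone never
produces an expressed bin; planted regions are written at a configurable
multiple of that threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotation import ExonUniverse, build_exon_universe, parse_annotation
from .coverage import CoverageTrack, read_coverage
from .discovery import ReClass, RNAElement, classify_re
from .intervals import GenomicInterval

__all__ = [
    "FixtureConfig",
    "PlantedRE",
    "PlantedTruth",
    "Fixture",
    "FixtureError",
    "RecoveryMetrics",
    "generate_fixture",
    "score_recovery",
]


class FixtureError(ValueError):
    """Raised when the requested fixture cannot be laid out."""


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of a synthetic dataset.

    ``planted_res`` lists (class, length bp, depth multiplier) triples; the
    multiplier scales the reference absolute depth threshold
    (``mu_reference * library_size / 1e6``), so a multiplier of 10 plants
    signal at ten times the discovery threshold.  Background noise is
    clipped strictly below that threshold.
    """

    seed: int = 0
    n_chromosomes: int = 1
    chromosome_length: int = 200_000
    n_genes: int = 3
    exons_per_gene: int = 4
    planted_res: tuple[tuple[str, int, float], ...] = (
        ("Intronic", 400, 10.0),
        ("NearExon", 500, 10.0),
        ("Orphan", 600, 10.0),
    )
    noise_mean: float = 0.8  # mean background depth per base
    noise_dispersion: float = 0.5  # gamma shape; smaller = burstier
    library_size: int = 1_000_000
    read_length: int = 75
    n_samples: int = 2
    repeat_density: float = 2.0  # repeats per 10 kb
    mu_reference: float = 2.5  # RPM threshold the noise must stay under
    bin_size: int = 10
    fragmentation: bool = False  # punch <=150 bp holes into planted REs
    include_noncoding_transcript: bool = True

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise FixtureError("need at least one chromosome of positive length")
        if self.n_samples < 1:
            raise FixtureError("need at least one sample")
        for cls, length, mult in self.planted_res:
            if cls not in {"Exonic", "Intronic", "NearExon", "Orphan"}:
                raise FixtureError(f"unknown planted class {cls!r}")
            if length < 1 or mult <= 0:
                raise FixtureError(f"bad planted spec ({cls}, {length}, {mult})")

    @property
    def absolute_threshold(self) -> float:
        return self.mu_reference * self.library_size / 1e6


@dataclass(frozen=True)
class PlantedRE:
    """Ground truth for one planted element."""

    interval: GenomicInterval
    re_class: ReClass
    depth: float  # per-base depth written into every sample


@dataclass
class PlantedTruth:
    records: list[PlantedRE] = field(default_factory=list)

    def novel(self) -> list[PlantedRE]:
        return [r for r in self.records if r.re_class is not ReClass.EXONIC]


@dataclass
class Fixture:
    """An in-memory synthetic dataset plus its ground truth."""

    config: FixtureConfig
    gtf_text: str
    repeat_bed_text: str
    bedgraph_texts: dict[str, str]
    tracks: dict[str, CoverageTrack]
    truth: PlantedTruth
    universe: ExonUniverse
    chrom_sizes: dict[str, int]

    def sample_ids(self) -> list[str]:
        return sorted(self.tracks)

    def write(self, outdir) -> dict[str, str]:
        """Write annotation.gtf, repeats.bed, <sample>.bedGraph and a
        manifest echoing the configuration; returns name -> path."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}

        def _put(name: str, text: str) -> None:
            p = os.path.join(outdir, name)
            with open(p, "w") as fh:
                fh.write(text)
            paths[name] = p

        _put("annotation.gtf", self.gtf_text)
        _put("repeats.bed", self.repeat_bed_text)
        for sid, text in self.bedgraph_texts.items():
            _put(f"{sid}.bedGraph", text)
        manifest = ["# synthetic fixture manifest"]
        for k, v in vars(self.config).items():
            manifest.append(f"{k} = {v!r}")
        manifest.append(
            "library_sizes = "
            + ", ".join(f"{s}:{t.library_size}" for s, t in sorted(self.tracks.items()))
        )
        _put("manifest.txt", "\n".join(manifest) + "\n")
        return paths


# --------------------------------------------------------------------------
# genome layout

_REPEAT_CATALOG = [
    ("AluY", "SINE", "Alu"),
    ("L1HS", "LINE", "L1"),
    ("HERVE-int", "LTR", "ERV1"),
    ("MLT2A1", "LTR", "ERVL"),
    ("HSAT1", "Satellite", "Satellite"),
    ("(AATGG)n", "Simple_repeat", "Simple_repeat"),
    ("MER1A", "DNA", "hAT-Charlie"),
]


def _layout_genes(cfg: FixtureConfig, rng: np.random.Generator, chrom: str):
    """Place genes with jittered exon/intron sizes; returns (gtf lines,
    exon intervals, intron windows, intergenic windows, gene region end)."""
    lines: list[str] = []
    exons: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    intergenic: list[tuple[int, int]] = []
    pos = 2_000
    for g in range(cfg.n_genes):
        gene_id = f"{chrom}_G{g + 1}"
        gene_name = f"GENE{g + 1}_{chrom}"
        tx_id = f"{gene_id}.t1"
        gene_start = pos
        exon_spans = []
        for x in range(cfg.exons_per_gene):
            elen = int(rng.integers(200, 400))
            exon_spans.append((pos, pos + elen))
            pos += elen
            if x < cfg.exons_per_gene - 1:
                ilen = int(rng.integers(1_500, 2_500))
                introns.append((exon_spans[-1][1], exon_spans[-1][1] + ilen))
                pos += ilen
        gene_end = pos
        attrs = (
            f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
            f'gene_name "{gene_name}"; gene_biotype "protein_coding";'
        )
        lines.append(
            f"{chrom}\tsynth\tgene\t{gene_start + 1}\t{gene_end}\t.\t+\t.\t{attrs}"
        )
        lines.append(
            f"{chrom}\tsynth\ttranscript\t{gene_start + 1}\t{gene_end}\t.\t+\t.\t{attrs}"
        )
        for s, e in exon_spans:
            lines.append(f"{chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t+\t.\t{attrs}")
        exons.extend(exon_spans)
        spacing = int(rng.integers(2_500, 3_500))
        intergenic.append((gene_end, gene_end + spacing))
        pos = gene_end + spacing
    if cfg.include_noncoding_transcript:
        # a non-coding entry without exon lines: parsed as a single exon
        nc_len = int(rng.integers(300, 600))
        gene_id = f"{chrom}_NC1"
        attrs = (
            f'gene_id "{gene_id}"; transcript_id "{gene_id}.t1"; '
            f'gene_name "LINC_{chrom}"; gene_biotype "lincRNA";'
        )
        lines.append(
            f"{chrom}\tsynth\ttranscript\t{pos + 1}\t{pos + nc_len}\t.\t-\t.\t{attrs}"
        )
        exons.append((pos, pos + nc_len))
        pos += nc_len + 1_000
    return lines, exons, introns, intergenic, pos


def generate_fixture(config: FixtureConfig) -> Fixture:
    """Build a deterministic synthetic dataset from the configuration.

    Planted near-exon elements land in intergenic windows between genes
    (always within 10 kb of an exon); orphans land beyond 10.5 kb of the
    last exon; intronic elements land wholly inside generated introns with
    a safety margin.  Every planted class is re-derived from the generated
    annotation and checked, so the truth labels are self-consistent by
    construction.

    Raises :class:`FixtureError` when the chromosome cannot host the
    request (e.g. orphans on a too-short chromosome).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chrom_sizes = {c: cfg.chromosome_length for c in chroms}

    gtf_lines: list[str] = []
    exons_by_chrom: dict[str, list[tuple[int, int]]] = {}
    intron_windows: dict[str, list[tuple[int, int]]] = {}
    intergenic_windows: dict[str, list[tuple[int, int]]] = {}
    gene_region_end: dict[str, int] = {}
    for chrom in chroms:
        lines, exons, introns, inter, end = _layout_genes(cfg, rng, chrom)
        if end > cfg.chromosome_length:
            raise FixtureError(
                f"{chrom}: gene layout needs {end} bp, chromosome is "
                f"{cfg.chromosome_length} bp"
            )
        gtf_lines.extend(lines)
        exons_by_chrom[chrom] = exons
        intron_windows[chrom] = introns
        intergenic_windows[chrom] = inter
        gene_region_end[chrom] = end

    gtf_text = "\n".join(gtf_lines) + "\n"
    universe = build_exon_universe(parse_annotation(gtf_text))

    # ---- plant ground-truth elements, round-robin over chromosomes -----
    truth = PlantedTruth()
    orphan_cursor = {
        c: gene_region_end[c] + 10_500 for c in chroms
    }  # beyond near-exon reach
    intron_cursor = {c: 0 for c in chroms}
    inter_cursor = {c: 0 for c in chroms}
    margin = 200
    threshold = cfg.absolute_threshold
    for i, (cls, length, mult) in enumerate(cfg.planted_res):
        chrom = chroms[i % len(chroms)]
        if cls == "Exonic":
            exons = exons_by_chrom[chrom]
            s, e = exons[i % len(exons)]
            iv = GenomicInterval(chrom, s, min(e, s + length))
        elif cls == "Intronic":
            placed = None
            wins = intron_windows[chrom]
            while intron_cursor[chrom] < len(wins):
                s, e = wins[intron_cursor[chrom]]
                intron_cursor[chrom] += 1
                if e - s >= length + 2 * margin:
                    placed = (s + margin, s + margin + length)
                    break
            if placed is None:
                raise FixtureError(
                    f"{chrom}: no intron can host a {length} bp intronic element"
                )
            iv = GenomicInterval(chrom, *placed)
        elif cls == "NearExon":
            placed = None
            wins = intergenic_windows[chrom]
            while inter_cursor[chrom] < len(wins):
                s, e = wins[inter_cursor[chrom]]
                inter_cursor[chrom] += 1
                if e - s >= length + 2 * margin:
                    placed = (s + margin, s + margin + length)
                    break
            if placed is None:
                raise FixtureError(
                    f"{chrom}: no intergenic window can host a {length} bp "
                    "near-exon element"
                )
            iv = GenomicInterval(chrom, *placed)
        else:  # Orphan
            s = orphan_cursor[chrom]
            e = s + length
            if e > cfg.chromosome_length - 500:
                raise FixtureError(
                    f"{chrom}: chromosome too short for an orphan at {s}"
                )
            orphan_cursor[chrom] = e + 1_000
            iv = GenomicInterval(chrom, s, e)
        depth = max(1.0, round(mult * threshold))
        truth.records.append(PlantedRE(interval=iv, re_class=ReClass(cls), depth=depth))

    # self-consistency: planted labels must agree with the classifier
    for rec in truth.records:
        if rec.re_class is ReClass.EXONIC:
            if not universe.overlaps_exon(
                rec.interval.chrom, rec.interval.start, rec.interval.end
            ):
                raise FixtureError(f"planted exonic element {rec.interval} misses exons")
            continue
        derived = classify_re(rec.interval, universe)
        if derived is not rec.re_class:
            raise FixtureError(
                f"planted {rec.re_class} at {rec.interval} classifies as {derived}"
            )

    # ---- noisy coverage tracks ------------------------------------------
    max_noise = max(0, math.ceil(threshold) - 1)
    bedgraph_texts: dict[str, str] = {}
    tracks: dict[str, CoverageTrack] = {}
    for s_idx in range(cfg.n_samples):
        sid = f"S{s_idx + 1}"
        parts: list[str] = []
        for chrom in chroms:
            L = cfg.chromosome_length
            n_bins = -(-L // cfg.bin_size)
            shape = cfg.noise_dispersion
            lam = rng.gamma(shape, cfg.noise_mean / shape, size=n_bins)
            noise = rng.poisson(lam).astype(float)
            noise = np.minimum(noise, max_noise)
            base = np.repeat(noise, cfg.bin_size)[:L]
            for rec in truth.records:
                if rec.interval.chrom != chrom:
                    continue
                base[rec.interval.start : rec.interval.end] = rec.depth
                if cfg.fragmentation:
                    n_holes = int(rng.integers(1, 3))
                    for _ in range(n_holes):
                        hole = int(rng.integers(30, 151))
                        if rec.interval.length <= hole + 2:
                            continue
                        off = int(
                            rng.integers(1, rec.interval.length - hole)
                        )
                        hs = rec.interval.start + off
                        base[hs : hs + hole] = 0.0
            parts.append(_to_bedgraph(chrom, base))
        text = "".join(parts)
        bedgraph_texts[sid] = text
        tracks[sid] = read_coverage(text, cfg.library_size, sid)

    # ---- repeats ---------------------------------------------------------
    rep_lines: list[str] = []
    for chrom in chroms:
        n_rep = int(round(cfg.repeat_density * cfg.chromosome_length / 10_000))
        for _ in range(n_rep):
            name, rclass, rfam = _REPEAT_CATALOG[
                int(rng.integers(0, len(_REPEAT_CATALOG)))
            ]
            length = int(rng.integers(100, 1_000))
            start = int(rng.integers(0, max(1, cfg.chromosome_length - length)))
            rep_lines.append(
                f"{chrom}\t{start}\t{start + length}\t{name}\t{rclass}\t{rfam}"
            )
        # guarantee at least one repeat over each planted novel element so
        # overlap-based screens have signal
        for rec in truth.records:
            if rec.interval.chrom != chrom or rec.re_class is ReClass.EXONIC:
                continue
            name, rclass, rfam = _REPEAT_CATALOG[
                int(rng.integers(0, len(_REPEAT_CATALOG)))
            ]
            rep_lines.append(
                f"{chrom}\t{rec.interval.start}\t{rec.interval.end}\t{name}"
                f"\t{rclass}\t{rfam}"
            )
    repeat_bed_text = "\n".join(rep_lines) + "\n" if rep_lines else ""

    return Fixture(
        config=cfg,
        gtf_text=gtf_text,
        repeat_bed_text=repeat_bed_text,
        bedgraph_texts=bedgraph_texts,
        tracks=tracks,
        truth=truth,
        universe=universe,
        chrom_sizes=chrom_sizes,
    )


def _to_bedgraph(chrom: str, per_base: np.ndarray) -> str:
    """Run-length encode a per-base depth array, skipping zero runs."""
    change = np.nonzero(np.diff(per_base))[0] + 1
    bounds = np.concatenate(([0], change, [per_base.size]))
    out = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        d = per_base[s]
        if d != 0:
            out.append(f"{chrom}\t{int(s)}\t{int(e)}\t{d:g}\n")
    return "".join(out)


# --------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well discovery recovered the planted novel elements."""

    sensitivity: dict  # class -> fraction of truth elements recovered
    precision: dict  # class -> fraction of discovered elements matching truth
    jaccard: float  # per-base Jaccard, discovered novel vs planted novel


def _base_set(intervals: list[GenomicInterval]) -> set[tuple[str, int]]:
    out: set[tuple[str, int]] = set()
    for iv in intervals:
        out.update((iv.chrom, p) for p in range(iv.start, iv.end))
    return out


def score_recovery(
    discovered: list[RNAElement], truth: PlantedTruth
) -> RecoveryMetrics:
    """Score discovered novel elements against the planted ground truth.

    Per class: sensitivity is the fraction of planted elements overlapped
    (>= 1 bp) by a discovered element of the same class, precision the
    fraction of discovered elements of that class overlapping a planted
    element of the same class.  The Jaccard index is computed per base over
    the union of all novel (non-exonic) elements.
    """
    novel_disc = [el for el in discovered if el.re_class is not ReClass.EXONIC]
    novel_truth = truth.novel()
    classes = sorted({str(r.re_class) for r in novel_truth} | {str(e.re_class) for e in novel_disc})
    sens: dict[str, float] = {}
    prec: dict[str, float] = {}
    for cls in classes:
        t_cls = [r for r in novel_truth if str(r.re_class) == cls]
        d_cls = [e for e in novel_disc if str(e.re_class) == cls]
        if t_cls:
            hit = sum(
                any(r.interval.overlaps(e.interval) for e in d_cls) for r in t_cls
            )
            sens[cls] = hit / len(t_cls)
        if d_cls:
            hit = sum(
                any(e.interval.overlaps(r.interval) for r in t_cls) for e in d_cls
            )
            prec[cls] = hit / len(d_cls)
    d_bases = _base_set([e.interval for e in novel_disc])
    t_bases = _base_set([r.interval for r in novel_truth])
    union = d_bases | t_bases
    jaccard = len(d_bases & t_bases) / len(union) if union else 1.0
    return RecoveryMetrics(sensitivity=sens, precision=prec, jaccard=jaccard)
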