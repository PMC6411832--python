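"""Gene-annotation parsing and the exon universe.

The discovery workflow treats the gene annotation as a flat catalogue of
exon locations: every ``exon`` feature (and every non-coding transcript
without exon lines) becomes an exon record, transcript structure is
discarded, and overlapping exons are collapsed into a single disjoint track
of "exonic RNA elements".  Introns are the per-gene gaps between a gene's
own merged exons.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, TextIO, Union

import numpy as np
from gffutils.feature import feature_from_line

from .intervals import GenomicInterval, merge_arrays_with_gap

__all__ = [
    "ExonRecord",
    "ExonUniverse",
    "AnnotationError",
    "parse_annotation",
    "build_exon_universe",
]

# feature types treated as "one exon" when a transcript has no exon children
_TRANSCRIPT_TYPES = {"transcript", "mRNA"}


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class ExonRecord:
    """One exon occurrence from the annotation (transcript-redundant)."""

    interval: GenomicInterval
    gene_id: str
    gene_name: str
    feature_biotype: str = ""
    strand: str = "."


@dataclass
class _Chrom:
    """Merged exonic-RE arrays for one chromosome (sorted, disjoint)."""

    starts: np.ndarray
    ends: np.ndarray
    gene_names: list[frozenset[str]]


@dataclass
class ExonUniverse:
    """Disjoint exonic REs plus per-gene introns.

    ``exonic`` maps chromosome to sorted, pairwise-disjoint merged exon
    intervals, each carrying the union of contributing gene names.
    ``introns`` holds, per chromosome, arrays of intron starts/ends and the
    owning gene id; an intron is a gap between two merged exons of one gene.
    """

    exonic: dict[str, _Chrom] = field(default_factory=dict)
    intron_starts: dict[str, np.ndarray] = field(default_factory=dict)
    intron_ends: dict[str, np.ndarray] = field(default_factory=dict)
    intron_genes: dict[str, list[str]] = field(default_factory=dict)

    # -- queries ---------------------------------------------------------

    def exonic_intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self.exonic):
            c = self.exonic[chrom]
            out.extend(
                GenomicInterval(chrom, int(s), int(e))
                for s, e in zip(c.starts, c.ends)
            )
        return out

    def intron_intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self.intron_starts):
            out.extend(
                GenomicInterval(chrom, int(s), int(e))
                for s, e in zip(self.intron_starts[chrom], self.intron_ends[chrom])
            )
        return out

    def overlaps_exon(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) intersects any exonic RE by >= 1 bp."""
        c = self.exonic.get(chrom)
        if c is None or c.starts.size == 0:
            return False
        i = np.searchsorted(c.starts, end)  # exons starting before `end`
        if i == 0:
            return False
        return bool(c.ends[i - 1] > start) or bool(
            i >= 2 and c.ends[: i - 1].max() > start
        )

    def min_exon_gap(self, chrom: str, start: int, end: int) -> float:
        """Smallest empty-space gap from [start, end) to any exonic RE.

        0 if overlapping or book-ended; ``inf`` if the chromosome carries no
        exon.
        """
        c = self.exonic.get(chrom)
        if c is None or c.starts.size == 0:
            return float("inf")
        # exons are disjoint and sorted, so neighbours suffice
        i = int(np.searchsorted(c.starts, start))
        best = float("inf")
        if i < c.starts.size:
            best = min(best, max(0, int(c.starts[i]) - end))
        if i > 0:
            prev_gap = max(0, start - int(c.ends[i - 1]))
            if c.starts[i - 1] < end and c.ends[i - 1] > start:
                prev_gap = 0
            best = min(best, prev_gap)
        return best

    def in_intron(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) lies entirely within some gene's intron."""
        s = self.intron_starts.get(chrom)
        if s is None or s.size == 0:
            return False
        e = self.intron_ends[chrom]
        return bool(np.any((s <= start) & (e >= end)))

    # -- output ----------------------------------------------------------

    def to_bed(self, handle: TextIO) -> None:
        """Write the exonic REs as BED6 (name = comma-joined gene names)."""
        for chrom in sorted(self.exonic):
            c = self.exonic[chrom]
            for s, e, names in zip(c.starts, c.ends, c.gene_names):
                handle.write(
                    f"{chrom}\t{int(s)}\t{int(e)}\t{','.join(sorted(names))}\t0\t.\n"
                )


def _open_text(source: Union[str, os.PathLike, TextIO]) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    if isinstance(source, str) and ("\n" in source or source == ""):
        return io.StringIO(source)
    return open(source, "rt")


def parse_annotation(source: Union[str, os.PathLike, TextIO]) -> list[ExonRecord]:
    """Parse a GTF/GFF stream into exon records.

    ``exon`` features become one record each; transcripts that have no exon
    lines (common for non-coding entries) are kept as a single exon spanning
    the transcript.  GTF 1-based inclusive coordinates are converted to
    0-based half-open.

    Raises
    ------
    AnnotationError
        On a malformed line (names the line number) or an exon feature
        lacking a ``gene_id`` attribute.
    """
    exons: list[ExonRecord] = []
    transcripts: dict[str, ExonRecord] = {}
    transcripts_with_exons: set[str] = set()
    handle = _open_text(source)
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) < 9:
            raise AnnotationError(
                f"malformed annotation line {lineno}: expected 9 tab-separated "
                f"fields, got {len(line.split(chr(9)))}"
            )
        try:
            feat = feature_from_line(line)
        except Exception as exc:
            raise AnnotationError(f"malformed annotation line {lineno}: {exc}") from exc
        ftype = feat.featuretype
        if ftype != "exon" and ftype not in _TRANSCRIPT_TYPES:
            continue
        gene_ids = feat.attributes.get("gene_id", [])
        if not gene_ids or not gene_ids[0]:
            raise AnnotationError(
                f"line {lineno}: {ftype} feature missing gene_id attribute"
            )
        gene_id = gene_ids[0]
        gene_name = (feat.attributes.get("gene_name") or [gene_id])[0]
        biotype = (
            feat.attributes.get("gene_biotype")
            or feat.attributes.get("gene_type")
            or [""]
        )[0]
        rec = ExonRecord(
            interval=GenomicInterval(feat.seqid, feat.start - 1, feat.end),
            gene_id=gene_id,
            gene_name=gene_name,
            feature_biotype=biotype,
            strand=feat.strand or ".",
        )
        tx_id = (feat.attributes.get("transcript_id") or [""])[0]
        if ftype == "exon":
            exons.append(rec)
            if tx_id:
                transcripts_with_exons.add(tx_id)
        else:
            transcripts[tx_id or f"__line{lineno}"] = rec
    # transcript entries with no exon children count as one exon
    for tx_id, rec in transcripts.items():
        if tx_id not in transcripts_with_exons:
            exons.append(rec)
    return exons


def build_exon_universe(records: Iterable[ExonRecord]) -> ExonUniverse:
    """Collapse transcript-redundant exons into the disjoint exon universe.

    Overlapping or book-ended exons on a chromosome merge into one exonic RE
    carrying the union of gene names, regardless of which gene they belong
    to.  Introns are computed per gene as the gaps in that gene's own exon
    union; a region exonic in one gene and intronic in another is exonic.
    """
    universe = ExonUniverse()
    by_chrom: dict[str, list[ExonRecord]] = {}
    by_gene: dict[tuple[str, str], list[ExonRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.interval.chrom, []).append(rec)
        by_gene.setdefault((rec.interval.chrom, rec.gene_id), []).append(rec)

    for chrom, recs in by_chrom.items():
        starts = [r.interval.start for r in recs]
        ends = [r.interval.end for r in recs]
        ms, me, members = merge_arrays_with_gap(starts, ends, max_gap=0)
        names = [
            frozenset(recs[i].gene_name for i in idxs) for idxs in members
        ]
        universe.exonic[chrom] = _Chrom(starts=ms, ends=me, gene_names=names)

    for (chrom, _gene), recs in sorted(by_gene.items()):
        starts = [r.interval.start for r in recs]
        ends = [r.interval.end for r in recs]
        ms, me, _ = merge_arrays_with_gap(starts, ends, max_gap=0)
        if ms.size < 2:
            continue
        i_starts = me[:-1]
        i_ends = ms[1:]
        keep = i_ends > i_starts
        if not keep.any():
            continue
        prev_s = universe.intron_starts.get(chrom, np.empty(0, dtype=np.int64))
        prev_e = universe.intron_ends.get(chrom, np.empty(0, dtype=np.int64))
        universe.intron_starts[chrom] = np.concatenate([prev_s, i_starts[keep]])
        universe.intron_ends[chrom] = np.concatenate([prev_e, i_ends[keep]])
        universe.intron_genes.setdefault(chrom, []).extend(
            [recs[0].gene_id] * int(keep.sum())
        )

    # remove intron bases that overlap the merged exon track of *any* gene
    # (exon precedence): an intron interval is kept only where it stays
    # clear of all exonic REs; partial overlaps are trimmed away entirely,
    # since a novel RE there would not be "within an intron" in a usable
    # sense. Introns fully containing an exon of another gene are split.
    for chrom in list(universe.intron_starts):
        c = universe.exonic.get(chrom)
        if c is None or c.starts.size == 0:
            continue
        new_s: list[int] = []
        new_e: list[int] = []
        new_g: list[str] = []
        for s, e, g in zip(
            universe.intron_starts[chrom],
            universe.intron_ends[chrom],
            universe.intron_genes[chrom],
        ):
            # subtract exonic REs from [s, e)
            lo = int(np.searchsorted(c.ends, s, side="right"))
            cur = int(s)
            for j in range(lo, c.starts.size):
                xs, xe = int(c.starts[j]), int(c.ends[j])
                if xs >= e:
                    break
                if xs > cur:
                    new_s.append(cur)
                    new_e.append(xs)
                    new_g.append(g)
                cur = max(cur, xe)
            if cur < e:
                new_s.append(cur)
                new_e.append(int(e))
                new_g.append(g)
        universe.intron_starts[chrom] = np.asarray(new_s, dtype=np.int64)
        universe.intron_ends[chrom] = np.asarray(new_e, dtype=np.int64)
        universe.intron_genes[chrom] = new_g

    # sort introns for reproducible output
    for chrom in universe.intron_starts:
        order = np.lexsort(
            (universe.intron_ends[chrom], universe.intron_starts[chrom])
        )
        universe.intron_starts[chrom] = universe.intron_starts[chrom][order]
        universe.intron_ends[chrom] = universe.intron_ends[chrom][order]
        universe.intron_genes[chrom] = [
            universe.intron_genes[chrom][i] for i in order
        ]
    return universe
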