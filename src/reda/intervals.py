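"""Genomic interval primitives.

All coordinates in this package are 0-based half-open ``[start, end)``,
matching BED/bedGraph conventions.  GTF input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["GenomicInterval", "gap_between", "merge_with_gap"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contiguous genomic span on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start.
    end : int
        Exclusive end; ``end > start``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self!r}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def gap_between(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs of empty space between two intervals on one chromosome.

    Overlapping or book-ended intervals have gap 0.  Raises ``ValueError``
    for intervals on different chromosomes, where no gap is defined.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"gap undefined across chromosomes: {a}, {b}")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def merge_with_gap(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Fuse intervals whose separation is at most ``max_gap`` base pairs.

    A single sorted linear scan per chromosome: the current run is extended
    while ``next.start - run.end <= max_gap``.  With ``max_gap=0`` this is a
    plain union merge (book-ended intervals fuse).  The result is sorted and
    pairwise separated by more than ``max_gap``.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        run_start, run_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - run_end <= max_gap:
                run_end = max(run_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, run_start, run_end))
                run_start, run_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, run_start, run_end))
    return out


def merge_arrays_with_gap(
    starts: Sequence[int], ends: Sequence[int], max_gap: int = 0
) -> tuple[np.ndarray, np.ndarray, list[list[int]]]:
    """Array version of :func:`merge_with_gap` for one chromosome.

    Returns merged ``(starts, ends, members)`` where ``members[j]`` lists the
    input indices fused into output interval ``j`` (used to carry gene names
    and sample provenance through merges).
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends, []
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    out_s: list[int] = [int(s[0])]
    out_e: list[int] = [int(e[0])]
    members: list[list[int]] = [[int(order[0])]]
    for i in range(1, s.size):
        if s[i] - out_e[-1] <= max_gap:
            out_e[-1] = max(out_e[-1], int(e[i]))
            members[-1].append(int(order[i]))
        else:
            out_s.append(int(s[i]))
            out_e.append(int(e[i]))
            members.append([int(order[i])])
    return np.asarray(out_s), np.asarray(out_e), members
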