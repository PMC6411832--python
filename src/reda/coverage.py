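"""Coverage tracks, fixed-grid binning, and the RPM depth threshold.

A coverage track is a per-chromosome step function of read depth (the
bedGraph model); binning reduces it to the mean depth of every 10 bp
genomic segment on a grid anchored at coordinate 0, and the discovery
threshold mu (reads per million) is converted per sample into an absolute
depth via the library size.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import TextIO, Union

import numpy as np

__all__ = [
    "CoverageTrack",
    "BinnedCoverage",
    "DepthThreshold",
    "CoverageFormatError",
    "read_coverage",
    "read_bigwig",
    "write_bedgraph",
    "bin_coverage",
    "rpm_to_depth",
]


class CoverageFormatError(ValueError):
    """Raised for malformed or out-of-order coverage records."""


@dataclass
class CoverageTrack:
    """Step-function read depth for one sample.

    ``steps`` maps chromosome to ``(starts, ends, depths)`` arrays, sorted
    and non-overlapping within each chromosome.  Positions not covered by a
    step have depth 0.
    """

    sample_id: str
    library_size: int
    steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def depth_at(self, chrom: str, pos: int) -> float:
        trio = self.steps.get(chrom)
        if trio is None:
            return 0.0
        starts, ends, depths = trio
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and ends[i] > pos:
            return float(depths[i])
        return 0.0

    def mass(self, chrom: str, start: int, end: int) -> float:
        """Total per-base depth over [start, end) (sum of depth x bases)."""
        trio = self.steps.get(chrom)
        if trio is None:
            return 0.0
        starts, ends, depths = trio
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * depths[lo:hi]))

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base depth over [start, end)."""
        if end <= start:
            raise ValueError("empty interval")
        return self.mass(chrom, start, end) / (end - start)

    def total_mass(self) -> float:
        return sum(
            float(np.sum((e - s) * d)) for s, e, d in self.steps.values()
        )


@dataclass
class BinnedCoverage:
    """Mean depth per fixed-size genomic bin, grid anchored at 0.

    ``means[chrom][b]`` is the mean per-base depth over
    ``[b*bin_size, (b+1)*bin_size)``; bins past the stored array are 0.
    """

    bin_size: int
    means: dict[str, np.ndarray] = field(default_factory=dict)

    def mean(self, chrom: str, bin_index: int) -> float:
        arr = self.means.get(chrom)
        if arr is None or bin_index >= arr.size:
            return 0.0
        return float(arr[bin_index])

    def to_bedgraph(self, handle: TextIO) -> None:
        """Write non-zero bin means as bedGraph records (for inspection)."""
        b = self.bin_size
        for chrom in sorted(self.means):
            arr = self.means[chrom]
            for i in np.nonzero(arr)[0]:
                handle.write(f"{chrom}\t{i * b}\t{(i + 1) * b}\t{arr[i]:g}\n")


@dataclass(frozen=True)
class DepthThreshold:
    """The discovery threshold mu expressed as an absolute read depth."""

    mu: float
    library_size: int
    absolute_depth: float


def rpm_to_depth(mu: float, library_size: int) -> DepthThreshold:
    """Convert a reads-per-million threshold into absolute depth.

    ``absolute_depth = mu * library_size / 1e6``: with a 20 M-read library,
    mu = 2.5 RPM corresponds to 50 reads of depth.
    """
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    return DepthThreshold(
        mu=mu, library_size=library_size, absolute_depth=mu * library_size / 1e6
    )


def _open_text(source: Union[str, os.PathLike, TextIO]) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    if isinstance(source, str) and ("\n" in source or source == ""):
        return io.StringIO(source)
    return open(source, "rt")


def read_coverage(
    source: Union[str, os.PathLike, TextIO],
    library_size: int,
    sample_id: str = "",
) -> CoverageTrack:
    """Read a bedGraph stream into a :class:`CoverageTrack`.

    Records must be sorted and non-overlapping within each chromosome
    (bedtools genomecov output satisfies this); a violation raises
    :class:`CoverageFormatError` naming the offending record.
    """
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    handle = _open_text(source)
    chroms: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in enumerate(handle, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise CoverageFormatError(
                f"bedGraph record {lineno}: expected 4 columns, got {len(parts)}"
            )
        chrom, start, end, depth = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if depth < 0:
            raise CoverageFormatError(f"bedGraph record {lineno}: negative depth")
        if end <= start:
            raise CoverageFormatError(
                f"bedGraph record {lineno}: empty interval {chrom}:{start}-{end}"
            )
        recs = chroms.setdefault(chrom, [])
        if recs and start < recs[-1][1]:
            raise CoverageFormatError(
                f"bedGraph record {lineno}: {chrom}:{start}-{end} overlaps or "
                f"precedes previous record ending at {recs[-1][1]}"
            )
        recs.append((start, end, depth))
    track = CoverageTrack(sample_id=sample_id, library_size=library_size)
    for chrom, recs in chroms.items():
        arr = np.asarray(recs, dtype=float)
        track.steps[chrom] = (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2],
        )
    return track


def read_bigwig(
    path: Union[str, os.PathLike], library_size: int, sample_id: str = ""
) -> CoverageTrack:
    """Read a bigWig file into the same step representation.

    Requires the optional ``pyBigWig`` dependency.
    """
    import pyBigWig  # deferred: optional dependency

    bw = pyBigWig.open(os.fspath(path))
    track = CoverageTrack(sample_id=sample_id, library_size=library_size)
    try:
        for chrom in bw.chroms():
            ivs = bw.intervals(chrom)
            if not ivs:
                continue
            arr = np.asarray(ivs, dtype=float)
            keep = arr[:, 2] != 0
            arr = arr[keep]
            track.steps[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
    finally:
        bw.close()
    return track


def write_bedgraph(track: CoverageTrack, handle: TextIO) -> None:
    """Write a coverage track as bedGraph (all stored steps, as stored)."""
    for chrom in sorted(track.steps):
        starts, ends, depths = track.steps[chrom]
        for s, e, d in zip(starts, ends, depths):
            handle.write(f"{chrom}\t{int(s)}\t{int(e)}\t{d:g}\n")


def bin_coverage(
    track: CoverageTrack,
    bin_size: int = 10,
    chrom_sizes: dict[str, int] | None = None,
) -> BinnedCoverage:
    """Reduce a step track to mean depth per fixed ``bin_size`` bp bin.

    Each bin's value is the arithmetic mean of per-base depth over its
    ``bin_size`` bases; bases beyond the last step count as 0.  When the
    chromosome length is known and not a bin multiple, the final partial
    bin averages over the actual remaining bases.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    binned = BinnedCoverage(bin_size=bin_size)
    for chrom, (starts, ends, depths) in track.steps.items():
        if starts.size == 0:
            continue
        length = None if chrom_sizes is None else chrom_sizes.get(chrom)
        last = int(ends.max())
        if length is not None and last > length:
            raise ValueError(
                f"{chrom}: coverage extends to {last}, past stated length {length}"
            )
        span = length if length is not None else last
        n_bins = -(-span // bin_size)
        # accumulate depth mass per bin from the step endpoints
        mass = np.zeros(n_bins, dtype=float)
        for s, e, d in zip(starts, ends, depths):
            if d == 0:
                continue
            b0, b1 = int(s) // bin_size, (int(e) - 1) // bin_size
            if b0 == b1:
                mass[b0] += d * (e - s)
                continue
            mass[b0] += d * ((b0 + 1) * bin_size - s)
            mass[b1] += d * (e - b1 * bin_size)
            if b1 > b0 + 1:
                mass[b0 + 1 : b1] += d * bin_size
        denom = np.full(n_bins, float(bin_size))
        if length is not None and length % bin_size:
            denom[-1] = length % bin_size
        binned.means[chrom] = mass / denom
    return binned
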