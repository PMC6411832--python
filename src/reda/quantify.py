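"""RPKM quantification of RNA elements and expressed-element calling.

Elements are quantified per sample as reads per kilobase per million
mapped reads; samples are grouped into cell types and an element is
"expressed" in a cell type when its median RPKM over the group's samples
exceeds 25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .discovery import RNAElement

__all__ = [
    "ExpressionMatrix",
    "ExpressedCall",
    "rpkm",
    "quantify_res",
    "call_expressed",
]

logger = logging.getLogger(__name__)

EXPRESSED_RPKM_THRESHOLD = 25.0
DEFAULT_READ_LENGTH = 75


def rpkm(read_count: float, re_length: int, library_size: int) -> float:
    """Reads per kilobase of element per million mapped reads.

    ``1e9 * read_count / (library_size * re_length)``.
    """
    if re_length <= 0:
        raise ValueError(f"re_length must be positive, got {re_length}")
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    return 1e9 * read_count / (library_size * re_length)


@dataclass
class ExpressionMatrix:
    """Element x sample RPKM values with a sample -> cell-type grouping."""

    values: pd.DataFrame  # index = re_id, columns = sample_id
    groups: dict[str, str]  # sample_id -> cell type

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without a cell-type group: {sorted(missing)}")

    def cell_types(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def group_values(self, cell_type: str) -> pd.DataFrame:
        cols = [s for s in self.values.columns if self.groups[s] == cell_type]
        return self.values[cols]

    def aggregate(self, cell_type: str, how: str = "median") -> pd.Series:
        """Per-element median (or mean) RPKM over the cell type's samples."""
        sub = self.group_values(cell_type)
        if sub.shape[1] == 0:
            raise ValueError(f"cell type {cell_type!r} has no samples")
        return sub.median(axis=1) if how == "median" else sub.mean(axis=1)

    def to_tsv(self, handle, res: "list[RNAElement] | None" = None) -> None:
        df = self.values.copy()
        if res is not None:
            meta = pd.DataFrame(
                {
                    "class": [str(el.re_class) for el in res],
                    "gene_names": [",".join(sorted(el.gene_names)) for el in res],
                },
                index=[el.id for el in res],
            )
            df = meta.join(df, how="right")
        df.index.name = "re_id"
        df.to_csv(handle, sep="\t")


@dataclass(frozen=True)
class ExpressedCall:
    """Expressed/not-expressed call for one element in one cell type."""

    re_id: str
    cell_type: str
    median_rpkm: float
    expressed: bool


def quantify_res(
    res: list[RNAElement],
    tracks: list[CoverageTrack],
    groups: dict[str, str] | None = None,
    read_length: int = DEFAULT_READ_LENGTH,
) -> ExpressionMatrix:
    """RPKM of every element in every sample, from coverage tracks.

    The read count over an element is estimated from coverage as
    ``(sum of per-base depth) / read_length``; an element on a chromosome a
    sample lacks gets 0 with a logged warning.
    """
    ids = [el.id for el in res]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate element ids")
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    data = {}
    warned: set[tuple[str, str]] = set()
    for track in tracks:
        col = np.zeros(len(res))
        for i, el in enumerate(res):
            iv = el.interval
            if iv.chrom not in track.steps:
                key = (track.sample_id, iv.chrom)
                if key not in warned:
                    logger.warning(
                        "sample %s has no coverage on %s; RPKM set to 0",
                        track.sample_id,
                        iv.chrom,
                    )
                    warned.add(key)
                continue
            count = track.mass(iv.chrom, iv.start, iv.end) / read_length
            col[i] = rpkm(count, iv.length, track.library_size)
        data[track.sample_id] = col
    values = pd.DataFrame(data, index=ids)
    if groups is None:
        groups = {t.sample_id: t.sample_id for t in tracks}
    return ExpressionMatrix(values=values, groups=groups)


def call_expressed(
    matrix: ExpressionMatrix,
    threshold: float = EXPRESSED_RPKM_THRESHOLD,
    aggregator: str = "median",
) -> list[ExpressedCall]:
    """Call each (element, cell type) expressed when the group median RPKM
    strictly exceeds ``threshold`` (default 25 RPKM)."""
    calls: list[ExpressedCall] = []
    for cell_type in matrix.cell_types():
        agg = matrix.aggregate(cell_type, aggregator)
        for re_id, value in agg.items():
            calls.append(
                ExpressedCall(
                    re_id=str(re_id),
                    cell_type=cell_type,
                    median_rpkm=float(value),
                    expressed=bool(value > threshold),
                )
            )
    return calls


def expressed_ids_by_cell_type(calls: list[ExpressedCall]) -> dict[str, set[str]]:
    """Group the expressed element ids of a call list by cell type."""
    out: dict[str, set[str]] = {}
    for c in calls:
        out.setdefault(c.cell_type, set())
        if c.expressed:
            out[c.cell_type].add(c.re_id)
    return out


def calls_to_frame(calls: list[ExpressedCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "re_id": [c.re_id for c in calls],
            "cell_type": [c.cell_type for c in calls],
            "median_rpkm": [c.median_rpkm for c in calls],
            "expressed": [c.expressed for c in calls],
        }
    )
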