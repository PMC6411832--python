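"""Repeat-family enrichment of expressed elements.

For each repeat name, the expressed elements of a cell type are tested
against the repeat's frequency among all elements with a hypergeometric
test (both tails: enrichment and depletion), Bonferroni-corrected over the
repeat names tested, and filtered to effects where observed and expected
counts differ by more than 10 elements.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import TextIO, Union

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .discovery import RNAElement
from .intervals import GenomicInterval

__all__ = [
    "RepeatFeature",
    "EnrichmentResult",
    "read_repeats",
    "annotate_repeat_overlap",
    "hypergeom_enrichment",
    "bonferroni",
    "effect_filter",
    "compute_enrichment",
]

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_DIFF = 10.0


@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker-style repeat instance."""

    interval: GenomicInterval
    repeat_name: str
    repeat_class: str = ""
    repeat_family: str = ""

    def __post_init__(self) -> None:
        if not self.repeat_name:
            raise ValueError("repeat_name must be non-empty")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one repeat in one cell type's
    expressed elements.

    N elements in the universe, K of them overlapping the repeat; n
    expressed elements, k of them overlapping the repeat.  ``expected`` is
    the null draw ``n * K / N``.
    """

    repeat_name: str
    cell_type: str
    universe_size: int  # N
    universe_hits: int  # K
    sample_size: int  # n
    observed: int  # k
    expected: float
    p_enrich: float
    p_deplete: float
    p_adj: float
    direction: str  # enriched | depleted | none
    retained: bool


def _open_text(source: Union[str, os.PathLike, TextIO]) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    if isinstance(source, str) and ("\n" in source or source == ""):
        return io.StringIO(source)
    return open(source, "rt")


def read_repeats(source: Union[str, os.PathLike, TextIO]) -> list[RepeatFeature]:
    """Read a RepeatMasker-style BED/TSV repeat annotation.

    Expects at least 4 tab-separated columns (chrom, start, end, name);
    columns 5 and 6, when present, are the repeat class and family (UCSC
    rmsk ``genoName genoStart genoEnd repName repClass repFamily`` order).
    """
    out: list[RepeatFeature] = []
    for line in _open_text(source):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"repeat record needs >= 4 columns: {line!r}")
        out.append(
            RepeatFeature(
                interval=GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                repeat_name=parts[3],
                repeat_class=parts[4] if len(parts) > 4 else "",
                repeat_family=parts[5] if len(parts) > 5 else "",
            )
        )
    return out


def annotate_repeat_overlap(
    res: list[RNAElement], repeats: list[RepeatFeature]
) -> dict[str, set[str]]:
    """Map each element id to the repeat names it intersects by >= 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for rep in repeats:
        trees.setdefault(rep.interval.chrom, IntervalTree()).addi(
            rep.interval.start, rep.interval.end, rep.repeat_name
        )
    out: dict[str, set[str]] = {}
    for el in res:
        iv = el.interval
        tree = trees.get(iv.chrom)
        hits = (
            {h.data for h in tree.overlap(iv.start, iv.end)} if tree else set()
        )
        out[el.id] = hits
    return out


def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Two tail probabilities for X ~ Hypergeometric(N, K, n).

    Returns ``(P(X >= k), P(X <= k))`` — enrichment and depletion
    p-values for observing ``k`` repeat-overlapping elements among ``n``
    drawn from a universe of ``N`` with ``K`` hits.
    """
    if not (0 <= k <= n <= N):
        raise ValueError(f"need 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if k > K:
        raise ValueError(f"observed k={k} exceeds universe hits K={K}")
    dist = hypergeom(M=N, n=K, N=n)
    p_enrich = float(dist.sf(k - 1))
    p_deplete = float(dist.cdf(k))
    return min(p_enrich, 1.0), min(p_deplete, 1.0)


def bonferroni(p_values: list[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: ``min(1, m * p)`` with ``m`` = number of
    tests (defaults to ``len(p_values)``)."""
    if m is None:
        m = len(p_values)
    for p in p_values:
        if not (0 <= p <= 1):
            raise ValueError(f"p-value out of [0, 1]: {p}")
    return [min(1.0, m * p) for p in p_values]


def effect_filter(
    results: list[EnrichmentResult], min_diff: float = DEFAULT_MIN_DIFF
) -> list[EnrichmentResult]:
    """Keep results whose observed count differs from the expected count by
    strictly more than ``min_diff`` elements and are significant."""
    return [r for r in results if r.retained and abs(r.observed - r.expected) > min_diff]


def compute_enrichment(
    res: list[RNAElement],
    repeat_overlap: dict[str, set[str]],
    expressed_ids_by_cell_type: dict[str, set[str]],
    alpha: float = DEFAULT_ALPHA,
    min_diff: float = DEFAULT_MIN_DIFF,
) -> list[EnrichmentResult]:
    """Run the full repeat screen for every cell type.

    The universe is the collective element set; per cell type, every repeat
    name present in the universe is tested, Bonferroni correction uses the
    number of repeat names tested for that cell type, and ``retained``
    requires both an adjusted p-value below ``alpha`` (either tail) and an
    observed-vs-expected difference above ``min_diff`` elements.
    """
    N = len(res)
    if N == 0:
        return []
    universe_ids = [el.id for el in res]
    repeat_names = sorted({r for hits in repeat_overlap.values() for r in hits})
    hits_by_repeat = {
        name: {i for i in universe_ids if name in repeat_overlap.get(i, ())}
        for name in repeat_names
    }
    out: list[EnrichmentResult] = []
    for cell_type, expressed in sorted(expressed_ids_by_cell_type.items()):
        expressed = expressed & set(universe_ids)
        n = len(expressed)
        m = len(repeat_names)
        for name in repeat_names:
            K_ids = hits_by_repeat[name]
            K = len(K_ids)
            k = len(expressed & K_ids)
            p_enr, p_dep = hypergeom_enrichment(k, n, K, N)
            expected = n * K / N
            if p_enr <= p_dep:
                direction_p, direction = p_enr, "enriched"
            else:
                direction_p, direction = p_dep, "depleted"
            p_adj = min(1.0, m * direction_p)
            significant = p_adj < alpha
            if not significant:
                direction = "none"
            retained = significant and abs(k - expected) > min_diff
            out.append(
                EnrichmentResult(
                    repeat_name=name,
                    cell_type=cell_type,
                    universe_size=N,
                    universe_hits=K,
                    sample_size=n,
                    observed=k,
                    expected=expected,
                    p_enrich=p_enr,
                    p_deplete=p_dep,
                    p_adj=p_adj,
                    direction=direction,
                    retained=retained,
                )
            )
    return out


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_type": [r.cell_type for r in results],
            "repeat": [r.repeat_name for r in results],
            "N": [r.universe_size for r in results],
            "K": [r.universe_hits for r in results],
            "n": [r.sample_size for r in results],
            "k": [r.observed for r in results],
            "expected": [r.expected for r in results],
            "p_enrich": [r.p_enrich for r in results],
            "p_deplete": [r.p_deplete for r in results],
            "p_adj": [r.p_adj for r in results],
            "direction": [r.direction for r in results],
            "retained": [r.retained for r in results],
        }
    )
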