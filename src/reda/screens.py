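"""Downstream screens on quantified elements.

Four small procedures: the log2 fold change between total-RNA and
poly(A+)-selected libraries, the maternal/paternal transmission rules for
zygotic elements, the positive-predictive-value sweep over the discovery
threshold mu and the expression threshold, and the intersect of expressed
exonic-element gene names with a reference expression database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransmissionCall",
    "PPVGrid",
    "IntersectSummary",
    "fold_change",
    "classify_transmission",
    "ppv_sweep",
    "expression_intersect",
    "DEFAULT_MU_GRID",
    "DEFAULT_THRESHOLD_GRID",
]

# sweep defaults: mu from 1 to 10 RPM in 0.5 steps, expression threshold
# from 1 to 200 RPKM in steps of 1
DEFAULT_MU_GRID: tuple[float, ...] = tuple(np.arange(1.0, 10.01, 0.5).round(2))
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(float(t) for t in range(1, 201))

DEFAULT_PSEUDOCOUNT = 0.5

# transmission rule thresholds (median RPKM)
ZYGOTE_MIN = 10.0
SPERM_ABSENT_MAX = 2.0
SPERM_PRESENT_MIN = 25.0
OOCYTE_PRESENT_MIN = 25.0
OOCYTE_LOW_MAX = 5.0
OOCYTE_ABSENT_MAX = 2.0


def fold_change(
    total_mean: float, polyA_mean: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """log2(mean(total RNA) / mean(poly(A+))) with a zero-guard pseudocount.

    Positive values mean higher abundance in the total-RNA library.
    """
    if total_mean < 0 or polyA_mean < 0:
        raise ValueError("means must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    num = total_mean + pseudocount
    den = polyA_mean + pseudocount
    if den == 0:
        return math.inf if num > 0 else 0.0
    if num == 0:
        return -math.inf
    return math.log2(num / den)


@dataclass(frozen=True)
class TransmissionCall:
    """Parental-transmission label for one zygotic element."""

    re_id: str
    label: str  # maternal | paternal_high | paternal_moderate | unassigned
    oocyte_median: float
    sperm_median: float
    zygote_median: float


def classify_transmission(
    oocyte_median: float,
    sperm_median: float,
    zygote_median: float,
    re_id: str = "",
) -> TransmissionCall:
    """Apply the parental-transmission threshold rules (median RPKM).

    maternal: zygote > 10, sperm < 2, oocyte > 25.
    paternal (greatest confidence): zygote > 10, sperm > 25, oocyte < 2.
    paternal (moderate confidence): zygote > 10, sperm > 25, oocyte < 5.
    The two paternal tiers overlap; the most stringent applicable label is
    reported, and all boundaries are strict as stated.
    """
    o, s, z = oocyte_median, sperm_median, zygote_median
    if min(o, s, z) < 0:
        raise ValueError("medians must be non-negative")
    if z > ZYGOTE_MIN and s < SPERM_ABSENT_MAX and o > OOCYTE_PRESENT_MIN:
        label = "maternal"
    elif z > ZYGOTE_MIN and s > SPERM_PRESENT_MIN and o < OOCYTE_ABSENT_MAX:
        label = "paternal_high"
    elif z > ZYGOTE_MIN and s > SPERM_PRESENT_MIN and o < OOCYTE_LOW_MAX:
        label = "paternal_moderate"
    else:
        label = "unassigned"
    return TransmissionCall(
        re_id=re_id, label=label, oocyte_median=o, sperm_median=s, zygote_median=z
    )


@dataclass
class PPVGrid:
    """Positive predictive value per (mu, expression threshold) cell.

    ``ppv.loc[mu, t]`` is the fraction of the novel elements discovered at
    ``mu`` whose median RPKM strictly exceeds ``t``; ``n_expressed`` holds
    the numerator counts and ``n_total`` the per-mu denominators.  Cells
    where no novel element was discovered are NaN (PPV undefined).
    """

    ppv: pd.DataFrame  # index = mu, columns = threshold
    n_expressed: pd.DataFrame
    n_total: pd.Series


def ppv_sweep(
    medians_by_mu: Mapping[float, Sequence[float]],
    thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> PPVGrid:
    """Sweep the expression threshold over per-mu novel-element medians.

    ``PPV(mu, t) = #(medians > t) / #(all novel elements at mu)`` — the
    denominator partitions into elements above and at-or-below the
    threshold, so PPV is non-increasing in ``t`` for fixed mu.
    """
    mus = sorted(medians_by_mu)
    thresholds = list(thresholds)
    ppv = pd.DataFrame(index=pd.Index(mus, name="mu"), columns=thresholds, dtype=float)
    n_exp = pd.DataFrame(index=ppv.index, columns=thresholds, dtype=float)
    totals = pd.Series({mu: len(medians_by_mu[mu]) for mu in mus}, name="n_total")
    for mu in mus:
        med = np.asarray(list(medians_by_mu[mu]), dtype=float)
        total = med.size
        for t in thresholds:
            above = int(np.sum(med > t))
            n_exp.loc[mu, t] = above
            ppv.loc[mu, t] = above / total if total else np.nan
    return PPVGrid(ppv=ppv, n_expressed=n_exp, n_total=totals)


@dataclass(frozen=True)
class IntersectSummary:
    """Overlap of reference-expressed genes with element-expressed genes,
    restricted to the gene names present in both inputs."""

    reference_genes: frozenset[str]  # A: reference expression > tpm_cut
    re_genes: frozenset[str]  # B: exonic-element expression > rpkm_cut
    shared_names: frozenset[str]  # the comparable name space
    intersection: frozenset[str]  # A & B
    overlap_fraction: float  # |A & B| / |B|


def _dedupe_mean(pairs: Iterable[tuple[str, float]]) -> dict[str, float]:
    """Collapse duplicated gene names to the mean of their values."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for name, value in pairs:
        sums[name] = sums.get(name, 0.0) + float(value)
        counts[name] = counts.get(name, 0) + 1
    return {name: sums[name] / counts[name] for name in sums}


def expression_intersect(
    reference_gene_tpm: Iterable[tuple[str, float]] | Mapping[str, float],
    exonic_re_rpkm: Iterable[tuple[str, float]] | Mapping[str, float],
    tpm_cut: float = 5.0,
    rpkm_cut: float = 25.0,
) -> IntersectSummary:
    """Compare reference-database gene expression with exonic-element RPKM.

    Duplicated gene names on either side are replaced by the mean of their
    values before thresholding; only names present in both inputs enter the
    comparison.  Returns the two above-cut gene sets, their intersection,
    and ``|A intersect B| / |B|`` (the fraction of element-expressed genes
    recovered in the reference).
    """
    ref = _dedupe_mean(
        reference_gene_tpm.items()
        if isinstance(reference_gene_tpm, Mapping)
        else reference_gene_tpm
    )
    res = _dedupe_mean(
        exonic_re_rpkm.items()
        if isinstance(exonic_re_rpkm, Mapping)
        else exonic_re_rpkm
    )
    shared = set(ref) & set(res)
    a = frozenset(g for g in shared if ref[g] > tpm_cut)
    b = frozenset(g for g in shared if res[g] > rpkm_cut)
    inter = a & b
    frac = len(inter) / len(b) if b else float("nan")
    return IntersectSummary(
        reference_genes=a,
        re_genes=b,
        shared_names=frozenset(shared),
        intersection=inter,
        overlap_fraction=frac,
    )
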