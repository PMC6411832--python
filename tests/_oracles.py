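"""Brute-force reference implementations used only by the tests.

Every oracle here works on explicit per-base boolean/float arrays or naive
fixpoint iteration, independently of the package's sorted-scan and
searchsorted code paths.
"""

from __future__ import annotations

import math

import numpy as np

from reda.intervals import GenomicInterval


def mask_merge_oracle(intervals, length):
    """Union-merge one chromosome's intervals via a per-base boolean mask."""
    mask = np.zeros(length, dtype=bool)
    chrom = intervals[0].chrom
    for iv in intervals:
        mask[iv.start : iv.end] = True
    out = []
    in_run = False
    for p in range(length):
        if mask[p] and not in_run:
            start, in_run = p, True
        elif not mask[p] and in_run:
            out.append(GenomicInterval(chrom, start, p))
            in_run = False
    if in_run:
        out.append(GenomicInterval(chrom, start, length))
    return out


def gap_merge_oracle(intervals, max_gap):
    """Fixpoint pairwise fusion: repeatedly fuse any two intervals whose
    gap is <= max_gap until nothing changes (O(n^2) per pass)."""
    items = [(iv.chrom, iv.start, iv.end) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                ci, si, ei = items[i]
                cj, sj, ej = items[j]
                if ci != cj:
                    continue
                gap = max(0, max(si, sj) - min(ei, ej))
                if gap <= max_gap:
                    items[i] = (ci, min(si, sj), max(ei, ej))
                    items.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(GenomicInterval(c, s, e) for c, s, e in items)


def per_base_depth(steps, length):
    """Expand (start, end, depth) records into a per-base float array."""
    arr = np.zeros(length)
    for s, e, d in steps:
        arr[s:e] = d
    return arr


def bin_means_oracle(steps, length, bin_size):
    """Bin means by padding the per-base array and reshaping."""
    arr = per_base_depth(steps, length)
    n_bins = -(-length // bin_size)
    padded = np.zeros(n_bins * bin_size)
    padded[:length] = arr
    return padded.reshape(n_bins, bin_size).mean(axis=1)


def overlap_oracle(a: GenomicInterval, b: GenomicInterval, length) -> bool:
    """>=1 bp intersection decided on per-base masks."""
    if a.chrom != b.chrom:
        return False
    ma = np.zeros(length, dtype=bool)
    mb = np.zeros(length, dtype=bool)
    ma[a.start : a.end] = True
    mb[b.start : b.end] = True
    return bool(np.any(ma & mb))


def min_exon_gap_oracle(interval, exon_intervals) -> float:
    """Brute-force minimum gap from an interval to a set of exons."""
    best = math.inf
    for ex in exon_intervals:
        if ex.chrom != interval.chrom:
            continue
        gap = max(0, max(interval.start, ex.start) - min(interval.end, ex.end))
        best = min(best, gap)
    return best


def hypergeom_tails_exact(k, n, K, N):
    """Exact tail probabilities by integer enumeration of the pmf."""
    den = math.comb(N, n)
    lo = max(0, n + K - N)
    hi = min(n, K)
    num_ge = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(max(k, lo), hi + 1))
    num_le = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(lo, min(k, hi) + 1))
    return num_ge / den, num_le / den
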