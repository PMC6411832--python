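# Methods

This note documents the model implemented by `reda`, its parameters and
defaults, the synthetic-data generator used for validation, and the design
decisions taken where the procedure left genuine freedom.

## Coordinates and the exon universe

All intervals are 0-based half-open, matching BED/bedGraph; GTF input
(1-based inclusive) is converted on read. Strand is recorded but ignored:
coverage tracks produced by standard unstranded pipelines
(`genomeCoverageBed -split -bg`) carry no strand, so discovery and
classification are unstranded throughout.

The annotation is flattened into a single disjoint exon track. Every
`exon` feature contributes; a transcript entry with no exon children
(common for non-coding annotations) counts as one exon spanning the
transcript. Overlapping exons are merged regardless of gene, and a merged
exonic RE carries the union of contributing gene names — a single genome-
wide exon track requires collapsing across genes. Introns are computed per
gene as the gaps in that gene's own merged exons, then trimmed against the
global exon track (exon precedence): a region exonic in gene A and
intronic in gene B is exonic, and the intron interval is split around the
intruding exon. Consequently no stored intron interval overlaps any exon,
and "intronic" containment tests are unambiguous.

## Discovery

For each sample the threshold μ (reads per million) becomes an absolute
depth `μ · library_size / 10⁶`. The library size is the mapped-read
count, supplied explicitly; mapped rather than total reads is standard
practice for per-million normalisation.

Coverage is averaged over fixed bins (default 10 bp) anchored at
coordinate 0. Anchoring at a fixed grid rather than at coverage-run starts
makes results independent of how the bedGraph happens to fragment a
constant-depth region; a conservation test (bin means × bin width sum to
the track's depth mass) and a split-invariance test pin this down. When
the chromosome length is known and is not a bin multiple, the final
partial bin averages over the actual remaining bases; otherwise trailing
bases are treated as zeros across a full-width bin.

A bin is *expressed* when its mean depth **strictly** exceeds the absolute
threshold ("surpassing" read strictly; configurable via
`strict_threshold`) and it overlaps no exonic RE by even one base.
Expressed bins separated by ≤ 150 bp fuse into per-sample novel REs; the
same gap rule then fuses the pooled novel REs of all samples, with the
union of source sample ids retained. Gap semantics are uniform everywhere:
`gap = start(later) − end(earlier)` under half-open coordinates, with
"within d" meaning gap ≤ d.

Classification is hierarchical: Intronic (wholly contained in an intron —
checked first, since an intron is by construction always within reach of
its flanking exons), then NearExon (minimum exon gap ≤ 10 kb), then
Orphan (> 10 kb). An RE straddling an intron boundary is not "within an
intron" and falls through to the distance rule.

### Exon extension

An exonic RE absorbs an adjacent NearExon RE when their gap is ≤ 50 bp and
the relative difference of their mean per-base depths,
`|d_e − d_n| / max(d_e, d_n)`, is strictly below 0.5. Two choices here
were open and are ours:

- *Which coverage?* With several samples there is no single depth. We use
  the across-sample mean of each sample's RPM-normalised mean depth over
  the element. This is symmetric in the samples and insensitive to library
  size; any other aggregate (pooled raw depth, a single reference sample)
  would weight deep libraries more.
- *Chaining.* Extension is applied once per exon/neighbour adjacency, to
  the nearest qualifying neighbour; extended exons are not re-examined, so
  a chain of novel REs cannot walk an exon boundary outward. If both
  depths are zero the relative difference is undefined and the rule does
  not fire.

Element ids are coordinate-derived (`chrom_start_end`) and therefore
stable across runs of identical inputs.

## Quantification and expressed calls

RPKM = `10⁹ · reads / (library_size · length)`. When quantifying from
coverage rather than alignments, the read count over an element is
estimated as (total per-base depth) / read_length (default 75 bp); for
reads fully contained in an element this equals the exact ≥ 1 bp-overlap
read count, and it is exact under uniform coverage. An element on a
chromosome absent from a sample scores 0 with a logged warning.

Samples are grouped into cell types; an element is *expressed* in a cell
type when the group's **median** RPKM strictly exceeds 25. Median is the
default aggregator everywhere; means are used only by the fold-change
screen, which is defined on means.

## Repeat enrichment

For each cell type, each repeat name present in the element universe is
tested: universe size N (all REs), universe hits K (REs intersecting the
repeat by ≥ 1 bp), sample size n (expressed REs), observed k. Both tails
of Hypergeometric(N, K, n) are computed (enrichment `P(X ≥ k)`, depletion
`P(X ≤ k)`); the smaller tail sets the direction and is Bonferroni-
corrected by the number of repeat names tested for that cell type. The
significance level on the adjusted value defaults to 0.05 (a conventional
choice, configurable), and a result is *retained* only if additionally
`|k − n·K/N| > 10` elements — an absolute effect filter that covers both
enrichment and depletion. Tests run at the repeat-name level
(e.g. HERVE-int, HSAT1); family/class roll-ups can be done by relabelling
the input features.

## Screens

- **Fold change**: `log2((mean_total + c) / (mean_polyA + c))` with
  pseudocount c = 0.5 RPKM by default (0 restores the exact ratio;
  antisymmetry under swapping inputs holds at c = 0).
- **Transmission**: with oocyte/sperm/zygote median RPKM (o, s, z):
  maternal ⇔ z > 10 ∧ s < 2 ∧ o > 25; paternal (greatest confidence) ⇔
  z > 10 ∧ s > 25 ∧ o < 2; paternal (moderate) ⇔ z > 10 ∧ s > 25 ∧ o < 5.
  The paternal tiers overlap by construction (o < 2 implies o < 5); the
  most stringent applicable label is reported. All inequalities are strict
  exactly as stated; anything else is `unassigned`.
- **PPV sweep**: discovery is re-run at each μ ∈ {1.0, 1.5, …, 10.0}; for
  each expression threshold t ∈ {1, …, 200} RPKM,
  `PPV(μ, t) = #(median > t) / #(novel REs at μ)`. The denominator
  partitions into the two formula terms, so PPV is non-increasing in t;
  a μ with no novel elements yields NaN cells rather than 0.
- **Expression intersect**: duplicated gene names on either side are
  collapsed to the mean of their values *before* thresholding; only names
  present in both inputs are compared; the summary reports A (reference
  genes > 5 TPM), B (element genes > 25 RPKM), A∩B and |A∩B|/|B|.

## Synthetic data

`generate_fixture` emulates the tool's real inputs at desk scale: a
200 kb chromosome (configurable, multiple chromosomes supported) carrying
three 4-exon genes with 1.5–2.5 kb introns and 2.5–3.5 kb intergenic
spacing, one non-coding transcript without exon lines (exercising that
annotation path), a RepeatMasker-style repeat track (default 2 repeats per
10 kb drawn from a small catalogue of real repeat names, plus one repeat
over each planted element so overlap screens have signal), and per-sample
bedGraph tracks.

Noise is an over-dispersed gamma-Poisson count per 10 bp bin (mean depth
0.8, shape 0.5), clipped strictly below the reference threshold
(μ = 2.5 RPM at the configured library size of 10⁶ reads → absolute depth
2.5, so noise depth ≤ 2). The clipping is deliberate: the generator's
contract is that background alone never produces an expressed bin, so any
discovered novel element is attributable to planted signal. Planted
elements (default one Intronic/NearExon/Orphan each, at 10× the threshold)
are written at constant depth into every sample; a `fragmentation` option
punches 1–2 random ≤ 150 bp zero-coverage holes into each planted element
to exercise the merge-gap logic. Every planted label is re-derived with
the classifier against the generated annotation, so truth labels are
self-consistent by construction, and all outputs are byte-deterministic
given the seed.

What the generator does **not** model: read-level sampling (no FASTQ, no
alignment artefacts), strand, splice junctions, depth variation along a
planted element, or biases correlated with sequence content. Passing the
planted-truth tests therefore demonstrates the correctness of the
thresholding/merging/classification machinery under the stated noise
model, not performance on real libraries.

Recovery is scored per class (sensitivity: planted elements overlapped by
a same-class discovered element; precision: the converse) plus a per-base
Jaccard index between discovered and planted novel elements. Because bin
boundaries quantise discovered coordinates to 10 bp, perfect recovery of
planted elements a few hundred bp long yields Jaccard ≈ 0.97–0.99 rather
than exactly 1.

## Numerical and interface choices

- Hypergeometric tails come from `scipy.stats.hypergeom` and are verified
  in the tests against exhaustive integer enumeration for all universes
  N ≤ 30 at 10⁻¹² absolute tolerance.
- Interval merging is a sorted linear scan (fuse while
  `next.start − run.end ≤ gap`); tests check it against a naive fixpoint
  pairwise-fusion oracle, since half-gap dilation is *not* equivalent.
- Degenerate inputs fail loudly: empty intervals, non-positive μ or
  library sizes, overlapping bedGraph records, exon-overlapping input to
  the classifier, and inconsistent hypergeometric counts all raise typed
  errors.
- Problem sizes in the test-suite and in `scripts/acceptance.py`
  (200 kb chromosomes, 2–4 samples, ~20-element universes, the full
  19 × 200 PPV grid) were chosen as the smallest sizes at which every
  code path — cross-sample merging, all three novel classes, partial
  bins, the extension rule — is exercised; all quantities reported by the
  acceptance script are recomputed from scratch at run time.

## Known limitations

- Discovery is unstranded; antisense elements merge with sense ones.
- The read-count estimate from coverage slightly over-counts reads that
  straddle element boundaries (boundary reads contribute fractionally in
  proportion to their overlap, where a true ≥ 1 bp-overlap counter counts
  them fully — the two agree when reads lie inside elements).
- Exon extension uses a single pass; pathological tilings of alternating
  exonic/novel elements could in principle support further merging.
- The 25 RPKM expressed threshold is taken as a fixed constant of the
  procedure, not re-derived from the data.
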