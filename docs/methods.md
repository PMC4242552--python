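# Methods

## Segments and scores

Per-read CpG methylation calls (Bismark methylation-extractor dialect) are
strand-collapsed: a CpG dinucleotide is one unit anchored at the forward-
strand C, and a call on the reverse-strand cytosine (position p+1) is
folded onto the unit at p. Collapsing can be disabled for strand-resolved
work. Paired-end mates sharing a read id are treated as one fragment;
mates that disagree at a CpG void that position for the fragment. Fragments
with fewer than four CpG calls are discarded before scanning.

The scanner slides a window of `window_cpgs` (default 4) consecutive CpG
units one unit at a time, so windows overlap. A fragment contributes a
pattern only when it carries unambiguous calls at *all* window CpGs;
partial coverage contributes nothing, because the scores operate on whole
patterns. A window is emitted when `min_reads` (default 16) fragments
qualify — 16 = 2⁴ is the smallest sample that can in principle populate
every four-CpG pattern, which is what keeps the entropy scale comparable
across windows. The genomic span of a window is [first CpG, last CpG + 2),
covering both bases of the last dinucleotide; all overlap operations use
this span with ≥ 1 bp half-open intersection.

Scores per window (b CpGs, N fragments, pattern counts nᵢ):

| score | definition | range |
|---|---|---|
| level L | Σ nᵢ·popcount(i) / (b·N) | [0, 1] |
| entropy ME | (1/b) Σ −(nᵢ/N) log₂(nᵢ/N) | [0, (1/b)·log₂ min(N, 2ᵇ)] |
| weighted entropy WME | (1/b) Σ tᵢ·[−(nᵢ/N) log₂(nᵢ/N)] | ≥ 0 |

with 0·log 0 := 0 and tᵢ the number of adjacent M↔U transitions in
pattern i. The weights are applied inside the sum without renormalising by
Σtᵢ: this makes WME exactly 0 whenever only transition-free patterns
(all-M, all-U) are present, which is precisely the property the bipolar
screen needs. A renormalised variant would not separate bipolar windows
from single-pattern windows.

## Level-preserving null

The null for a window keeps N and the exact observed methylated-call count
M fixed and re-arranges those M calls uniformly among the b·N slots of the
read-by-CpG matrix (the constraint is at the window scale, not per CpG
column). Each window owns an RNG stream derived from the global seed and
the window key (chromosome hash, first CpG position), so p-values are
independent of processing order and parallel layout.

- `n_reps` = 1,000 simulations per window (default).
- `null_median_entropy` is the median ME of the simulations.
- the p-value is the fraction of simulations with WME *strictly* below the
  observed WME; ties count against significance, so the estimator is
  conservative. A consequence worth noting: any window whose observed WME
  is 0 — including trivial single-pattern windows — gets p = 0, which is
  why the detection pipeline restricts to bipolar windows *before* the
  p-value filter ever acts.
- `downsample_reads` keeps round(fraction·N) reads without replacement for
  depth-matching between samples of unequal coverage (e.g. 20/28 ≈ 71.4%).

## Detection pipeline

1. keep windows with ≥ 1 all-M and ≥ 1 all-U read (bipolar);
2. compute WME p-values against the null;
3. drop windows overlapping supplied ASM regions by ≥ 1 bp, and windows
   with p > 0.05 (p = 0.05 exactly is retained — the removal condition is
   strict);
4. merge surviving spans that overlap or sit ≤ 1 bp apart;
5. associate regions to promoters, defined as TSS − 1,000 bp to
   TSS + 200 bp in transcription orientation (minus-strand promoters
   reflect around the TSS at txEnd); all regions inside one promoter merge
   regardless of gap; transcripts sharing a gene id pool the union of
   their promoters;
6. drop genes with < 10 CpG units in the promoter.

The ASM catalog is an input BED; the package bundles none. Every stage
logs record counts, and counts are monotone non-increasing through the
filters.

## Annotation and profiles

Two promoter definitions coexist deliberately: `promoter_1kb` (1 kb
upstream of the TSS) for feature-class summaries, and the −1,000/+200
window for the detection pipeline and per-gene averages — they serve
different summaries and are configured independently. CGI shores are the
2 kb flanks of merged CpG islands minus the islands; shelves are the next
2 kb minus shores and islands; both are clipped at position 0 and at
neighbouring islands, so shore/shelf/island never overlap. Segment-to-
class assignment is multi-label (≥ 1 bp overlap, one count per segment key
per class); unassigned segments land in an explicit bucket.

Methylation-state classes use strict cutoffs: hypermethylated L > 0.8,
hypomethylated L < 0.2, completely (un)methylated at exactly 1 (0).

Expression grouping is rank-based into five groups of equal size (±1),
stable under ties, group 5 highest, zero expression ranked lowest. TSS
profiles average level and entropy of segments whose *midpoint* falls in
each 100 bp bin over ±3 kb (both configurable), offsets oriented so
upstream of transcription is negative; empty bins are missing values, not
zeros. Midpoint assignment was chosen over overlap-weighting for
simplicity and because segments (≈ 30–80 bp) are much smaller than the
span; the difference is confined to bin boundaries.

## Synthetic methylomes

The generator emulates extractor-level output of a mixed cell population:
a labelled CpG landscape (uniform hypo/hyper, stochastic-intermediate,
cell-subset-specific, ASM loci), fragments drawn per window with
subpopulation sampled by fraction and calls Bernoulli(per-CpG
probability), symmetric call-flip noise, and ~50% of fragments emitted in
reverse orientation to exercise strand collapsing. ASM loci override the
subpopulation mechanism with two equal-fraction alleles of opposite state.
No fragment spans a window wider than `max_fragment_span_bp` (default
500 bp, the scale of a paired-end insert), so windows bridging distant
loci receive no reads.

Default study conditions (`mixture_study_spec`): two subpopulations at
50/50 with per-CpG probabilities 0.995 vs 0.005 at cell-subset loci, 0.02
(hypo) / 0.98 (hyper) at uniform loci, 0.5 at stochastic loci; 12 CpGs per
locus spaced 25 bp (so every promoter carries ≥ 10 CpGs and ~9 windows);
loci laid out at a 2.5 kb pitch with same-kind loci grouped, so each
gene's −1,000/+200 promoter covers exactly its own locus; depth
Poisson(20) fragments per window; 1% call-flip noise. Asymmetric bisulfite
non-conversion (unmethylated read as methylated) is available via
`non_conversion_rate`, default off.

What the generator does **not** emulate: sequence-level artifacts (quality,
mapping bias, PCR duplicates), correlated methylation along fragments
beyond the subpopulation structure, CpG-density variation within a locus,
and more than point-mass subpopulation mixtures. Passing tests therefore
demonstrate correctness of the scores, the null and the filtering logic
under a controlled mixture — not robustness to alignment artifacts or to
continuous gradients of subpopulation structure in real methylomes.

## Problem sizes and tolerances

The test and acceptance runs use ~56 loci (~500 four-CpG window slots,
~430 emitted segments) at depth 20 with 1,000-rep nulls, 500 null-drawn
segments for p-value calibration, and exhaustive oracle checks of the
entropy formula over every pattern multiset with N ≤ 8. Entropy
equivalence against the independent Shannon-entropy oracle is asserted to
1e-12; calibration allows three binomial standard errors of Monte-Carlo
noise; parameter recovery requires ≥ 95% sensitivity with zero calls at
uniform or ASM loci. Whole runs are deterministic given the seed and
reruns are compared byte for byte.

## Known limitations

- Window width is fixed per run; widths > 4 raise the depth needed to
  populate 2ᵇ patterns (b = 5 already wants 32 reads) and are supported by
  the scanner but not by tuned defaults.
- The p-value is Monte-Carlo with resolution 1/n_reps and no multiple-
  testing correction is applied, matching the screening character of the
  pipeline.
- Windows with an ambiguous call inside the window exclude that fragment
  entirely rather than imputing; at very low depth this can drop windows
  near the `min_reads` threshold.
- The common-segment comparison assumes identical CpG indices across
  samples; it keys on (chromosome, CpG positions) and silently intersects.
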