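# Methods

## Two-region isoform quantification

The *NEAT1* locus is modelled as two adjacent 1-based inclusive intervals
on chr11 (GRCh38): a common region (65,422,798–65,426,532; 3,735 bp) shared
by both isoforms and a *NEAT1_2*-specific region (65,426,533–65,445,540;
19,008 bp). The adjacency of the printed coordinates (…532 → …533)
confirms the inclusive convention, and the resulting common-region length
matches the 3.7 kb short-isoform size. On-disk BED uses 0-based half-open
coordinates with conversion at the I/O boundary only. The ~22.3 kb
full-length figure sometimes quoted for the long isoform differs slightly
from the 22,743 bp implied by the coordinates; the implementation follows
the coordinates.

A fragment is the outermost template span of a read pair (template-length
semantics, unsequenced insert gap included), matching fragment-level
(`-p`-style) counting. Classification is by ≥ 1 bp overlap of closed
intervals: both regions → *spanning* (excluded from both counts, tallied
separately), exactly one → that region, neither → *outside*. The
exclusion rule applies only at the internal junction; a fragment running
off the locus ends still counts to the single region it overlaps. RMt is
the total mapped-fragment count of the library, not locus-restricted.
Multi-mapped and non-proper pairs are counted when mapped; a
`require_proper_pairs` switch tightens this. The *NEAT1_1* eligibility
boundary is strict: specific-region FPKM < 1.0.

The locus is treated as intronless (single-exon region model), so
transcript and genomic coordinates coincide up to an offset; no CIGAR-aware
gapped overlap is attempted, and no EM-style isoform deconvolution is in
scope — the specific region alone is the unambiguous *NEAT1_2* readout.

## Synthetic libraries

`simulate_locus_fragments` places short-isoform fragments uniformly in
transcript coordinates along the common region, long-isoform fragments
along the full 22,743 bp locus, and "background" fragments on a sentinel
contig that only inflates RMt (the single global quantity FPKM needs; a
full transcriptome would add nothing). Insert sizes are truncated-normal
(default mean 300 bp, sd 50 bp, 2×48 bp reads — a conventional short-insert
library; the defaults are a convention, not data-derived), redrawn until
read_length ≤ length ≤ transcript length. A short-isoform request whose
mean insert exceeds the common-region length is rejected as an impossible
library. Output serializes to coordinate-sorted, properly-paired SAM.

For a fixed fragment length *l* placed uniformly on the *L* bp locus,
*l* − 1 of the *L* − *l* + 1 admissible starts cover the junction; the
simulated spanning fraction is checked against this closed form. Note a
small systematic consequence: because fragments must fit inside the
transcript and junction-spanning fragments are excluded, uniform
long-isoform coverage gives a specific/common FPKM ratio slightly above
1 (≈ 1.07 at the default insert size), not exactly 1; the recovery check
uses 20,000 fragments so sampling noise does not dominate this edge bias.

## FISH quantification

Pipeline: per-channel maximum-intensity projection over z → Otsu threshold
on the DAPI projection (the standard operationalization of an "automatic
threshold"; no specific variant is mandated by the workflow being
reproduced) → hole filling → removal of components below `min_area`
(default 100 px) → 8-connected labelling. Touching nuclei are not split
(no watershed): the generator places non-overlapping nuclei, and manual
outlines can be supplied as an external label mask that bypasses
segmentation entirely. Single-plane FFPE images are the z = 1 degenerate
case. A constant DAPI image has no defined threshold and yields an empty
mask with a warning.

Per-nucleus mean signal intensity is the arithmetic mean of signal-channel
pixels under the label. Foci are local maxima within a nucleus exceeding
`median + factor × (1.4826 · MAD)` of that nucleus's pixels (factor 5 by
default) with non-maximum suppression at 3 px; foci are sparse, so the
nucleus median/MAD estimate the local background robustly. A tiny epsilon
keeps perfectly flat nuclei focus-free.

The ordinal 0–3 score is defined operationally: a nucleus is positive with
≥ 1 focus, and the sample score counts how many of the ascending
positive-fraction thresholds (default 5% / 25% / 60%) the sample reaches.
Published scoring criteria of this kind are shown as reference images, not
numbers, so the fraction-based rule with configurable thresholds is this
package's explicit, reproducible operationalization; image-level results
are method-matched rather than bit-matched to any particular manual
scoring, and whether focus size/brightness should also weigh in is left to
the configurable criteria.

The generator emulates 40x confocal fields at ~0.2 µm/px: 7 z-slices,
512×512 px, disc-shaped nuclei of radius 18–26 px (~8–10 µm diameter)
placed without overlap (error after 1,000 failed attempts),
diffraction-limited Gaussian foci (σ 1.5 px, amplitude 200 vs DAPI 150,
noise sd 10) each confined to one random z slice, additive Gaussian noise
clipped at zero. Foci within one nucleus keep a minimum 5 px separation:
closer foci would be indistinguishable in the image itself, and the truth
record must remain recoverable in principle for exact-recovery tests (real
paraspeckles do cluster below the resolution limit — which is precisely why
per-nucleus intensity, also provided, is the robust readout for such data).
What passing tests show is therefore that the operators are correct on
resolvable, disc-nucleus data; crowded tissue with touching nuclei,
autofluorescence gradients, or sub-resolution clusters will degrade foci
counts before intensities.

## ΔΔCq

The reference panel Cq is the arithmetic mean of the *GAPDH*, *B2M* and
*RPLP0* Cq values — identical to the geometric mean of their relative
quantities 2^(−Cq) expressed back in Cq space, the only self-consistent
reading of a "geometric mean" reference panel (a geometric mean of Cq
values directly would be scale-dependent). Technical replicates are
averaged (arithmetic mean of Cq) before normalization; efficiency is fixed
at 2.0 with no standard-curve correction. ΔCq = Cq_target − Cq_panel,
ΔΔCq = ΔCq_sample − ΔCq_calibrator (default calibrator MCF7), fold =
2^(−ΔΔCq); the calibrator's fold change is exactly 1. Averaging biological
replicates before vs after fold-change computation is left to the caller —
both orders are reachable from the API.

The plate generator writes target Cq = calibrator Cq − true log2 fold
change (+ noise), stable reference-gene means, and an optional per-sample
global Cq shift that must cancel under normalization (shift invariance).

## Association statistics

Chi-square is Pearson's, over all four score levels (no positive/negative
collapse), no Yates correction, no cell pooling — verified to reproduce all
eight published screening-cohort p-values (0.920, 0.027, 0.156, 0.213,
0.990, 0.131, 0.226, 0.042) from the published counts to 3 decimals.
Missing data are excluded per variable (diameter n = 69, lymph node
n = 71), never by whole-cohort deletion. Degenerate tables (zero margins)
are rejected.

Rank tests: Mann-Whitney uses full enumeration of group assignments when
n₁ + n₂ ≤ 10 (two-sided p = probability of a |U − n₁n₂/2| deviation at
least as large; mid-ranks handle ties naturally) and the tie-corrected
normal approximation otherwise. Kruskal-Wallis is tie-corrected with a χ²
approximation; an all-identical input returns H = 0, p = 1 by definition.
Pairwise Wilcoxon post-tests report unadjusted p (as conventionally
printed) alongside Holm-adjusted p, explicitly labelled — no adjustment
method is standard for such post-test stars, so both are shown. Spearman
uses mid-ranks with an exact permutation p for n ≤ 9 and the t
approximation otherwise; constant inputs flag rho as undefined rather than
guessing.

The packaged screening cohort stores the published per-variable
cross-tabulations; the patient-level accessor reconstructs a synthetic
74-row table whose every per-variable margin matches exactly. The joint
distribution across variables is not identifiable from published margins,
so variables are assigned independently within each score group — harmless
for any one-variable-at-a-time analysis, wrong for cross-variable models,
and documented as such.

The cohort generator draws stratum labels from a marginal weight vector and
scores from per-stratum probability vectors (validated to sum to 1 within
1e-9); defaults are the screening cohort's grade-row proportions, which
give Table-1-like structure under the alternative and exact exchangeability
under the null when strata share a vector.

## Problem sizes and numerics

Default validation sizes: 10⁴ random fragments for the counting oracle,
5,000–20,000 simulated fragments for FPKM recovery, 20-nucleus stacks for
FISH recovery, 50-sample plates at Cq noise sd 0.2 (recovered log2
fold-change MAE ≤ 0.5), 200 replicates for type-I/power simulation of
Kruskal-Wallis, 10⁴ permutations for the chi-square null cross-check.
These sizes make every stochastic check stable at its stated tolerance
while keeping the whole suite runnable on a laptop in about a minute.
All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical parameters and seed give
bit-identical outputs.

Known limitations: no spliced-alignment awareness; no 3-D segmentation,
deconvolution, declumping, or deep-learning segmentation; no qPCR
efficiency estimation or amplification-curve processing; no microarray
preprocessing, copy-number segmentation, or expression-subtype
classification; the original microarray/RNA-seq cohorts (controlled
access) are not ingested — their statistical machinery is validated on
synthetic cohorts only.
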