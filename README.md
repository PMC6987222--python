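# neatquant

Isoform-resolved quantification of the overlapping *NEAT1* lncRNA
transcripts, paraspeckle RNA-FISH scoring, ΔΔCq qPCR normalization, and the
cohort association statistics that tie them to breast-cancer
clinicopathology.

## The problem

The *NEAT1* locus (chr11, GRCh38) produces two overlapping isoforms: the
short, polyadenylated *NEAT1_1* (3.7 kb) completely overlaps the 5′ end of
the long *NEAT1_2* (~22.7 kb by coordinates), which is essential for
assembling nuclear paraspeckles. No RNA-seq read can positively identify
*NEAT1_1*, so isoform-level questions need a region-based strategy:

* **common region** chr11:65,422,798–65,426,532 (3,735 bp) — shared by both
  isoforms (the *NEAT1_1* transcript body);
* **specific region** chr11:65,426,533–65,445,540 (19,008 bp) — unique to
  *NEAT1_2*.

Paired-end fragments (the full template span of each read pair) are counted
per region; fragments spanning the junction between the regions are
ambiguous and excluded. Counts become

```
FPKM = RMg · 10⁹ / (RMt · L)
```

with RMg the per-region fragment count, RMt the library's total mapped
fragments, and L the region length in bp. Samples with specific-region
FPKM ≥ 1.0 express *NEAT1_2* appreciably and are filtered out when
attributing common-region signal to *NEAT1_1*.

Around that core the package provides:

* `fish_quant` — paraspeckle RNA-FISH quantification: max-intensity
  projection, Otsu segmentation of the DAPI channel, per-nucleus mean
  signal, punctate-focus detection, and an ordinal 0–3 sample score (score
  ≥ 1 = *NEAT1_2*-positive).
* `qpcr_quant` — ΔΔCq fold changes normalized to the geometric mean of a
  *GAPDH*/*B2M*/*RPLP0* reference panel (fold = 2^(−ΔΔCq)).
* `assoc_stats` — Pearson chi-square on score-by-variable tables,
  Mann-Whitney / Kruskal-Wallis / pairwise Wilcoxon rank tests, Spearman
  correlation, positivity rates, significance stars. Small samples use
  exact enumeration.
* `synthetic` — generators for alignments, image stacks, Cq plates, and
  cohorts with ground-truth records, so every pipeline is testable at desk
  scale.
* `datasets` — the packaged 74-patient screening-cohort cross-tabulations
  (plus benign n=27 and lactating n=8 score tallies).

## Worked example

```python
from neatquant.isoform_quant import RegionModel, quantify_sample
from neatquant.synthetic import ReadSimParams, simulate_locus_fragments

model = RegionModel.default()
params = ReadSimParams(
    n_fragments_short_isoform=1000,
    n_fragments_long_isoform=5000,
    n_background_fragments=4000,
    seed=1,
)
frags, truth = simulate_locus_fragments(params, model)
q = quantify_sample("patient_A", frags, model)
print(q.counts)
print(round(q.fpkm_common, 1), round(q.fpkm_specific, 1), q.neat1_1_eligible)
```

prints

```
RegionCounts(rm_common=1794, rm_specific=4127, n_spanning_excluded=79,
             rm_total=10000, n_outside=4000, n_unmapped_skipped=0)
48032.1 21711.9 False
```

Of the 6,000 locus fragments, 79 span the junction and are excluded; the
library has appreciable specific-region signal (FPKM 21,712 ≥ 1.0), so the
sample is not *NEAT1_1*-eligible — its common-region FPKM is an isoform
mixture.

The association battery on the packaged screening cohort:

```sh
neatquant reproduce-table1
```

prints the eight variable × score cross-tabulations with row percentages
and chi-square p-values (grade p = 0.027, HER2 p = 0.042, all others
non-significant) and the cohort positivity rate (66.2% of 74 patients).

## Command line

`neatquant quantify-isoforms`, `neatquant quantify-fish`, `neatquant qpcr`,
`neatquant associate`, `neatquant reproduce-table1` — see `--help` on each.
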