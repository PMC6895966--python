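# Methods

`panel-mutdyn` re-implements, as a tested library, the analysis pattern of
small neoadjuvant-chemotherapy (NAC) series in triple-negative breast
cancer profiled with a targeted cancer panel on FFPE tissue: paired
pre-treatment biopsy and residual-disease (RD) surgical samples, a matched
normal per patient, a few hundred genes, and a handful of somatic mutations
per sample. This note records the models, parameter choices and numerical
conventions behind each stage, and what the synthetic validation does and
does not demonstrate.

## Somatic filter cascade

Variants are discarded when they trip at least one of eight rules
(`somatic_filtering`): phred < 30; strand-bias p < 0.01; < 7 supporting
reads; VAF < 5% without ≥ 500× depth; VAF < 10% for C>T/G>A changes (FFPE
cytosine-deamination artifacts); population allele frequency ≥ 1% (1000
Genomes EUR or ExAC NFE) with corroborating germline evidence; normal depth
< 10×; normal VAF ≥ 10%. All rules are evaluated for every record so the
audit trail is complete; comparison operators are applied literally, and
the boundary cases (VAF = 0.05, depth = 500, normal VAF = 0.10, pop AF =
0.01, phred = 30, 7 reads) are pinned by tests.

The population-frequency rule is stated ambiguously in the sources this
kind of pipeline descends from; we gate on frequency by default (common
allele AND (dbSNP OR shallow normal)) because a frequency filter firing on
any dbSNP entry would discard rare somatic hotspots that happen to have an
rs identifier. The alternative parse is available (`r6_parse="dbsnp_or"`).
The shallow-normal clause of that rule is logically subsumed by the
standalone normal-depth rule; both are kept, as printed, for audit
fidelity. Missing evidence fields (plain-MAF input) skip the rule and flag
it in lenient mode, or discard the variant in strict mode; a missing
population frequency counts as 0 and missing dbSNP membership as False —
absence of evidence of commonness.

## Statistics

All tests are two-sided (`stats_core`). Fisher's exact test uses the
point-probability two-sided definition — the sum of hypergeometric
probabilities of all tables with fixed margins whose point probability does
not exceed the observed one — with a relative slack of 1e-7 on the
comparison so platform rounding cannot flip a boundary table. This is the
convention of R's `fisher.test` and of maftools' co-occurrence scan. The
hypergeometric upper tail is accumulated in log space. Rank tests take the
exact path (enumeration) whenever min group size ≤ 25 and the data are
tie-free — cohorts of ≤ 19 patients always qualify — and otherwise fall
back to mid-rank normal approximations with continuity correction.
Benjamini–Hochberg q-values are computed within feature scope (genes
separately from pathways, KEGG separately from GO), because the
corresponding results are reported separately. Every exact routine is
tested against an independent brute-force enumeration oracle.

## Synthetic cohorts

The generator (`synthetic_cohort`) is the validation substrate: no
per-patient variant tables are publicly deposited for the cohorts this
pipeline targets, so correctness is demonstrated by parameter recovery on
simulated data with known truth.

Model: each patient carries 1–66 mutations (log-normal count law, median
parameter 5.5, σ = 0.9, clipped to range) distributed over 1–3 clones. The
expected VAF of a mutation in a clone with cancer-cell fraction (CCF) c is
purity · c / 2 (diploid, heterozygous, no copy number — the simplest
identifiable model; purity defaults to 0.6). Read counts are overdispersed:
depth ~ negative binomial (mean 800, dispersion 10, so sd ≈ 255), alt reads
~ binomial(depth, VAF); a call is emitted only with ≥ 3 supporting reads, a
caller detection floor. The count-law median was calibrated once so that
the median number of *retained high/moderate* mutations per sample lands at
4, the figure such series report; with it, ~87% of patients carry a
truncal TP53 event (never Silent — published recurrence counts functional
mutations).

Clone CCFs sit on a fixed ladder (truncal 1.0; optional subclone 0.55 ±
0.03). A stick-breaking scheme was tried first and rejected: it places
subclones at arbitrarily similar CCFs, and two clones closer than the
binomial read noise are unidentifiable — the planted truth would be
ambiguous, which defeats the purpose of planting it. pCR patients have no
post-treatment sample (no residual tumor to sequence). Each RD patient is
planted *stable* (every clone's CCF moves ≤ 0.05 across therapy) or
*changed*: one clone with CCF ≥ 0.5 is eradicated (lost) or appears
(emergent). The planted clone receives at least two mutations when the
budget allows, because a VAF cluster needs two points to be resolvable;
patients with fewer than four mutations are planted as wholesale clonal
loss, the only change the per-patient clustering can register below its
n ≥ 4 operating floor. Contamination: per sample, Poisson(3) FFPE artifacts
(C>T/G>A, true VAF uniform 0.01–0.09); per patient, Poisson(2) germline
leak-throughs present in all of that patient's samples (normal VAF uniform
0.35–0.65, population AF ≥ 1% with probability 0.8). Clinical labels tie
relapse to profile (stable RD always relapses, changed RD with probability
0.375) so the cross-tab stage has signal to find.

Determinism: one global seed; each patient draws from
`default_rng([seed, patient_index])`, cohort-level assignments and artifact
injection from fixed offsets of the same seed, so identical configurations
are bit-identical across platforms.

What the simulations do *not* emulate: copy-number change and
loss-of-heterozygosity (which push real VAFs above purity/2), sequencing
error at the base level, spatial heterogeneity between biopsy and
resection, and panel footprint effects. Passing recovery tests therefore
shows the pipeline implements its stated model faithfully — not that the
model captures every property of real FFPE panel data.

## Paired VAF clustering and clonal profiles

Mutations are matched across timepoints by genomic key (chromosome,
position, ref, alt) — never by gene symbol — and a mutation absent at one
timepoint enters the VAF matrix as 0; loss and emergence are the signal,
not missing data. Clustering is agglomerative with Ward linkage and
Euclidean distance on (pre-VAF, post-VAF) points. The number of clusters
maximizes the mean silhouette over k ∈ 2..min(6, n−1), with fallback to a
single cluster when n < 4 or the best silhouette is below 0.25; mutations
are key-sorted before linkage so labels are deterministic. Cluster ids are
canonicalized by decreasing size, then decreasing mean pre-VAF, then
smallest member key. A cluster is *lost* when every member is below the
detection threshold (0.05, mirroring the filter's VAF floor) after therapy
and at least one was detectable before; *emergent* in the mirror case;
*retained* otherwise. A patient's profile is *changed* iff at least one
cluster was lost or emergent. These operationalizations (silhouette cut,
fate thresholds, profile rule) fill gaps the qualitative descriptions of
such analyses leave open; all are exposed as parameters.

Known limitation: mean silhouette scores a singleton cluster 0, so a single
leaked artifact or an isolated one-mutation clone can be absorbed into a
neighboring cluster (missing a change) or split out (faking one). At the
default generator settings this costs a few percent of profile calls —
recovery is ~94–98% over 50 RD patients across seeds — and is the honest
behavior of the method, not a bug to be patched around.

## Association, co-occurrence, enrichment

Only pre-treatment samples enter the response association: post-treatment
samples exist only for RD patients, a perfect confounder. Gene status is
binarized (≥ 1 high/moderate mutation), pathways inherit the OR over member
genes, and each feature gets a Fisher test against pCR/RD with BH
correction within scope; constant features are reported at p = 1 and
flagged non-informative. The reporting selection "mutated in ≥ 3 RD and 0
pCR samples" is exposed with both thresholds tunable.

Co-occurrence tests every unordered pair of genes mutated in ≥ 2 samples;
direction is co-occurrence iff the odds ratio exceeds 1; the significance
gate defaults to BH FDR < 0.05 and mutual-exclusivity pairs are excluded
from module seeding. Significant co-occurring genes seed a first-neighbor
expansion in the PPI graph; all induced edges are kept, disconnected
components retained with the largest flagged. Enrichment is a
hypergeometric upper tail against an explicit universe (default: gene-set
vocabulary ∪ PPI nodes; configurable to the panel), BH within source, gates
q < 0.05 for KEGG/custom and q < 0.01 for GO.

## Problem sizes and tolerances

Validation cohorts use 50 patients (≈ 90 samples, ≈ 900 variant rows) —
large enough for stable rates, small enough that the full suite runs in
seconds. Null calibrations use 1,000 label permutations (association) and
500 replicates of 40 × 50 Bernoulli(0.3) matrices (co-occurrence FDR).
Because Fisher's exact test is discrete, its type-I rate under permutation
is below the nominal 0.05; the calibration checks assert the one-sided
bound (no anti-conservatism). Exact-test oracle comparisons use relative
tolerance 1e-7 or tighter; clustering recovery demands exact partition
equality, not approximate agreement.
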