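# panel-mutdyn

Somatic mutation dynamics in paired pre/post neoadjuvant-chemotherapy
(NAC) tumor samples profiled with a targeted cancer gene panel.

Small NAC series — typified by triple-negative breast cancer cohorts with
a pre-treatment biopsy, a residual-disease surgical sample, a matched
normal, and a few hundred sequenced genes on FFPE tissue — all need the
same analysis chain, and each paper tends to re-implement it ad hoc.
`panel-mutdyn` packages that chain as a tested library plus CLI:

1. **FFPE-aware somatic filtering** — an eight-rule cascade over phred
   quality, strand bias, supporting reads, VAF/depth, the C>T/G>A
   deamination signature, population allele frequency, and the matched
   normal, with a complete per-variant audit trail.
2. **Mutational landscape** — per-sample burden (high/moderate impact or
   all), mutation-type and substitution-spectrum counts, top-N recurrent
   gene matrix, group burden comparisons.
3. **Response association** — binary gene/pathway status vs pCR/RD by
   Fisher's exact test with Benjamini–Hochberg correction per scope.
4. **Clonal dynamics** — the core: per-patient Ward/Euclidean clustering of
   mutations over (pre-VAF, post-VAF), cluster fates (retained / lost /
   emergent relative to a detection threshold), stable-vs-changed profile
   calls, and the profile × relapse cross-tab.
5. **Co-occurrence networks** — significantly co-occurring mutated gene
   pairs (FDR-gated Fisher), first-neighbor PPI module extraction, and
   hypergeometric gene-set enrichment (GMT input).
6. **Synthetic cohorts** — a ground-truthed generator (clones with
   pre/post cancer-cell fractions, VAF = purity·CCF/2, negative-binomial
   depth, binomial reads, FFPE artifacts, germline leak-through, planted
   stable/changed profiles) so the whole pipeline is testable end to end
   without any data download.

The statistical core (exact Fisher with the point-probability two-sided
convention, log-space hypergeometric tails, exact rank tests, BH) is
validated against brute-force enumeration oracles in the test suite. See
`docs/methods.md` for models, parameter defaults and numerical conventions.

## Worked example

```python
from panel_mutdyn import SimulationConfig, simulate_cohort, apply_filter_cascade
from panel_mutdyn.clonal_dynamics import build_paired_patients, cluster_vafs, relapse_crosstab
from panel_mutdyn.mutational_landscape import mutation_burden

config = SimulationConfig(n_patients=19, seed=7)
cohort = simulate_cohort(config)
passed, outcomes = apply_filter_cascade(cohort.variants)
print(f"{len(cohort.variants)} raw calls -> {len(passed)} confident somatic calls")

burden = mutation_burden(passed, scope="high_moderate",
                         roster=[(s, tp) for _p, s, tp in cohort.samples])
print(f"median high/moderate mutations per sample: {burden.n_mutations.median():.0f}")

paired = build_paired_patients(passed, roster=[(p, tp) for p, _s, tp in cohort.samples])
profiles = {p.patient_id: cluster_vafs(p).profile for p in paired}
table, test, _ = relapse_crosstab(profiles, cohort.clinical)
print(f"paired patients: {len(paired)}; changed profiles: "
      f"{sum(v == 'changed' for v in profiles.values())}")
print(f"stable/changed x relapse table: {table.as_array().tolist()}, "
      f"Fisher p = {test.p_value:.3f}")
```

Output:

```
471 raw calls -> 285 confident somatic calls
median high/moderate mutations per sample: 5
paired patients: 15; changed profiles: 10
stable/changed x relapse table: [[5, 0], [5, 5]], Fisher p = 0.101
```

Reading it: the filter cascade discarded 186 of 471 raw rows — every
injected germline call, and all but one FFPE artifact (the survivor's
observed VAF drifted above the 10% deamination gate) — the surviving burden is a
handful of functional mutations per sample, and 10 of 15 paired patients
show a changed clonal profile after chemotherapy. All five patients with a
stable profile relapsed versus 5 of 10 with a changed one — in a cohort
this small the cross-tab's Fisher p (0.101) stays above 0.05, which is the
expected behavior, not a failure.

The same pipeline runs from the shell:

```bash
panel-mutdyn simulate --seed 7 --out run/
panel-mutdyn filter   --in run/variants.maf.tsv --out run/filtered/
panel-mutdyn dynamics --in run/filtered/passed.tsv --clinical run/clinical.tsv --out run/dynamics/
```

Real data enter through the same door: a MAF-compatible TSV (standard
columns plus optional `phred_quality`, `strand_bias_p`, `n_vaf`,
`dbsnp_member`, `pop_af_1kg_eur`, `pop_af_exac_nfe` evidence columns), a
clinical TSV, GMT gene sets, and a two-column PPI edge list.

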