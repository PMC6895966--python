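"""Synthetic paired pre/post-treatment cohorts with full ground truth.

No per-patient variant data are publicly deposited for the kind of small
neoadjuvant TNBC panel-sequencing series this pipeline targets, so every
stage is exercised on simulated cohorts that emulate the statistical
structure the analysis assumes:

* patients carry 1-66 somatic mutations (long-tailed, median ~4 high/
  moderate-impact calls per sample after filtering);
* mutations belong to clonal sub-populations with per-timepoint cancer-cell
  fractions (CCF); expected VAF = purity * CCF / 2 under the diploid
  heterozygous no-copy-number model;
* read counts are overdispersed: depth ~ negative binomial, alt reads ~
  binomial(depth, true VAF);
* FFPE deamination artifacts enter as low-VAF C>T/G>A calls, germline
  leak-throughs as ~50% normal-VAF calls with common population alleles;
* patients achieving pCR have no post-treatment sample; residual-disease
  patients carry a planted *stable* or *changed* clonal profile (a changed
  patient has one clone lost after therapy or one emergent clone).

Every variant row carries a truth label (``true_somatic`` /
``ffpe_artifact`` / ``germline``) and a clone assignment; every RD patient
a truth profile.  Generation is deterministic given the seed: one global
seed, per-patient substreams derived from it by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import POST, PRE, ClinicalRecord, VariantRecord

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_read_counts",
    "inject_artifacts",
    "PANEL_GENES",
]

#: Subset of a comprehensive cancer panel used as the simulated target space.
PANEL_GENES = (
    "TP53 PIK3CA KRAS NRAS HRAS BRAF EGFR ERBB2 ERBB3 ERBB4 KIT FLT3 MTOR "
    "PTEN RB1 BRCA1 BRCA2 ATM ATR CHEK1 CHEK2 NOTCH1 NOTCH2 NOTCH3 NOTCH4 "
    "KMT2A KMT2C KMT2D ARID1A ARID1B ARID2 SMARCA4 SMARCB1 CREBBP EP300 "
    "MYH11 SYNE1 LRP1B FN1 BCL9 BCL2 MYC MYCN CCND1 CCND2 CCNE1 CDK4 CDK6 "
    "CDKN2A CDKN1B FGFR1 FGFR2 FGFR3 FGFR4 IGF1R IGF2 JAK1 JAK2 JAK3 TYK2 "
    "STAT3 CARD11 IKBKB REL RELA NFKB1 MAP2K1 MAP2K2 MAP2K4 MAP3K1 MAPK1 "
    "AKT1 AKT2 AKT3 RICTOR RPTOR TSC1 TSC2 STK11 NF1 NF2 SMAD2 SMAD4 "
    "TGFBR1 TGFBR2 GPR124 KEAP1 NFE2L2 RNASEL TPR NUP214 ITGB2 SOX11 SOX9 "
    "TAF1L TCF7L1 TCF7L2 GATA3 FOXA1 RUNX1 ESR1 AR LTK SF3B1 U2AF1 SRSF2 "
    "MSH2 MSH6 MLH1 PMS2 POLE POLD1 APC CTNNB1 AXIN1 FBXW7 VHL KDM5C "
    "KDM6A SETD2 DNMT3A TET2 IDH1 IDH2"
).split()

_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23))

_CLASSIFICATION_WEIGHTS = {
    "Missense_Mutation": 0.55,
    "Silent": 0.16,
    "Nonsense_Mutation": 0.08,
    "Splice_Site": 0.07,
    "Frame_Shift_Del": 0.05,
    "Frame_Shift_Ins": 0.03,
    "In_Frame_Del": 0.03,
    "Nonstop_Mutation": 0.01,
    "In_Frame_Ins": 0.01,
    "Translation_Start_Site": 0.01,
}

_SNV_CLASS_ALLELES = {
    # strand-merged class -> (pyrimidine representative, purine representative)
    "C>A/G>T": (("C", "A"), ("G", "T")),
    "C>G/G>C": (("C", "G"), ("G", "C")),
    "C>T/G>A": (("C", "T"), ("G", "A")),
    "T>A/A>T": (("T", "A"), ("A", "T")),
    "T>C/A>G": (("T", "C"), ("A", "G")),
    "T>G/A>C": (("T", "G"), ("A", "C")),
}

#: A caller will not emit a variant supported by fewer reads than this.
MIN_ALT_READS_EMIT = 3


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable knobs of the cohort generator (defaults are the study conditions)."""

    n_patients: int = 19
    pcr_fraction: float = 4 / 19
    mutations_per_patient: tuple[int, int] = (1, 66)
    #: Median of the log-normal mutation-count law, before clipping to the
    #: range above.  Calibrated so the median count of retained high/moderate
    #: mutations per sample lands near 4.
    mutation_count_median: float = 5.5
    mutation_count_sigma: float = 0.9
    n_clones: tuple[int, int] = (1, 4)
    depth_mean: float = 800.0
    depth_overdispersion: float = 10.0
    purity: float = 0.6
    ffpe_artifact_rate: float = 3.0
    germline_rate: float = 2.0
    #: Fraction of residual-disease patients planted with a *changed* profile.
    changed_fraction: float = 8 / 12
    #: Probability that a patient carries a truncal TP53 mutation.
    driver_rate: float = 0.87
    driver_gene: str = "TP53"
    seed: int = 42

    def validate(self) -> None:
        for name in ("pcr_fraction", "purity", "changed_fraction", "driver_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        lo, hi = self.mutations_per_patient
        if lo < 1 or hi < lo:
            raise ConfigError(f"invalid mutations_per_patient range ({lo}, {hi})")
        clo, chi = self.n_clones
        if clo < 1 or chi < clo:
            raise ConfigError(f"invalid n_clones range ({clo}, {chi})")
        if clo > lo:
            raise ConfigError(
                f"n_clones minimum ({clo}) exceeds mutations_per_patient minimum ({lo})"
            )
        if self.depth_mean <= 0:
            raise ConfigError(f"depth_mean must be positive, got {self.depth_mean}")
        if self.depth_overdispersion <= 0:
            raise ConfigError("depth_overdispersion must be positive")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be at least 1")


@dataclass
class SyntheticCohort:
    """Simulated variant table + clinical sheet + per-variant truth labels."""

    variants: list[VariantRecord]
    clinical: list[ClinicalRecord]
    truth: pd.DataFrame  # one row per emitted variant record
    profiles: dict[str, str]  # RD patient -> planted {stable, changed}
    samples: list[tuple[str, str, str]]  # (patient_id, sample_id, timepoint)
    config: SimulationConfig


def _key_str(record: VariantRecord) -> str:
    return f"{record.chromosome}:{record.position}:{record.ref_allele}:{record.alt_allele}"


def simulate_read_counts(
    true_vaf: float,
    depth_mean: float,
    overdispersion: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw (depth, alt_reads) for one site.

    Depth follows a negative binomial with the given mean and dispersion
    parameter (variance = mean + mean^2 / overdispersion), floored at one
    read; alt reads are binomial(depth, true_vaf).
    """
    if depth_mean <= 0:
        raise ConfigError(f"depth_mean must be positive, got {depth_mean}")
    if not 0.0 <= true_vaf <= 1.0:
        raise ValueError(f"true_vaf must lie in [0, 1], got {true_vaf}")
    p = overdispersion / (overdispersion + depth_mean)
    depth = int(max(1, rng.negative_binomial(overdispersion, p)))
    alt = int(rng.binomial(depth, true_vaf))
    return depth, alt


def _draw_classification(rng: np.random.Generator) -> tuple[str, str]:
    labels = list(_CLASSIFICATION_WEIGHTS)
    weights = np.array(list(_CLASSIFICATION_WEIGHTS.values()))
    label = str(rng.choice(labels, p=weights / weights.sum()))
    if label in ("Frame_Shift_Del", "In_Frame_Del"):
        vtype = "DEL"
    elif label in ("Frame_Shift_Ins", "In_Frame_Ins"):
        vtype = "INS"
    else:
        vtype = "SNV"
    return label, vtype


def _draw_alleles(vtype: str, rng: np.random.Generator, forced_class: str | None = None):
    bases = "ACGT"
    if vtype == "SNV":
        cls = forced_class if forced_class else str(rng.choice(list(_SNV_CLASS_ALLELES)))
        return _SNV_CLASS_ALLELES[cls][int(rng.integers(2))]
    anchor = bases[int(rng.integers(4))]
    tail = "".join(bases[int(rng.integers(4))] for _ in range(int(rng.integers(1, 4))))
    if vtype == "DEL":
        return anchor + tail, anchor
    return anchor, anchor + tail  # INS


def _clean_evidence(rng: np.random.Generator, depth_mean: float, phi: float) -> dict:
    """Evidence fields of a well-supported somatic call in a clean normal."""
    n_depth = int(max(10, rng.negative_binomial(phi, phi / (phi + depth_mean * 0.8))))
    n_alt = int(rng.binomial(n_depth, 0.002))
    dbsnp = bool(rng.random() < 0.03)
    pop_af = float(rng.uniform(0.0, 0.005)) if rng.random() < 0.3 else None
    return dict(
        phred_quality=float(rng.uniform(45.0, 99.0)),
        strand_bias_p=float(rng.uniform(0.05, 1.0)),
        normal_depth=n_depth,
        normal_vaf=n_alt / n_depth,
        dbsnp_member=dbsnp,
        pop_af_1kg_eur=pop_af,
        pop_af_exac_nfe=None,
    )


#: Pre-treatment CCFs of the truncal clone and a possible subclone.  The
#: rungs are spaced far apart so that distinct clones are identifiable at
#: panel depth: closer clones produce VAF clusters whose separation falls
#: below the binomial read-count noise and no clustering method can (or
#: should) tell them apart.  A planted emergent clone can come on top, for
#: at most three clones per patient.
_CCF_LADDER = (1.0, 0.55)


def _clone_ccfs(n_clones: int, rng: np.random.Generator) -> np.ndarray:
    """Well-separated decreasing CCFs: truncal at exactly 1, jittered subclones."""
    ccfs = [1.0]
    for rung in _CCF_LADDER[1:n_clones]:
        ccfs.append(float(np.clip(rung + rng.uniform(-0.03, 0.03), 0.1, 0.85)))
    return np.asarray(ccfs)


def _assign_mutations(n_mut: int, n_clones: int, rng: np.random.Generator) -> np.ndarray:
    """Clone index per mutation, every clone guaranteed at least one mutation."""
    assignment = np.concatenate(
        [np.arange(n_clones), rng.integers(0, n_clones, size=n_mut - n_clones)]
    )
    rng.shuffle(assignment)
    return assignment


def _simulate_patient(
    idx: int,
    response: str,
    profile: str | None,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    pid = f"p{idx + 1}"
    lo, hi = config.mutations_per_patient
    n_mut = int(
        np.clip(
            round(rng.lognormal(np.log(config.mutation_count_median), config.mutation_count_sigma)),
            lo,
            hi,
        )
    )
    clo, chi = config.n_clones
    # A VAF cluster needs >= 2 supporting mutations to be resolvable, so the
    # clone count cannot exceed half the mutation count; the CCF ladder
    # supports at most three pre-existing clones (a possible emergent clone
    # comes on top).
    cap = min(max(1, n_mut // 2), len(_CCF_LADDER))
    n_clones = int(min(rng.integers(clo, chi + 1), cap))

    ccf_pre = _clone_ccfs(n_clones, rng)
    jitter = rng.uniform(-0.05, 0.05, size=n_clones)
    ccf_post = np.clip(ccf_pre + jitter, 0.0, 1.0)

    planted_clone = None
    if profile == "changed":
        # A planted lost/emergent clone carries CCF >= 0.5 so the change is
        # unambiguous at panel depth (expected VAF >= 0.15, far from the
        # 0.05 detection floor).
        if n_mut < 4:
            # Below four mutations the per-patient clustering cannot resolve
            # a mixed change, so the planted change is wholesale: a single
            # clone holding every mutation, eradicated by therapy.
            n_clones = 1
            ccf_pre = np.array([1.0])
            ccf_post = np.array([0.0])
            planted_clone = 0
        elif rng.random() < 0.5:
            # lost clone: present before therapy, eradicated after
            target = int(rng.integers(n_clones))
            if ccf_pre[target] < 0.5:
                ccf_pre[target] = float(rng.uniform(0.5, 0.9))
            ccf_post[target] = 0.0
            planted_clone = target
        else:
            # emergent clone: absent before therapy, expanded after
            ccf_pre = np.append(ccf_pre, 0.0)
            ccf_post = np.append(ccf_post, float(rng.uniform(0.5, 0.9)))
            planted_clone = n_clones
            n_clones += 1

    assignment = _assign_mutations(n_mut, n_clones, rng)

    genes = list(rng.choice(PANEL_GENES, size=n_mut, replace=False))
    driver_slot = None
    driver_idx = None
    if rng.random() < config.driver_rate:
        # plant the recurrent driver on the truncal clone — but never at the
        # cost of de-populating another clone
        if config.driver_gene in genes:
            slot = genes.index(config.driver_gene)
        else:
            slot = 0
            genes[slot] = config.driver_gene
        current = int(assignment[slot])
        if current != 0:
            siblings = np.flatnonzero(assignment == current)
            if siblings.size >= 2:
                assignment[slot] = 0
            else:
                donors = np.flatnonzero(assignment == 0)
                if donors.size >= 1:
                    assignment[donors[0]] = current
                    assignment[slot] = 0
        driver_idx = slot
        if int(assignment[slot]) == 0:
            driver_slot = slot

    if planted_clone is not None:
        # the planted clone needs >= 2 supporting mutations to form its own
        # resolvable VAF cluster; steal one (never the planted driver) from
        # the largest clone that can spare it
        members = np.flatnonzero(assignment == planted_clone)
        if members.size < 2:
            counts = np.bincount(assignment, minlength=n_clones)
            counts[planted_clone] = 0
            donor = int(np.argmax(counts))
            if counts[donor] >= 2:
                movable = [
                    i for i in np.flatnonzero(assignment == donor) if i != driver_slot
                ]
                if movable:
                    assignment[movable[int(rng.integers(len(movable)))]] = planted_clone

    positions: set[tuple[str, int]] = set()
    mutations = []
    for m in range(n_mut):
        chrom = str(rng.choice(_CHROMOSOMES))
        while True:
            pos = int(rng.integers(10_000, 50_000_000))
            if (chrom, pos) not in positions:
                positions.add((chrom, pos))
                break
        label, vtype = _draw_classification(rng)
        if m == driver_idx and label == "Silent":
            # a planted driver event is functional: recurrence frequencies in
            # the literature count high/moderate-impact calls only
            label, vtype = "Missense_Mutation", "SNV"
        ref, alt = _draw_alleles(vtype, rng)
        mutations.append(
            dict(
                gene=genes[m],
                chromosome=chrom,
                position=pos,
                ref=ref,
                alt=alt,
                classification=label,
                vtype=vtype,
                clone=int(assignment[m]),
            )
        )

    timepoints = [PRE] if response == "pCR" else [PRE, POST]
    records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    for tp in timepoints:
        sample_id = f"{pid}_{tp}"
        ccfs = ccf_pre if tp == PRE else ccf_post
        for mut in mutations:
            ccf = float(ccfs[mut["clone"]])
            true_vaf = config.purity * ccf / 2.0
            depth, alt_reads = simulate_read_counts(
                true_vaf, config.depth_mean, config.depth_overdispersion, rng
            )
            if alt_reads < MIN_ALT_READS_EMIT:
                continue
            evidence = _clean_evidence(rng, config.depth_mean, config.depth_overdispersion)
            record = VariantRecord(
                patient_id=pid,
                sample_id=sample_id,
                timepoint=tp,
                gene=mut["gene"],
                chromosome=mut["chromosome"],
                position=mut["position"],
                ref_allele=mut["ref"],
                alt_allele=mut["alt"],
                variant_type=mut["vtype"],
                variant_classification=mut["classification"],
                tumor_depth=depth,
                tumor_alt_reads=alt_reads,
                **evidence,
            )
            records.append(record)
            truth_rows.append(
                dict(
                    patient_id=pid,
                    sample_id=sample_id,
                    timepoint=tp,
                    key=_key_str(record),
                    gene=mut["gene"],
                    label="true_somatic",
                    clone=mut["clone"],
                    ccf_pre=float(ccf_pre[mut["clone"]]),
                    ccf_post=float(ccf_post[mut["clone"]]) if response == "RD" else np.nan,
                    expected_vaf=true_vaf,
                )
            )

    samples = [(pid, f"{pid}_{tp}", tp) for tp in timepoints]
    return records, truth_rows, samples


def inject_artifacts(
    records: list[VariantRecord],
    samples: Sequence[tuple[str, str, str]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[VariantRecord], list[dict]]:
    """Add FFPE deamination artifacts and germline leak-throughs.

    FFPE artifacts are per-sample low-VAF (uniform 0.01-0.09) C>T/G>A SNVs;
    germline leak-throughs are per-patient, appear in every sequenced sample
    of that patient, carry a normal VAF drawn uniform(0.35, 0.65) and a
    population allele frequency >= 1% with probability 0.8.  Returns the
    extended record list plus the matching truth rows.
    """
    new_records = list(records)
    truth_rows: list[dict] = []

    for pid, sample_id, tp in samples:
        n_artifacts = int(rng.poisson(config.ffpe_artifact_rate))
        for _ in range(n_artifacts):
            true_vaf = float(rng.uniform(0.01, 0.09))
            depth, alt = simulate_read_counts(
                true_vaf, config.depth_mean, config.depth_overdispersion, rng
            )
            if alt < MIN_ALT_READS_EMIT:
                continue
            ref, alt_allele = _SNV_CLASS_ALLELES["C>T/G>A"][int(rng.integers(2))]
            evidence = _clean_evidence(rng, config.depth_mean, config.depth_overdispersion)
            record = VariantRecord(
                patient_id=pid,
                sample_id=sample_id,
                timepoint=tp,
                gene=str(rng.choice(PANEL_GENES)),
                chromosome=str(rng.choice(_CHROMOSOMES)),
                position=int(rng.integers(10_000, 50_000_000)),
                ref_allele=ref,
                alt_allele=alt_allele,
                variant_type="SNV",
                variant_classification="Missense_Mutation",
                tumor_depth=depth,
                tumor_alt_reads=alt,
                **evidence,
            )
            new_records.append(record)
            truth_rows.append(
                dict(
                    patient_id=pid,
                    sample_id=sample_id,
                    timepoint=tp,
                    key=_key_str(record),
                    gene=record.gene,
                    label="ffpe_artifact",
                    clone=-1,
                    ccf_pre=np.nan,
                    ccf_post=np.nan,
                    expected_vaf=true_vaf,
                )
            )

    by_patient: dict[str, list[tuple[str, str]]] = {}
    for pid, sample_id, tp in samples:
        by_patient.setdefault(pid, []).append((sample_id, tp))
    for pid, patient_samples in by_patient.items():
        n_germline = int(rng.poisson(config.germline_rate))
        for _ in range(n_germline):
            gene = str(rng.choice(PANEL_GENES))
            chrom = str(rng.choice(_CHROMOSOMES))
            pos = int(rng.integers(10_000, 50_000_000))
            label, vtype = _draw_classification(rng)
            ref, alt_allele = _draw_alleles(vtype, rng)
            common = rng.random() < 0.8
            pop_af = float(rng.uniform(0.01, 0.4)) if common else float(rng.uniform(0.0, 0.009))
            dbsnp = bool(rng.random() < 0.9)
            for sample_id, tp in patient_samples:
                depth, alt = simulate_read_counts(
                    0.5, config.depth_mean, config.depth_overdispersion, rng
                )
                if alt < MIN_ALT_READS_EMIT:
                    continue
                phi = config.depth_overdispersion
                n_depth = int(
                    max(10, rng.negative_binomial(phi, phi / (phi + config.depth_mean * 0.8)))
                )
                record = VariantRecord(
                    patient_id=pid,
                    sample_id=sample_id,
                    timepoint=tp,
                    gene=gene,
                    chromosome=chrom,
                    position=pos,
                    ref_allele=ref,
                    alt_allele=alt_allele,
                    variant_type=vtype,
                    variant_classification=label,
                    tumor_depth=depth,
                    tumor_alt_reads=alt,
                    phred_quality=float(rng.uniform(45.0, 99.0)),
                    strand_bias_p=float(rng.uniform(0.05, 1.0)),
                    normal_depth=n_depth,
                    normal_vaf=float(rng.uniform(0.35, 0.65)),
                    dbsnp_member=dbsnp,
                    pop_af_1kg_eur=pop_af,
                    pop_af_exac_nfe=None,
                )
                new_records.append(record)
                truth_rows.append(
                    dict(
                        patient_id=pid,
                        sample_id=sample_id,
                        timepoint=tp,
                        key=_key_str(record),
                        gene=gene,
                        label="germline",
                        clone=-1,
                        ccf_pre=np.nan,
                        ccf_post=np.nan,
                        expected_vaf=0.5,
                    )
                )
    return new_records, truth_rows


_TRUTH_COLUMNS = [
    "patient_id",
    "sample_id",
    "timepoint",
    "key",
    "gene",
    "label",
    "clone",
    "ccf_pre",
    "ccf_post",
    "expected_vaf",
]


def simulate_cohort(config: SimulationConfig = SimulationConfig()) -> SyntheticCohort:
    """Generate a full cohort; bit-identical for identical config + seed."""
    config.validate()
    n = config.n_patients
    cohort_rng = np.random.default_rng([config.seed, 0xC0F0])

    n_pcr = int(round(config.pcr_fraction * n))
    responses = np.array(["RD"] * n, dtype=object)
    responses[cohort_rng.permutation(n)[:n_pcr]] = "pCR"
    rd_indices = [i for i in range(n) if responses[i] == "RD"]
    n_changed = int(round(config.changed_fraction * len(rd_indices)))
    changed_set = {
        rd_indices[j] for j in cohort_rng.permutation(len(rd_indices))[:n_changed]
    }

    all_records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    samples: list[tuple[str, str, str]] = []
    clinical: list[ClinicalRecord] = []
    profiles: dict[str, str] = {}

    for i in range(n):
        rng = np.random.default_rng([config.seed, i])
        response = str(responses[i])
        profile = None
        if response == "RD":
            profile = "changed" if i in changed_set else "stable"
        records, rows, patient_samples = _simulate_patient(i, response, profile, config, rng)
        all_records.extend(records)
        truth_rows.extend(rows)
        samples.extend(patient_samples)
        pid = f"p{i + 1}"
        if profile is not None:
            profiles[pid] = profile

        if rng.random() < 0.63:
            age = int(rng.integers(32, 50))
        else:
            age = int(rng.integers(50, 76))
        stage = str(
            rng.choice(["IIA", "IIB", "IIIA", "IIIB", "IIIC"], p=[0.26, 0.53, 0.11, 0.05, 0.05])
        )
        grade = "G3" if rng.random() < 0.95 else "G2"
        if response == "pCR":
            relapse = bool(rng.random() < 0.1)
        elif profile == "stable":
            relapse = True
        else:
            relapse = bool(rng.random() < 0.375)
        stils_pre = float(np.round(rng.uniform(1.0, 35.0), 1))
        stils_post = (
            float(np.round(np.clip(stils_pre + rng.normal(2.0, 8.0), 0.0, 60.0), 1))
            if response == "RD"
            else None
        )
        clinical.append(
            ClinicalRecord(
                patient_id=pid,
                age_years=age,
                response=response,
                relapse=relapse,
                stage=stage,
                grade=grade,
                stils_pre=stils_pre,
                stils_post=stils_post,
            )
        )

    artifact_rng = np.random.default_rng([config.seed, 0xA011])
    all_records, artifact_rows = inject_artifacts(all_records, samples, config, artifact_rng)
    truth_rows.extend(artifact_rows)

    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS)
    return SyntheticCohort(
        variants=all_records,
        clinical=clinical,
        truth=truth,
        profiles=profiles,
        samples=samples,
        config=config,
    )
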