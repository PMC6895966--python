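"""Eight-rule somatic variant filter cascade for FFPE tumor/normal panels.

A variant is discarded when it trips *at least one* rule:

==== =====================================================================
R1   phred quality score < 30
R2   strand-bias p-value < 0.01
R3   variant-supporting reads < 7
R4   tumor VAF < 5% and tumor depth < 500x (deep coverage rescues low VAF)
R5   tumor VAF < 10% and C>T/G>A substitution (possible FFPE deamination)
R6   population allele frequency >= 1% (1000G EUR or ExAC NFE) combined
     with corroborating germline evidence (dbSNP membership or normal
     depth < 10x)
R7   normal-sample depth < 10x
R8   normal-sample VAF >= 10%
==== =====================================================================

All eight rules are evaluated for every record (no short-circuiting), so
the audit trail lists every reason a variant failed.  Comparison operators
are applied exactly as written above: a VAF of exactly 0.05 does not trip
R4, a normal VAF of exactly 0.10 does trip R8.

The wording of R6 is ambiguous about operator precedence; the default
parse gates on the population frequency (``af_gated``: pop_af >= 1% AND
(dbSNP OR normal depth < 10x)), because a population-frequency filter
should only ever fire on common alleles.  The alternative reading
(``dbsnp_or``: dbSNP OR (normal depth < 10x AND pop_af >= 1%)) — which
discards every dbSNP variant regardless of frequency — is available behind
the ``r6_parse`` switch.

Records read from a plain MAF lack several evidence fields.  In the
default ``lenient`` mode a rule whose inputs are missing is skipped and
flagged (``skipped_rules``); in ``strict`` mode the variant is discarded
and the unevaluable rule is listed among the failures.  Two deliberate
exceptions: a missing population frequency counts as 0 (absence of
evidence of commonness), and missing dbSNP membership counts as False.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import VariantRecord

__all__ = [
    "FilterThresholds",
    "FilterOutcome",
    "DEFAULT_THRESHOLDS",
    "RULE_IDS",
    "classify_impact",
    "substitution_class",
    "evaluate_rules",
    "apply_filter_cascade",
]

RULE_IDS = ("R1", "R2", "R3", "R4", "R5", "R6", "R7", "R8")

HIGH_IMPACT = frozenset(
    {
        "Nonsense_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "Splice_Site",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)
MODERATE_IMPACT = frozenset({"Missense_Mutation", "In_Frame_Ins", "In_Frame_Del"})
LOW_IMPACT = frozenset({"Silent"})

#: The six strand-merged single-base substitution classes.
SUBSTITUTION_CLASSES = (
    "C>A/G>T",
    "C>G/G>C",
    "C>T/G>A",
    "T>A/A>T",
    "T>C/A>G",
    "T>G/A>C",
)
NOT_SNV = "NOT_SNV"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class FilterThresholds:
    """Named constants of the filter cascade; logged with every run."""

    phred_min: float = 30.0
    strand_bias_p_min: float = 0.01
    alt_reads_min: int = 7
    low_vaf: float = 0.05
    depth_rescue: int = 500
    ffpe_vaf: float = 0.10
    pop_af_max: float = 0.01
    normal_depth_min: int = 10
    normal_vaf_max: float = 0.10


DEFAULT_THRESHOLDS = FilterThresholds()


@dataclass
class FilterOutcome:
    """Per-variant audit entry: pass/fail plus every rule that fired or was skipped."""

    sample_id: str
    key: tuple[str, int, str, str]
    passed: bool
    failed_rules: list[str] = field(default_factory=list)
    skipped_rules: list[str] = field(default_factory=list)


def classify_impact(variant_classification: str, strict: bool = True) -> str:
    """Map a variant classification to HIGH / MODERATE / LOW / MODIFIER.

    HIGH covers protein-truncating or start/stop-disrupting events,
    MODERATE in-frame coding changes, LOW synonymous changes.  Unknown
    labels raise in strict mode and fall through to MODIFIER otherwise.
    """
    if variant_classification in HIGH_IMPACT:
        return "HIGH"
    if variant_classification in MODERATE_IMPACT:
        return "MODERATE"
    if variant_classification in LOW_IMPACT:
        return "LOW"
    known_other = variant_classification in {
        "3'UTR",
        "5'UTR",
        "Intron",
        "IGR",
        "RNA",
        "3'Flank",
        "5'Flank",
    }
    if strict and not known_other:
        raise ValueError(f"unknown variant classification {variant_classification!r}")
    return "MODIFIER"


def substitution_class(ref: str, alt: str) -> str:
    """Strand-merged substitution class of a single-base change.

    Purine changes are folded onto their pyrimidine complement, e.g. both
    G>A and C>T report ``C>T/G>A``.  Indels and multi-nucleotide variants
    return :data:`NOT_SNV`.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == "-" or alt == "-":
        return NOT_SNV
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT allele in substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref}")
    if ref in ("G", "A"):  # fold onto the pyrimidine representative
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    for cls in SUBSTITUTION_CLASSES:
        if cls.startswith(f"{ref}>{alt}"):
            return cls
    raise AssertionError("unreachable")


def evaluate_rules(
    record: VariantRecord,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    mode: str = "lenient",
    r6_parse: str = "af_gated",
) -> FilterOutcome:
    """Evaluate all eight rules on one record (no short-circuiting)."""
    if mode not in ("lenient", "strict"):
        raise ValueError(f"unknown mode {mode!r}; use 'lenient' or 'strict'")
    if r6_parse not in ("af_gated", "dbsnp_or"):
        raise ValueError(f"unknown r6_parse {r6_parse!r}; use 'af_gated' or 'dbsnp_or'")
    t = thresholds
    failed: list[str] = []
    skipped: list[str] = []
    vaf = record.tumor_vaf
    if vaf is None:
        vaf = record.tumor_alt_reads / record.tumor_depth if record.tumor_depth else 0.0

    # R1 — base quality
    if record.phred_quality is None:
        skipped.append("R1")
    elif record.phred_quality < t.phred_min:
        failed.append("R1")
    # R2 — strand bias
    if record.strand_bias_p is None:
        skipped.append("R2")
    elif record.strand_bias_p < t.strand_bias_p_min:
        failed.append("R2")
    # R3 — supporting reads
    if record.tumor_alt_reads < t.alt_reads_min:
        failed.append("R3")
    # R4 — low VAF without deep coverage
    if vaf < t.low_vaf and record.tumor_depth < t.depth_rescue:
        failed.append("R4")
    # R5 — low-VAF C>T/G>A (FFPE deamination signature)
    if vaf < t.ffpe_vaf and substitution_class(record.ref_allele, record.alt_allele) == "C>T/G>A":
        failed.append("R5")
    # R6 — common population allele with germline corroboration
    pop_af = max(record.pop_af_1kg_eur or 0.0, record.pop_af_exac_nfe or 0.0)
    dbsnp = bool(record.dbsnp_member)
    if record.normal_depth is None:
        skipped.append("R6")
        skipped.append("R7")
    else:
        shallow_normal = record.normal_depth < t.normal_depth_min
        if r6_parse == "af_gated":
            r6 = pop_af >= t.pop_af_max and (dbsnp or shallow_normal)
        else:
            r6 = dbsnp or (shallow_normal and pop_af >= t.pop_af_max)
        if r6:
            failed.append("R6")
        # R7 — uninformative normal
        if shallow_normal:
            failed.append("R7")
    # R8 — variant present in the matched normal
    if record.normal_vaf is None:
        skipped.append("R8")
    elif record.normal_vaf >= t.normal_vaf_max:
        failed.append("R8")

    if mode == "strict" and skipped:
        failed = sorted(set(failed) | set(skipped), key=RULE_IDS.index)
    return FilterOutcome(
        sample_id=record.sample_id,
        key=record.key,
        passed=not failed,
        failed_rules=failed,
        skipped_rules=skipped,
    )


def apply_filter_cascade(
    records: Sequence[VariantRecord],
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    mode: str = "lenient",
    r6_parse: str = "af_gated",
) -> tuple[list[VariantRecord], list[FilterOutcome]]:
    """Filter a variant table; returns (passed records, one outcome per input).

    Input order is preserved in both outputs, and re-filtering the passed
    set is a no-op (idempotence).
    """
    outcomes = [evaluate_rules(r, thresholds, mode, r6_parse) for r in records]
    passed = [r for r, o in zip(records, outcomes) if o.passed]
    return passed, outcomes
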