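"""Cohort-level mutation summaries: burden, spectrum, recurrent genes.

All summaries operate on *filtered* variant records and are invariant
under permutation of the input order.  Burden counts distinct variant keys
per sample (two hits in one gene count twice); the recurrent-gene matrix
collapses to per-gene presence (two hits in one gene count once), matching
oncoplot semantics.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import VariantRecord
from .somatic_filtering import classify_impact, substitution_class, NOT_SNV, SUBSTITUTION_CLASSES
from .stats_core import wilcoxon_rank_sum

__all__ = [
    "mutation_burden",
    "recurrent_genes",
    "spectrum_summary",
    "compare_burden",
    "MUTATION_TYPE_GROUPS",
]

#: Reporting groups for mutation types.
MUTATION_TYPE_GROUPS = {
    "missense": frozenset({"Missense_Mutation"}),
    "truncating": frozenset(
        {"Nonsense_Mutation", "Frame_Shift_Ins", "Frame_Shift_Del", "Nonstop_Mutation"}
    ),
    "splice": frozenset({"Splice_Site"}),
    "in_frame_indel": frozenset({"In_Frame_Ins", "In_Frame_Del"}),
}

BURDEN_SCOPES = ("high_moderate", "all")


def _is_high_moderate(record: VariantRecord) -> bool:
    return classify_impact(record.variant_classification, strict=False) in (
        "HIGH",
        "MODERATE",
    )


def mutation_burden(
    records: Sequence[VariantRecord],
    scope: str = "high_moderate",
    roster: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-sample mutation counts.

    Returns one row per sample with ``n_mutations_high_moderate``,
    ``n_mutations_all`` and ``n_mutations`` (the *scope* column).  Samples
    listed in *roster* (pairs of sample_id, timepoint) but absent from the
    records are retained with count 0.
    """
    if scope not in BURDEN_SCOPES:
        raise ValueError(f"unknown scope {scope!r}; use one of {BURDEN_SCOPES}")
    counts: dict[str, dict] = {}
    if roster is not None:
        for sample_id, timepoint in roster:
            counts[sample_id] = dict(timepoint=timepoint, hm=0, all=0, keys=set())
    for r in records:
        entry = counts.setdefault(
            r.sample_id, dict(timepoint=r.timepoint, hm=0, all=0, keys=set())
        )
        if r.key in entry["keys"]:
            continue  # distinct variant keys only
        entry["keys"].add(r.key)
        entry["all"] += 1
        if _is_high_moderate(r):
            entry["hm"] += 1
    rows = [
        dict(
            sample_id=sid,
            timepoint=entry["timepoint"],
            n_mutations_high_moderate=entry["hm"],
            n_mutations_all=entry["all"],
        )
        for sid, entry in counts.items()
    ]
    table = pd.DataFrame(
        rows,
        columns=["sample_id", "timepoint", "n_mutations_high_moderate", "n_mutations_all"],
    )
    table["n_mutations"] = (
        table["n_mutations_high_moderate"] if scope == "high_moderate" else table["n_mutations_all"]
    )
    return table


def recurrent_genes(
    records: Sequence[VariantRecord],
    top_n: int = 10,
    roster: Sequence[str] | None = None,
    response: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Binary gene x sample matrix of the *top_n* most recurrently mutated genes.

    A gene counts as mutated in a sample when it carries at least one
    high/moderate-impact variant there.  Genes are ordered by decreasing
    mutated-sample frequency with alphabetical tie-break; samples by
    response group (when *response* maps sample_id to pCR/RD) then id.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    sample_ids = list(roster) if roster is not None else sorted(
        {r.sample_id for r in records}
    )
    hits: dict[str, set[str]] = {}
    for r in records:
        if r.sample_id not in sample_ids or not _is_high_moderate(r):
            continue
        hits.setdefault(r.gene, set()).add(r.sample_id)
    ranked = sorted(hits.items(), key=lambda item: (-len(item[1]), item[0]))[:top_n]
    if response is not None:
        order = {"pCR": 0, "RD": 1}
        sample_ids = sorted(
            sample_ids, key=lambda s: (order.get(response.get(s, ""), 2), s)
        )
    matrix = pd.DataFrame(
        0, index=[gene for gene, _ in ranked], columns=sample_ids, dtype=int
    )
    for gene, mutated in ranked:
        matrix.loc[gene, [s for s in mutated if s in matrix.columns]] = 1
    matrix.index.name = "gene"
    return matrix


def spectrum_summary(
    records: Sequence[VariantRecord],
) -> tuple[dict[str, int], dict[str, int]]:
    """Counts per mutation-type group and per substitution class.

    Type groups follow :data:`MUTATION_TYPE_GROUPS` with everything else
    under ``other``; substitution classes are tallied over SNVs only, so
    the class counts sum to the number of SNV records.
    """
    type_counts = {name: 0 for name in MUTATION_TYPE_GROUPS}
    type_counts["other"] = 0
    class_counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    for r in records:
        for name, members in MUTATION_TYPE_GROUPS.items():
            if r.variant_classification in members:
                type_counts[name] += 1
                break
        else:
            type_counts["other"] += 1
        cls = substitution_class(r.ref_allele, r.alt_allele)
        if cls != NOT_SNV:
            class_counts[cls] += 1
    return type_counts, class_counts


def compare_burden(
    burden: pd.DataFrame,
    grouping: Mapping[str, str] | Callable[[str], str],
    scope_column: str = "n_mutations",
) -> dict:
    """Wilcoxon rank-sum comparison of per-sample burden between two groups.

    *grouping* maps sample_id to a group label; samples it does not cover
    are excluded.  Returns the test result plus median and range per group.
    """
    lookup = grouping if callable(grouping) else grouping.get
    labels = burden["sample_id"].map(lookup)
    kept = burden[labels.notna()]
    labels = labels[labels.notna()]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    values = {
        g: kept.loc[labels == g, scope_column].to_numpy(dtype=float) for g in groups
    }
    result = wilcoxon_rank_sum(values[groups[0]], values[groups[1]])
    summary = {
        g: dict(
            n=int(v.size),
            median=float(np.median(v)),
            range=(float(v.min()), float(v.max())),
        )
        for g, v in values.items()
    }
    return dict(groups=groups, test=result, summary=summary)
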