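"""Gene- and pathway-level association of mutation status with NAC response.

Mutation status is binarized per sample (1 = at least one high/moderate-
impact mutation), pathways inherit the OR over their member genes, and
each feature is tested against pCR/RD with Fisher's exact test followed by
Benjamini-Hochberg correction within scope (genes and pathways are
corrected separately, as they are reported separately).

Only pre-treatment samples should enter the association: post-treatment
samples exist only for residual-disease patients, which would confound the
comparison perfectly.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneSetCollection, VariantRecord
from .mutational_landscape import _is_high_moderate
from .stats_core import bh_fdr, fisher_exact_2x2

__all__ = [
    "binarize",
    "pathway_status",
    "feature_response_association",
    "select_rd_enriched",
]


def binarize(
    records: Sequence[VariantRecord], samples: Sequence[str]
) -> pd.DataFrame:
    """Binary gene x sample matrix: 1 iff >= 1 high/moderate mutation.

    Records from samples outside *samples* are ignored; samples with no
    mutations appear as all-zero columns.
    """
    if len(samples) == 0:
        raise ValueError("sample list must be non-empty")
    sample_set = set(samples)
    genes = sorted(
        {r.gene for r in records if r.sample_id in sample_set and _is_high_moderate(r)}
    )
    matrix = pd.DataFrame(0, index=genes, columns=list(samples), dtype=int)
    for r in records:
        if r.sample_id in sample_set and _is_high_moderate(r):
            matrix.loc[r.gene, r.sample_id] = 1
    matrix.index.name = "gene"
    matrix.attrs["scope"] = "gene"
    return matrix


def pathway_status(
    gene_matrix: pd.DataFrame, gene_sets: GeneSetCollection
) -> tuple[pd.DataFrame, list[str]]:
    """Pathway x sample matrix: OR over member genes present in the panel.

    Pathways with no member gene in the gene matrix are dropped; their
    names are returned alongside the matrix.
    """
    if len(gene_sets) == 0:
        raise ValueError("gene-set collection is empty")
    panel = set(gene_matrix.index)
    rows = {}
    dropped: list[str] = []
    for name, members in gene_sets.items():
        present = sorted(members & panel)
        if not present:
            dropped.append(name)
            continue
        rows[name] = (gene_matrix.loc[present].sum(axis=0) > 0).astype(int)
    matrix = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=gene_matrix.columns)
    matrix = matrix.reindex(columns=gene_matrix.columns, fill_value=0).astype(int)
    matrix.index.name = "pathway"
    matrix.attrs["scope"] = "pathway"
    return matrix, dropped


def feature_response_association(
    matrix: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Fisher's exact test of each binary feature against pCR/RD labels.

    The 2x2 table per feature is [[mutated & RD, mutated & pCR],
    [wild-type & RD, wild-type & pCR]].  Features mutated in none or all
    samples are non-informative: reported with p = 1 and flagged.  q-values
    are BH-corrected across all features of the matrix.
    """
    sample_labels = pd.Series(
        {s: labels.get(s) for s in matrix.columns}, dtype=object
    ).dropna()
    unknown = set(sample_labels.unique()) - {"pCR", "RD"}
    if unknown:
        raise ValueError(f"unknown response labels: {sorted(unknown)}")
    if set(sample_labels.unique()) != {"pCR", "RD"}:
        raise ValueError("both response groups (pCR and RD) must be non-empty")
    cols = list(sample_labels.index)
    is_rd = (sample_labels == "RD").to_numpy()
    sub = matrix[cols].to_numpy()
    rows = []
    for i, feature in enumerate(matrix.index):
        mutated = sub[i].astype(bool)
        a = int(np.sum(mutated & is_rd))
        b = int(np.sum(mutated & ~is_rd))
        c = int(np.sum(~mutated & is_rd))
        d = int(np.sum(~mutated & ~is_rd))
        informative = 0 < a + b < len(cols)
        if informative:
            res = fisher_exact_2x2([[a, b], [c, d]])
            p, odds = res.p_value, res.odds_ratio
        else:
            p, odds = 1.0, np.nan
        rows.append(
            dict(
                feature=feature,
                mutated_rd=a,
                mutated_pcr=b,
                wildtype_rd=c,
                wildtype_pcr=d,
                odds_ratio=odds,
                p_value=p,
                informative=informative,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "feature",
            "mutated_rd",
            "mutated_pcr",
            "wildtype_rd",
            "wildtype_pcr",
            "odds_ratio",
            "p_value",
            "informative",
        ],
    )
    out["q_value"] = bh_fdr(out["p_value"]) if len(out) else []
    out.attrs["scope"] = matrix.attrs.get("scope", "gene")
    return out


def select_rd_enriched(
    matrix: pd.DataFrame,
    labels: Mapping[str, str],
    min_rd_count: int = 3,
    max_pcr_count: int = 0,
) -> list[str]:
    """Features mutated in >= *min_rd_count* RD samples and <= *max_pcr_count* pCR samples.

    A descriptive reporting selection (e.g. pathways preferentially mutated
    in unresponsive patients), not a significance test.
    """
    sample_labels = pd.Series({s: labels.get(s) for s in matrix.columns}).dropna()
    rd_cols = sample_labels.index[sample_labels == "RD"]
    pcr_cols = sample_labels.index[sample_labels == "pCR"]
    rd_counts = matrix[rd_cols].sum(axis=1)
    pcr_counts = matrix[pcr_cols].sum(axis=1)
    keep = (rd_counts >= min_rd_count) & (pcr_counts <= max_pcr_count)
    return list(matrix.index[keep])
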