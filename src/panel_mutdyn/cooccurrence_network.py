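"""Co-occurring mutated gene pairs, PPI module extraction and enrichment.

Pairwise co-occurrence / mutual exclusivity is tested per unordered gene
pair with Fisher's exact test on the 2x2 sample cross-tab (both / a only /
b only / neither), BH-corrected across all tested pairs.  Genes mutated in
fewer samples than ``min_mutated_samples`` are not paired — with one
mutated sample the table is degenerate and only dilutes the correction.

Significant co-occurring pairs seed a first-neighbor expansion in a
protein-protein interaction network: the module consists of the seeds plus
every direct interactor, with all induced edges.  Mutual-exclusivity pairs
are excluded from seeding by default.

Gene-set enrichment uses the hypergeometric upper tail against a fixed
universe, BH-corrected within each source tag, with default significance
gates q < 0.05 for KEGG/custom collections and q < 0.01 for GO terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import EdgeList, GeneSetCollection
from .stats_core import bh_fdr, fisher_exact_2x2, hypergeometric_upper_tail

__all__ = [
    "NetworkModule",
    "cooccurrence_scan",
    "extract_module",
    "enrich",
    "DEFAULT_Q_THRESHOLDS",
]

DEFAULT_Q_THRESHOLDS: dict[str, float] = {"KEGG": 0.05, "GO": 0.01, "C2": 0.05, "custom": 0.05}


@dataclass
class NetworkModule:
    """First-neighbor PPI expansion of a seed gene list."""

    nodes: frozenset[str]
    seeds: frozenset[str]
    edges: frozenset[tuple[str, str]]
    components: dict[str, int]  # node -> component id (0 = largest)

    @property
    def component_count(self) -> int:
        return len(set(self.components.values())) if self.components else 0


def cooccurrence_scan(
    matrix: pd.DataFrame, min_mutated_samples: int = 2
) -> pd.DataFrame:
    """Fisher co-occurrence test over all eligible unordered gene pairs.

    *matrix* is a binary gene x sample frame.  Returns one row per tested
    pair with the sample counts, odds ratio, p, BH q and direction
    (co_occurrence iff odds ratio > 1).
    """
    n_samples = matrix.shape[1]
    if n_samples < 3:
        raise ValueError(f"co-occurrence needs >= 3 samples, got {n_samples}")
    data = matrix.to_numpy(dtype=bool)
    eligible = [
        i for i in range(matrix.shape[0]) if data[i].sum() >= min_mutated_samples
    ]
    rows = []
    for ai in range(len(eligible)):
        for bi in range(ai + 1, len(eligible)):
            i, j = eligible[ai], eligible[bi]
            gi, gj = data[i], data[j]
            both = int(np.sum(gi & gj))
            a_only = int(np.sum(gi & ~gj))
            b_only = int(np.sum(~gi & gj))
            neither = n_samples - both - a_only - b_only
            res = fisher_exact_2x2([[both, a_only], [b_only, neither]])
            odds = res.odds_ratio
            rows.append(
                dict(
                    gene_a=matrix.index[i],
                    gene_b=matrix.index[j],
                    both=both,
                    a_only=a_only,
                    b_only=b_only,
                    neither=neither,
                    odds_ratio=odds,
                    p_value=res.p_value,
                    direction=(
                        "co_occurrence"
                        if odds is not None and odds > 1
                        else "mutual_exclusivity"
                    ),
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_a",
            "gene_b",
            "both",
            "a_only",
            "b_only",
            "neither",
            "odds_ratio",
            "p_value",
            "direction",
        ],
    )
    out["q_value"] = bh_fdr(out["p_value"]) if len(out) else []
    return out


def extract_module(seed_genes: Iterable[str], edges: EdgeList) -> NetworkModule:
    """Seeds plus their first neighbors, with all induced edges.

    Seeds absent from the edge list stay in the module as isolated nodes.
    Connected components are numbered by decreasing size (ties broken by
    smallest member name); the largest has id 0.
    """
    seeds = frozenset(g.upper() for g in seed_genes)
    if not seeds:
        raise ValueError("seed gene list is empty")
    graph = nx.Graph()
    graph.add_edges_from(edges.edges)
    nodes = set(seeds)
    for seed in seeds & set(graph.nodes):
        nodes.update(graph.neighbors(seed))
    sub = graph.subgraph(nodes & set(graph.nodes)).copy()
    sub.add_nodes_from(nodes)  # isolated seeds
    comps = sorted(
        nx.connected_components(sub), key=lambda c: (-len(c), min(c))
    )
    components = {node: i for i, comp in enumerate(comps) for node in comp}
    module_edges = frozenset(tuple(sorted(e)) for e in sub.edges)
    return NetworkModule(
        nodes=frozenset(nodes),
        seeds=seeds,
        edges=module_edges,
        components=components,
    )


def enrich(
    query_genes: Iterable[str],
    gene_sets: GeneSetCollection,
    universe: Iterable[str],
    q_thresholds: Mapping[str, float] | None = None,
    return_all: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of *query_genes* in each gene set.

    Query and sets are intersected with the universe before testing; terms
    with no overlap in the universe are skipped.  q-values are BH-corrected
    within each source tag and filtered at the per-source thresholds unless
    *return_all* is set.
    """
    thresholds = dict(DEFAULT_Q_THRESHOLDS)
    if q_thresholds:
        thresholds.update(q_thresholds)
    universe_set = frozenset(g.upper() for g in universe)
    if not universe_set:
        raise ValueError("universe is empty")
    query = frozenset(g.upper() for g in query_genes) & universe_set
    if not query:
        raise ValueError("query has no genes inside the universe")
    n_universe = len(universe_set)
    n_query = len(query)
    rows = []
    for name, members in gene_sets.items():
        members_in = members & universe_set
        if not members_in:
            continue
        overlap = query & members_in
        if not overlap:
            continue
        p = hypergeometric_upper_tail(
            len(overlap), len(members_in), n_query, n_universe
        )
        rows.append(
            dict(
                term=name,
                source=gene_sets.sources.get(name, "custom"),
                overlap=len(overlap),
                set_size=len(members_in),
                query_size=n_query,
                universe_size=n_universe,
                p_value=p,
                genes=",".join(sorted(overlap)),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term",
            "source",
            "overlap",
            "set_size",
            "query_size",
            "universe_size",
            "p_value",
            "genes",
        ],
    )
    if len(out) == 0:
        out["q_value"] = []
        out["significant"] = []
        return out
    out["q_value"] = np.nan
    for source, group in out.groupby("source"):
        out.loc[group.index, "q_value"] = bh_fdr(group["p_value"])
    out["significant"] = [
        q < thresholds.get(src, 0.05) for q, src in zip(out["q_value"], out["source"])
    ]
    out = out.sort_values(["q_value", "p_value", "term"]).reset_index(drop=True)
    if return_all:
        return out
    return out[out["significant"]].reset_index(drop=True)
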