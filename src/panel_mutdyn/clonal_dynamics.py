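"""Paired pre/post-treatment VAF analysis: clonal dynamics per patient.

For every patient with both a pre- and a post-treatment sample, mutations
are identified across timepoints by their genomic key (chromosome,
position, ref, alt) — never by gene symbol, since two different mutations
in one gene must not be conflated.  A mutation absent at a timepoint
enters the VAF matrix as 0 rather than being dropped: loss and emergence
are the signal of interest.

Mutations are clustered on their (pre-VAF, post-VAF) coordinates by
agglomerative hierarchical clustering with Ward linkage and Euclidean
distance.  The number of clusters is chosen to maximize the mean
silhouette over k in 2..min(6, n-1), falling back to a single cluster
when fewer than four mutations are available or the best silhouette is
below 0.25.  Mutations are sorted by genomic key before clustering, which
together with Ward's deterministic merge order makes the labels
platform-independent.

Each cluster receives a fate relative to a detection threshold (default
VAF 0.05, mirroring the filter cascade's low-VAF floor): *lost* when
every member falls below it after treatment but at least one was
detectable before, *emergent* in the mirror case, *retained* otherwise.
A patient's profile is *changed* when at least one cluster was lost or
emerged, *stable* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .io_formats import POST, PRE, ClinicalRecord, GeneSetCollection, VariantRecord
from .stats_core import ContingencyTable2x2, TestResult, fisher_exact_2x2

__all__ = [
    "PairedPatient",
    "VafClusterResult",
    "build_paired_patients",
    "partition_shared_private",
    "cluster_vafs",
    "classify_cluster_fate",
    "classify_patient_profile",
    "relapse_crosstab",
    "residual_cluster_pathways",
]

DETECTION_THRESHOLD = 0.05


@dataclass
class PairedPatient:
    """All variant calls of one patient keyed by genomic identity."""

    patient_id: str
    pre: dict[tuple, VariantRecord] = field(default_factory=dict)
    post: dict[tuple, VariantRecord] = field(default_factory=dict)

    def vaf_matrix(self) -> pd.DataFrame:
        """Mutation x {PRE, POST} VAF table over the key union; absent = 0.

        Rows are sorted by genomic key (the deterministic clustering order).
        """
        keys = sorted(set(self.pre) | set(self.post))
        return pd.DataFrame(
            {
                "key": keys,
                PRE: [self.pre[k].tumor_vaf if k in self.pre else 0.0 for k in keys],
                POST: [self.post[k].tumor_vaf if k in self.post else 0.0 for k in keys],
                "gene": [(self.pre.get(k) or self.post[k]).gene for k in keys],
            }
        )


@dataclass
class VafClusterResult:
    """Per-patient clustering of mutations over (pre-VAF, post-VAF)."""

    patient_id: str
    k: int
    members: pd.DataFrame  # key, gene, pre_vaf, post_vaf, cluster, fate
    cluster_stats: pd.DataFrame  # cluster, n, mean_pre, mean_post, fate
    profile: str  # stable | changed
    silhouette: float | None


def build_paired_patients(
    records: Sequence[VariantRecord],
    roster: Iterable[tuple[str, str]] | None = None,
    require_both: bool = True,
) -> list[PairedPatient]:
    """Group records into per-patient paired containers, input order ignored.

    Whether a patient counts as paired is decided by the *roster* of
    sequenced (patient_id, timepoint) samples when one is supplied — a
    patient whose post-treatment sample yielded zero surviving calls is
    still paired, with an all-zero post column (total mutation loss).
    Without a roster, pairing falls back to the records themselves.
    """
    patients: dict[str, PairedPatient] = {}
    roster_set = {(p, tp) for p, tp in roster} if roster is not None else None
    if roster_set is not None:
        for pid, _tp in roster_set:
            patients.setdefault(pid, PairedPatient(patient_id=pid))
    for r in records:
        p = patients.setdefault(r.patient_id, PairedPatient(patient_id=r.patient_id))
        side = p.pre if r.timepoint == PRE else p.post
        side[r.key] = r

    def is_paired(p: PairedPatient) -> bool:
        if not require_both:
            return True
        if roster_set is not None:
            return (p.patient_id, PRE) in roster_set and (p.patient_id, POST) in roster_set
        return bool(p.pre) and bool(p.post)

    out = [p for p in patients.values() if is_paired(p) and (p.pre or p.post)]
    return sorted(out, key=lambda p: p.patient_id)


def partition_shared_private(
    pre_variants: Mapping[tuple, VariantRecord] | Iterable,
    post_variants: Mapping[tuple, VariantRecord] | Iterable,
) -> tuple[set, set, set]:
    """Partition the key union into (shared, private_pre, private_post)."""
    pre_keys = set(pre_variants)
    post_keys = set(post_variants)
    shared = pre_keys & post_keys
    return shared, pre_keys - shared, post_keys - shared


def classify_cluster_fate(
    pre_vafs: Sequence[float],
    post_vafs: Sequence[float],
    detection_threshold: float = DETECTION_THRESHOLD,
) -> str:
    """Fate of one cluster: lost, emergent or retained.

    *lost*: every member is undetectable after treatment and at least one
    was detectable before; *emergent*: the mirror image; *retained*:
    everything else.
    """
    pre = np.asarray(list(pre_vafs), dtype=float)
    post = np.asarray(list(post_vafs), dtype=float)
    if pre.size == 0:
        raise ValueError("cluster must be non-empty")
    if np.all(post < detection_threshold) and np.any(pre >= detection_threshold):
        return "lost"
    if np.all(pre < detection_threshold) and np.any(post >= detection_threshold):
        return "emergent"
    return "retained"


def classify_patient_profile(fates: Sequence[str]) -> str:
    """*changed* iff at least one cluster was lost or emergent."""
    if len(fates) == 0:
        raise ValueError("at least one cluster fate is required")
    return "changed" if any(f in ("lost", "emergent") for f in fates) else "stable"


def _choose_k(points: np.ndarray, merges: np.ndarray, k_max: int, silhouette_min: float):
    n = points.shape[0]
    best_k, best_s = 1, None
    for k in range(2, min(k_max, n - 1) + 1):
        labels = fcluster(merges, t=k, criterion="maxclust")
        if np.unique(labels).size < 2:
            continue
        try:
            s = float(silhouette_score(points, labels))
        except ValueError:
            continue
        if best_s is None or s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_s is None or best_s < silhouette_min:
        return 1, None
    return best_k, best_s


def cluster_vafs(
    paired: PairedPatient,
    k_max: int = 6,
    silhouette_min: float = 0.25,
    detection_threshold: float = DETECTION_THRESHOLD,
) -> VafClusterResult:
    """Ward/Euclidean clustering of a patient's mutations over paired VAFs."""
    matrix = paired.vaf_matrix()
    n = len(matrix)
    if n == 0:
        raise ValueError(f"patient {paired.patient_id} has no mutations")
    points = matrix[[PRE, POST]].to_numpy(dtype=float)
    if n >= 4 and np.unique(points, axis=0).shape[0] > 1:
        merges = linkage(points, method="ward", metric="euclidean")
        k, sil = _choose_k(points, merges, k_max, silhouette_min)
        labels = (
            fcluster(merges, t=k, criterion="maxclust") if k > 1 else np.ones(n, dtype=int)
        )
    else:
        k, sil = 1, None
        labels = np.ones(n, dtype=int)

    members = matrix.reset_index().rename(columns={PRE: "pre_vaf", POST: "post_vaf"})
    members["cluster"] = labels

    # canonical cluster ids: C1..Ck by decreasing size, then decreasing mean
    # pre-VAF, then smallest member key
    stats = []
    for label, group in members.groupby("cluster"):
        stats.append(
            (
                label,
                len(group),
                float(group["pre_vaf"].mean()),
                float(group["post_vaf"].mean()),
                tuple(group["key"].min()),
            )
        )
    stats.sort(key=lambda s: (-s[1], -s[2], s[4]))
    relabel = {old: i + 1 for i, (old, *_rest) in enumerate(stats)}
    members["cluster"] = members["cluster"].map(relabel)

    fates = {}
    rows = []
    for label, group in members.groupby("cluster"):
        fate = classify_cluster_fate(
            group["pre_vaf"], group["post_vaf"], detection_threshold
        )
        fates[label] = fate
        rows.append(
            dict(
                cluster=int(label),
                n=len(group),
                mean_pre=float(group["pre_vaf"].mean()),
                mean_post=float(group["post_vaf"].mean()),
                fate=fate,
            )
        )
    members["fate"] = members["cluster"].map(fates)
    cluster_stats = pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
    profile = classify_patient_profile(cluster_stats["fate"].tolist())
    k_final = int(cluster_stats.shape[0])
    return VafClusterResult(
        patient_id=paired.patient_id,
        k=k_final,
        members=members,
        cluster_stats=cluster_stats,
        profile=profile,
        silhouette=sil,
    )


def relapse_crosstab(
    profiles: Mapping[str, str],
    clinical: Sequence[ClinicalRecord],
) -> tuple[ContingencyTable2x2, TestResult, list[str]]:
    """2x2 stable/changed x relapse yes/no cross-tab with Fisher's exact test.

    Patients without a relapse label are excluded and listed.  Table rows
    are (stable, changed), columns (relapsed, relapse-free).
    """
    if not profiles:
        raise ValueError("no patient profiles supplied")
    relapse = {c.patient_id: c.relapse for c in clinical}
    counts = {("stable", True): 0, ("stable", False): 0, ("changed", True): 0, ("changed", False): 0}
    excluded: list[str] = []
    for pid, profile in profiles.items():
        flag = relapse.get(pid)
        if flag is None:
            excluded.append(pid)
            continue
        counts[(profile, bool(flag))] += 1
    table = ContingencyTable2x2(
        a=counts[("stable", True)],
        b=counts[("stable", False)],
        c=counts[("changed", True)],
        d=counts[("changed", False)],
    )
    return table, fisher_exact_2x2(table), excluded


def residual_cluster_pathways(
    result: VafClusterResult,
    gene_sets: GeneSetCollection,
    universe: Iterable[str],
    detection_threshold: float = DETECTION_THRESHOLD,
    q_thresholds: Mapping[str, float] | None = None,
) -> dict[int, pd.DataFrame | None]:
    """Gene-set enrichment of each cluster's genes still mutated post-treatment.

    Clusters with no member detectable after treatment report ``None``
    (not applicable).  Enrichment is delegated to
    :func:`panel_mutdyn.cooccurrence_network.enrich`.
    """
    from .cooccurrence_network import enrich  # local import: avoid cycle

    universe_set = frozenset(g.upper() for g in universe)
    out: dict[int, pd.DataFrame | None] = {}
    for label, group in result.members.groupby("cluster"):
        genes = sorted(set(group.loc[group["post_vaf"] >= detection_threshold, "gene"]))
        if not genes:
            out[int(label)] = None
            continue
        if not set(g.upper() for g in genes) & universe_set:
            out[int(label)] = pd.DataFrame(
                columns=["term", "source", "overlap", "set_size", "query_size",
                         "universe_size", "p_value", "genes", "q_value", "significant"]
            )
            continue
        out[int(label)] = enrich(
            genes, gene_sets, universe_set, q_thresholds=q_thresholds
        )
    return out
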