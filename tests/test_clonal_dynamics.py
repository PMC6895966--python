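"""Paired VAF clustering, fates, profiles and the relapse cross-tab."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage

import oracles
from conftest import make_record
from panel_mutdyn.io_formats import ClinicalRecord, GeneSetCollection, POST, PRE
from panel_mutdyn.clonal_dynamics import (
    PairedPatient,
    build_paired_patients,
    classify_cluster_fate,
    classify_patient_profile,
    cluster_vafs,
    partition_shared_private,
    relapse_crosstab,
    residual_cluster_pathways,
)


def paired_from_points(points, genes=None):
    """Build a PairedPatient whose mutations sit at given (pre, post) VAFs."""
    patient = PairedPatient(patient_id="pX")
    for i, (pre, post) in enumerate(points):
        gene = genes[i] if genes else f"G{i:02d}"
        common = dict(gene=gene, position=1000 + i, chromosome="chr1")
        if pre > 0:
            depth = 1000
            r = make_record(
                sample_id="pX_PRE", timepoint=PRE, tumor_depth=depth,
                tumor_alt_reads=round(pre * depth), tumor_vaf=None, **common,
            )
            patient.pre[r.key] = r
        if post > 0:
            depth = 1000
            r = make_record(
                sample_id="pX_POST", timepoint=POST, tumor_depth=depth,
                tumor_alt_reads=round(post * depth), tumor_vaf=None, **common,
            )
            patient.post[r.key] = r
    return patient


class TestPartition:
    def test_identical_sets_all_shared(self):
        keys = {("chr1", 1, "A", "C"), ("chr1", 2, "A", "C")}
        shared, pre_only, post_only = partition_shared_private(keys, set(keys))
        assert shared == keys and not pre_only and not post_only

    def test_disjoint_sets(self):
        shared, pre_only, post_only = partition_shared_private({"a", "b"}, {"c"})
        assert shared == set() and pre_only == {"a", "b"} and post_only == {"c"}

    def test_partition_identities_random(self, rng):
        universe = [f"k{i}" for i in range(30)]
        for _ in range(500):
            pre = set(rng.choice(universe, size=int(rng.integers(0, 20)), replace=False))
            post = set(rng.choice(universe, size=int(rng.integers(0, 20)), replace=False))
            shared, pre_only, post_only = partition_shared_private(pre, post)
            assert shared | pre_only == pre
            assert shared | post_only == post
            assert not (pre_only & post_only)
            assert len(shared) + len(pre_only) == len(pre)
            assert len(shared) + len(post_only) == len(post)


class TestFates:
    def test_lost(self):
        assert classify_cluster_fate([0.4, 0.3], [0.0, 0.02]) == "lost"

    def test_emergent(self):
        assert classify_cluster_fate([0.0], [0.3]) == "emergent"

    def test_retained(self):
        assert classify_cluster_fate([0.3], [0.3]) == "retained"

    def test_subthreshold_everywhere_is_retained(self):
        assert classify_cluster_fate([0.02, 0.03], [0.0, 0.01]) == "retained"

    def test_profile_rule(self):
        assert classify_patient_profile(["retained", "retained"]) == "stable"
        assert classify_patient_profile(["retained", "lost", "retained"]) == "changed"
        with pytest.raises(ValueError):
            classify_patient_profile([])


class TestClustering:
    def test_two_mutations_fall_back_to_single_cluster(self):
        result = cluster_vafs(paired_from_points([(0.3, 0.3), (0.1, 0.1)]))
        assert result.k == 1 and result.silhouette is None

    def test_empty_patient_rejected(self):
        with pytest.raises(ValueError):
            cluster_vafs(PairedPatient(patient_id="void"))

    def test_planted_two_clusters_recovered_exactly(self, rng):
        centers = [(0.5, 0.5), (0.4, 0.0)]
        points, labels = [], []
        for label, (cx, cy) in enumerate(centers):
            for _ in range(5):
                points.append(
                    (
                        float(np.clip(cx + rng.normal(0, 0.02), 0.01, 1)),
                        float(np.clip(cy + rng.normal(0, 0.02), 0, 1)),
                    )
                )
                labels.append(label)
        result = cluster_vafs(paired_from_points(points))
        assert result.k == 2
        # rows are key-sorted, and positions were assigned in point order, so
        # the planted partition is the first five rows vs the last five
        found = result.members["cluster"].to_numpy()
        split = {tuple(sorted(np.flatnonzero(found == c))) for c in (1, 2)}
        assert split == {tuple(range(5)), tuple(range(5, 10))}

    def test_lost_cluster_detected_and_profile_changed(self):
        points = [(0.42, 0.0), (0.40, 0.02), (0.41, 0.01), (0.30, 0.31), (0.29, 0.30)]
        result = cluster_vafs(paired_from_points(points))
        fates = set(result.cluster_stats["fate"])
        assert "lost" in fates and result.profile == "changed"

    def test_ward_merges_match_exhaustive_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 9))
            points = rng.random((n, 2))
            ours = sorted(linkage(points, method="ward")[:, 2])
            reference = sorted(oracles.ward_merge_heights(points))
            assert np.allclose(ours, reference, rtol=1e-8)

    def test_deterministic_given_input(self):
        points = [(0.3, 0.3), (0.28, 0.33), (0.1, 0.0), (0.12, 0.02), (0.0, 0.2)]
        a = cluster_vafs(paired_from_points(points))
        b = cluster_vafs(paired_from_points(points))
        assert a.members.equals(b.members) and a.k == b.k

    def test_merge_order_invariant_under_common_scaling(self):
        points = np.random.default_rng(5).random((7, 2))
        h1 = linkage(points, method="ward")[:, [0, 1]]
        h2 = linkage(points * 0.37, method="ward")[:, [0, 1]]
        assert np.array_equal(h1, h2)


class TestCrosstab:
    def test_published_counts_layout(self):
        profiles = {f"s{i}": "stable" for i in range(4)}
        profiles.update({f"c{i}": "changed" for i in range(8)})
        clinical = [
            ClinicalRecord(patient_id=p, response="RD", relapse=(p.startswith("s") or p in ("c0", "c1", "c2")))
            for p in profiles
        ]
        table, test, excluded = relapse_crosstab(profiles, clinical)
        assert (table.a, table.b, table.c, table.d) == (4, 0, 3, 5)
        assert excluded == []
        assert 0 < test.p_value <= 1

    def test_missing_relapse_listed_and_excluded(self):
        profiles = {"p1": "stable", "p2": "changed"}
        clinical = [
            ClinicalRecord(patient_id="p1", response="RD", relapse=True),
            ClinicalRecord(patient_id="p2", response="RD"),
        ]
        table, _test, excluded = relapse_crosstab(profiles, clinical)
        assert excluded == ["p2"]
        assert table.a + table.b + table.c + table.d == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            relapse_crosstab({}, [])

    def test_permuted_labels_type_i_control(self, rng):
        profiles = {f"p{i}": ("stable" if i < 5 else "changed") for i in range(12)}
        relapse_base = [True] * 6 + [False] * 6
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            relapse = rng.permutation(relapse_base)
            clinical = [
                ClinicalRecord(patient_id=f"p{i}", response="RD", relapse=bool(relapse[i]))
                for i in range(12)
            ]
            _table, test, _ = relapse_crosstab(profiles, clinical)
            hits += test.p_value < 0.05
        # Fisher on n=12 is conservative: stay at or below the upper 99%
        # binomial envelope of a nominal-0.05 test
        upper = 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / n_perm)
        assert hits / n_perm <= upper


class TestResidualPathways:
    def make_result(self, points, genes):
        return cluster_vafs(paired_from_points(points, genes=genes))

    def test_cluster_without_post_mutations_is_na(self):
        sets = GeneSetCollection(sets={"S": frozenset({"G00"})}, sources={"S": "KEGG"})
        result = self.make_result([(0.4, 0.0), (0.42, 0.0)], ["G00", "G01"])
        out = residual_cluster_pathways(result, sets, universe=["G00", "G01"])
        assert all(v is None for v in out.values())

    def test_full_set_overlap_closed_form(self):
        genes = [f"G{i:02d}" for i in range(5)]
        universe = [f"G{i:02d}" for i in range(10)]
        sets = GeneSetCollection(
            sets={"S": frozenset(genes)}, sources={"S": "KEGG"}
        )
        result = self.make_result([(0.3, 0.3)] * 5, genes)
        out = residual_cluster_pathways(result, sets, universe=universe)
        frame = out[1]
        assert frame.iloc[0]["p_value"] == pytest.approx(1 / 252, rel=1e-9)

    def test_genes_outside_all_sets_yield_empty(self):
        sets = GeneSetCollection(sets={"S": frozenset({"ZZZ"})}, sources={"S": "GO"})
        result = self.make_result([(0.3, 0.3), (0.31, 0.29)], ["G00", "G01"])
        out = residual_cluster_pathways(result, sets, universe=["G00", "G01", "ZZZ"])
        assert len(out[1]) == 0


class TestBuildPaired:
    def test_roster_pairs_patient_with_empty_post(self):
        records = [make_record(patient_id="q1", sample_id="q1_PRE", timepoint=PRE)]
        roster = [("q1", PRE), ("q1", POST)]
        (patient,) = build_paired_patients(records, roster=roster)
        assert patient.post == {}
        matrix = patient.vaf_matrix()
        assert (matrix[POST] == 0).all()

    def test_without_roster_requires_both_timepoints(self):
        records = [make_record(patient_id="q1", sample_id="q1_PRE", timepoint=PRE)]
        assert build_paired_patients(records) == []
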