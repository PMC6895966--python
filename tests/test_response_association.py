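"""Binarization, pathway roll-up and Fisher response association."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_record
from panel_mutdyn.io_formats import GeneSetCollection
from panel_mutdyn.response_association import (
    binarize,
    feature_response_association,
    pathway_status,
    select_rd_enriched,
)


def records_for(sample_genes):
    records, pos = [], 1
    for sample, genes in sample_genes.items():
        for gene in genes:
            records.append(make_record(sample_id=sample, gene=gene, position=pos))
            pos += 1
    return records


def gene_sets(mapping, source="custom"):
    collection = GeneSetCollection()
    for name, genes in mapping.items():
        collection.sets[name] = frozenset(genes)
        collection.sources[name] = source
    return collection


class TestBinarize:
    def test_empty_sample_is_zero_column(self):
        matrix = binarize(records_for({"s1": ["TP53"]}), ["s1", "s2"])
        assert matrix["s2"].sum() == 0

    def test_multiple_hits_collapse_to_one(self):
        records = [make_record(sample_id="s1", gene="TP53", position=p) for p in (1, 2, 3)]
        matrix = binarize(records, ["s1"])
        assert matrix.loc["TP53", "s1"] == 1

    def test_low_impact_ignored(self):
        records = [make_record(variant_classification="Silent", gene="KRAS", position=9)]
        matrix = binarize(records, ["p1_PRE"])
        assert "KRAS" not in matrix.index

    def test_column_sums_equal_mutated_gene_counts(self):
        layout = {"s1": ["TP53", "KRAS"], "s2": ["TP53"], "s3": []}
        matrix = binarize(records_for(layout), list(layout))
        for sample, genes in layout.items():
            assert matrix[sample].sum() == len(genes)


class TestPathwayStatus:
    def test_single_gene_pathway(self):
        matrix = binarize(records_for({"s1": ["TP53"]}), ["s1"])
        pmat, dropped = pathway_status(matrix, gene_sets({"P_TP53": ["TP53"]}))
        assert pmat.loc["P_TP53", "s1"] == 1 and dropped == []

    def test_pathway_without_panel_genes_dropped(self):
        matrix = binarize(records_for({"s1": ["TP53"]}), ["s1"])
        pmat, dropped = pathway_status(matrix, gene_sets({"P_NONE": ["BRAF"]}))
        assert dropped == ["P_NONE"] and len(pmat) == 0

    def test_equals_bruteforce_or(self, rng):
        genes = [f"G{i}" for i in range(12)]
        matrix = pd.DataFrame(
            rng.integers(0, 2, (12, 8)), index=genes, columns=[f"s{j}" for j in range(8)]
        )
        matrix.attrs["scope"] = "gene"
        sets = {
            f"P{k}": rng.choice(genes, size=int(rng.integers(1, 6)), replace=False).tolist()
            for k in range(10)
        }
        pmat, _ = pathway_status(matrix, gene_sets(sets))
        for name, members in sets.items():
            for sample in matrix.columns:
                expected = int(any(matrix.loc[g, sample] for g in members))
                assert pmat.loc[name, sample] == expected

    def test_monotone_in_mutations(self):
        matrix = binarize(records_for({"s1": ["TP53"], "s2": []}), ["s1", "s2"])
        sets = gene_sets({"P": ["TP53", "KRAS"]})
        before, _ = pathway_status(matrix, sets)
        more = binarize(records_for({"s1": ["TP53", "KRAS"], "s2": ["KRAS"]}), ["s1", "s2"])
        after, _ = pathway_status(more, sets)
        assert (after.loc["P"] >= before.loc["P"]).all()

    def test_empty_collection_rejected(self):
        matrix = binarize(records_for({"s1": ["TP53"]}), ["s1"])
        with pytest.raises(ValueError):
            pathway_status(matrix, GeneSetCollection())


class TestAssociation:
    def test_perfect_separation_exact_p(self):
        samples = [f"s{i}" for i in range(10)]
        labels = {s: ("RD" if i < 6 else "pCR") for i, s in enumerate(samples)}
        matrix = pd.DataFrame(
            [[1] * 6 + [0] * 4], index=["GENE"], columns=samples
        )
        result = feature_response_association(matrix, labels)
        row = result.iloc[0]
        assert (row.mutated_rd, row.mutated_pcr, row.wildtype_rd, row.wildtype_pcr) == (6, 0, 0, 4)
        assert row.p_value == pytest.approx(1 / 210, rel=1e-9)  # 1 / C(10,6)

    def test_constant_feature_flagged(self):
        samples = ["a", "b", "c", "d"]
        labels = {"a": "RD", "b": "RD", "c": "pCR", "d": "pCR"}
        matrix = pd.DataFrame([[1, 1, 1, 1], [0, 0, 0, 0]], index=["X", "Y"], columns=samples)
        result = feature_response_association(matrix, labels).set_index("feature")
        assert not result.loc["X", "informative"] and result.loc["X", "p_value"] == 1.0
        assert not result.loc["Y", "informative"]

    def test_single_class_labels_rejected(self):
        matrix = pd.DataFrame([[1, 0]], index=["X"], columns=["a", "b"])
        with pytest.raises(ValueError):
            feature_response_association(matrix, {"a": "RD", "b": "RD"})

    def test_sample_order_permutation_invariance(self, rng):
        samples = [f"s{i}" for i in range(8)]
        labels = {s: ("RD" if i % 2 else "pCR") for i, s in enumerate(samples)}
        matrix = pd.DataFrame(
            rng.integers(0, 2, (5, 8)), index=[f"G{i}" for i in range(5)], columns=samples
        )
        base = feature_response_association(matrix, labels).set_index("feature")["p_value"]
        perm = feature_response_association(
            matrix[rng.permutation(samples)], labels
        ).set_index("feature")["p_value"]
        assert np.allclose(base, perm)

    def test_planted_pathway_effect_detected(self):
        # mutated in 90% of RD / 10% of pCR, n = 40 samples, 100 replicates
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(40)]
        labels = {s: ("RD" if i < 20 else "pCR") for i, s in enumerate(samples)}
        qs = []
        for _ in range(100):
            planted = np.concatenate(
                [rng.random(20) < 0.9, rng.random(20) < 0.1]
            ).astype(int)
            noise = rng.integers(0, 2, (9, 40))
            matrix = pd.DataFrame(
                np.vstack([planted, noise]),
                index=["PLANTED"] + [f"N{i}" for i in range(9)],
                columns=samples,
            )
            result = feature_response_association(matrix, labels).set_index("feature")
            qs.append(result.loc["PLANTED", "q_value"])
        assert np.median(qs) < 0.05


class TestSelection:
    def test_rd_enriched_reporting_rule(self):
        samples = ["r1", "r2", "r3", "c1"]
        labels = {"r1": "RD", "r2": "RD", "r3": "RD", "c1": "pCR"}
        matrix = pd.DataFrame(
            [[1, 1, 1, 0], [1, 1, 1, 1], [1, 0, 0, 0]],
            index=["HIT", "TOO_COMMON", "TOO_RARE"],
            columns=samples,
        )
        assert select_rd_enriched(matrix, labels) == ["HIT"]
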