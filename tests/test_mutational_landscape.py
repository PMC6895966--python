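"""Burden, spectrum and recurrent-gene summaries."""

import numpy as np
import pytest

from conftest import make_record
from panel_mutdyn import SimulationConfig, apply_filter_cascade, simulate_cohort
from panel_mutdyn.mutational_landscape import (
    compare_burden,
    mutation_burden,
    recurrent_genes,
    spectrum_summary,
)


def sample_records():
    return [
        make_record(position=1),
        make_record(position=2, variant_classification="Nonsense_Mutation"),
        make_record(position=3, variant_classification="Missense_Mutation"),
        make_record(position=4, variant_classification="Silent"),
    ]


class TestBurden:
    def test_direct_counts(self):
        burden = mutation_burden(sample_records(), scope="high_moderate")
        row = burden.iloc[0]
        assert row.n_mutations_high_moderate == 3 and row.n_mutations_all == 4
        assert row.n_mutations == 3

    def test_roster_keeps_empty_samples(self):
        burden = mutation_burden(
            sample_records(), roster=[("p1_PRE", "PRE"), ("p9_PRE", "PRE")]
        )
        empty = burden.set_index("sample_id").loc["p9_PRE"]
        assert empty.n_mutations_all == 0

    def test_duplicate_key_counts_once(self):
        records = [make_record(position=1), make_record(position=1)]
        assert mutation_burden(records).iloc[0].n_mutations_all == 1

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError):
            mutation_burden([], scope="everything")

    def test_counts_match_generator_truth(self):
        cohort = simulate_cohort(SimulationConfig(n_patients=12, seed=42))
        passed, outcomes = apply_filter_cascade(cohort.variants)
        burden = mutation_burden(passed, scope="all").set_index("sample_id")
        kept = {
            (o.sample_id, ":".join(map(str, o.key))) for o in outcomes if o.passed
        }
        truth_counts = (
            cohort.truth[
                [(s, k) in kept for s, k in zip(cohort.truth.sample_id, cohort.truth.key)]
            ]
            .groupby("sample_id")["key"]
            .nunique()
        )
        for sample_id, count in truth_counts.items():
            assert burden.loc[sample_id].n_mutations_all == count


class TestRecurrentGenes:
    def test_universal_gene_ranked_first_with_ones(self):
        records = [
            make_record(sample_id=s, gene=g, position=p)
            for s, genes in [("s1", ["TP53", "KRAS"]), ("s2", ["TP53"]), ("s3", ["TP53"])]
            for p, g in enumerate(genes, start=1)
        ]
        matrix = recurrent_genes(records, top_n=5)
        assert matrix.index[0] == "TP53"
        assert matrix.loc["TP53"].tolist() == [1, 1, 1]

    def test_equal_frequency_breaks_alphabetically(self):
        records = [
            make_record(sample_id="s1", gene="ZZZ3", position=1),
            make_record(sample_id="s1", gene="AAA1", position=2),
        ]
        matrix = recurrent_genes(records, top_n=2)
        assert matrix.index.tolist() == ["AAA1", "ZZZ3"]

    def test_planted_driver_recovered_first(self):
        cohort = simulate_cohort(SimulationConfig(n_patients=30, seed=42))
        passed, _ = apply_filter_cascade(cohort.variants)
        pre = [r for r in passed if r.timepoint == "PRE"]
        matrix = recurrent_genes(pre, top_n=10)
        assert matrix.index[0] == "TP53"
        assert matrix.loc["TP53"].mean() > 0.5

    def test_order_invariant_under_input_permutation(self, rng):
        records = [
            make_record(sample_id=f"s{i%4}", gene=g, position=p)
            for p, (i, g) in enumerate(
                [(i, g) for i in range(4) for g in ("TP53", "KRAS", "EGFR")], start=1
            )
        ]
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert recurrent_genes(records, 3).equals(recurrent_genes(shuffled, 3))


class TestSpectrum:
    def test_type_groups(self):
        types, classes = spectrum_summary(
            [
                make_record(position=1),
                make_record(position=2),
                make_record(position=3, variant_classification="Nonsense_Mutation"),
            ]
        )
        assert types["missense"] == 2 and types["truncating"] == 1
        assert types["splice"] == 0 and types["other"] == 0

    def test_substitution_counts_sum_to_snvs(self):
        records = [
            make_record(position=1, ref_allele="C", alt_allele="T",
                        tumor_depth=800, tumor_alt_reads=400, tumor_vaf=None),
            make_record(position=2),
            make_record(position=3, ref_allele="AT", alt_allele="A",
                        variant_type="DEL"),
        ]
        _, classes = spectrum_summary(records)
        n_snv = sum(1 for r in records if len(r.ref_allele) == len(r.alt_allele) == 1)
        assert sum(classes.values()) == n_snv == 2

    def test_uniform_classes_without_ffpe_injection(self):
        cfg = SimulationConfig(n_patients=40, ffpe_artifact_rate=0.0,
                               germline_rate=0.0, seed=13)
        cohort = simulate_cohort(cfg)
        _, classes = spectrum_summary(cohort.variants)
        counts = np.array(list(classes.values()))
        total = counts.sum()
        # multinomial 99% band around the uniform expectation
        p = 1 / 6
        se = np.sqrt(total * p * (1 - p))
        assert np.all(np.abs(counts - total * p) <= 2.81 * se + 1)


class TestCompareBurden:
    def test_identical_groups(self):
        burden = mutation_burden(
            [make_record(sample_id=s, position=i) for i, s in enumerate(["a", "b"], 1)]
        )
        result = compare_burden(burden, {"a": "g1", "b": "g2"})
        assert result["test"].p_value == pytest.approx(1.0)

    def test_separated_groups_exact_p(self):
        records = []
        pos = 1
        for sample, count in [("a", 1), ("b", 2), ("c", 3), ("d", 10), ("e", 11), ("f", 12)]:
            for _ in range(count):
                records.append(make_record(sample_id=sample, position=pos))
                pos += 1
        burden = mutation_burden(records, scope="all")
        grouping = {s: ("young" if s in "abc" else "old") for s in "abcdef"}
        result = compare_burden(burden, grouping, scope_column="n_mutations_all")
        assert result["test"].p_value == pytest.approx(0.1)
        assert result["summary"]["young"]["median"] == 2

    def test_more_than_two_groups_rejected(self):
        burden = mutation_burden(
            [make_record(sample_id=s, position=i) for i, s in enumerate("abc", 1)]
        )
        with pytest.raises(ValueError):
            compare_burden(burden, {"a": "x", "b": "y", "c": "z"})

    def test_planted_burden_shift_detected(self):
        # Poisson(4) vs Poisson(12), n = 10 per group: power well above 90%
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            low, high = rng.poisson(4, 10), rng.poisson(12, 10)
            from panel_mutdyn.stats_core import wilcoxon_rank_sum

            if wilcoxon_rank_sum(low, high).p_value < 0.05:
                hits += 1
        assert hits >= 90
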