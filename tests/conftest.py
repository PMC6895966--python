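"""Shared fixtures: record factories and boundary-rich random variant draws."""

from __future__ import annotations

import numpy as np
import pytest

from panel_mutdyn.io_formats import VariantRecord

# boundary-heavy pools for the filter cascade
_PHRED = [None, 20.0, 29.9, 30.0, 31.0, 60.0, 95.0]
_STRAND = [None, 0.001, 0.0099, 0.01, 0.02, 0.5, 1.0]
_DEPTH = [40, 120, 499, 500, 501, 800, 1500]
_VAF = [0.005, 0.02, 0.049, 0.05, 0.051, 0.08, 0.099, 0.1, 0.101, 0.2, 0.45]
_NDEPTH = [None, 4, 9, 10, 11, 300, 800]
_NVAF = [None, 0.0, 0.01, 0.05, 0.099, 0.1, 0.101, 0.4]
_POP = [None, 0.0, 0.005, 0.0099, 0.01, 0.011, 0.2]
_ALLELES = [
    ("C", "T"), ("G", "A"), ("C", "A"), ("G", "T"), ("T", "C"), ("A", "G"),
    ("T", "A"), ("C", "G"), ("AT", "A"), ("A", "AG"),
]


def make_record(**overrides) -> VariantRecord:
    """A clean, unambiguously passing variant record; override fields at will."""
    fields = dict(
        patient_id="p1",
        sample_id="p1_PRE",
        timepoint="PRE",
        gene="TP53",
        chromosome="chr17",
        position=7_577_120,
        ref_allele="A",
        alt_allele="C",
        variant_type="SNV",
        variant_classification="Missense_Mutation",
        tumor_depth=800,
        tumor_alt_reads=160,
        phred_quality=90.0,
        strand_bias_p=0.5,
        normal_depth=600,
        normal_vaf=0.0,
        dbsnp_member=False,
        pop_af_1kg_eur=None,
        pop_af_exac_nfe=None,
    )
    fields.update(overrides)
    return VariantRecord(**fields)


def random_boundary_records(rng: np.random.Generator, n: int) -> list[VariantRecord]:
    """Random records whose fields are drawn from boundary-heavy pools."""

    def pick(pool):
        return pool[int(rng.integers(len(pool)))]

    records = []
    for i in range(n):
        depth = pick(_DEPTH)
        vaf = pick(_VAF)
        alt = min(depth, round(vaf * depth))
        ref, alt_allele = _ALLELES[int(rng.integers(len(_ALLELES)))]
        records.append(
            make_record(
                position=1000 + i,
                ref_allele=ref,
                alt_allele=alt_allele,
                variant_type="SNV" if len(ref) == len(alt_allele) == 1 else "DEL",
                tumor_depth=depth,
                tumor_alt_reads=alt,
                tumor_vaf=None,
                phred_quality=pick(_PHRED),
                strand_bias_p=pick(_STRAND),
                normal_depth=pick(_NDEPTH),
                normal_vaf=pick(_NVAF),
                dbsnp_member=pick([None, True, False]),
                pop_af_1kg_eur=pick(_POP),
                pop_af_exac_nfe=pick(_POP),
            )
        )
    return records


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
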