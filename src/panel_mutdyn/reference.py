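"""Bundled 19-patient example cohort (synthetic clinical sheet).

A small TNBC neoadjuvant-chemotherapy series constructed to match typical
published cohort-level marginals — 4/19 pCR, 7/19 relapses, 16 pre- and 15
post-treatment samples evaluable, 12 paired — so documentation examples
and cohort-arithmetic checks have a concrete input.  Individual rows are
synthetic: they reproduce marginal counts, not real patients.

Layout: patients r01-r04 achieved pCR (pre-treatment sample only, by
design no residual tumor to sequence); r05-r07 had inadequate
pre-treatment DNA (post only); r08-r19 are fully paired.  Among the twelve
paired patients four carried a stable clonal profile through therapy (all
four relapsed) and eight a changed one (three relapsed).
"""

from __future__ import annotations

import pandas as pd

from .io_formats import ClinicalRecord

__all__ = [
    "example_clinical",
    "example_evaluability",
    "example_profiles",
]

# patient_id, age, response, relapse, stage, grade, pre_evaluable, post_evaluable
_ROWS = [
    ("r01", 38, "pCR", False, "IIA", "G3", True, False),
    ("r02", 45, "pCR", False, "IIB", "G3", True, False),
    ("r03", 41, "pCR", False, "IIB", "G3", True, False),
    ("r04", 52, "pCR", False, "IIA", "G3", True, False),
    ("r05", 33, "RD", False, "IIB", "G3", False, True),
    ("r06", 47, "RD", False, "IIIA", "G3", False, True),
    ("r07", 58, "RD", False, "IIB", "G2", False, True),
    ("r08", 36, "RD", True, "IIA", "G3", True, True),   # stable
    ("r09", 44, "RD", True, "IIB", "G3", True, True),   # stable
    ("r10", 39, "RD", True, "IIB", "G3", True, True),   # stable
    ("r11", 61, "RD", True, "IIIC", "G3", True, True),  # stable
    ("r12", 43, "RD", True, "IIB", "G3", True, True),   # changed
    ("r13", 35, "RD", True, "IIA", "G3", True, True),   # changed
    ("r14", 49, "RD", True, "IIB", "G3", True, True),   # changed
    ("r15", 55, "RD", False, "IIIA", "G3", True, True),  # changed
    ("r16", 42, "RD", False, "IIB", "G3", True, True),  # changed
    ("r17", 37, "RD", False, "IIA", "G3", True, True),  # changed
    ("r18", 68, "RD", False, "IIB", "G3", True, True),  # changed
    ("r19", 46, "RD", False, "IIIB", "G3", True, True),  # changed
]

_STABLE = ("r08", "r09", "r10", "r11")


def example_clinical() -> list[ClinicalRecord]:
    """The 19 clinical records of the bundled example cohort."""
    return [
        ClinicalRecord(
            patient_id=pid,
            age_years=age,
            response=response,
            relapse=relapse,
            stage=stage,
            grade=grade,
        )
        for pid, age, response, relapse, stage, grade, _pre, _post in _ROWS
    ]


def example_evaluability() -> pd.DataFrame:
    """Per-patient sequencing evaluability flags of the example cohort."""
    return pd.DataFrame(
        [
            dict(patient_id=pid, pre_evaluable=pre, post_evaluable=post)
            for pid, _age, _resp, _rel, _st, _gr, pre, post in _ROWS
        ]
    )


def example_profiles() -> dict[str, str]:
    """Clonal-profile calls (stable/changed) for the twelve paired patients."""
    out = {}
    for pid, _age, _resp, _rel, _st, _gr, pre, post in _ROWS:
        if pre and post:
            out[pid] = "stable" if pid in _STABLE else "changed"
    return out
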