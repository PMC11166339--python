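"""Charlson Comorbidity Index from ICD-10 coded claims diagnoses.

Uses the Quan et al. (2005) ICD-10 coding algorithm for the 17 Charlson
comorbidity categories with the original Charlson weights. Categories are
detected by stem (prefix) matching on normalised codes; within the three
severity pairs (diabetes with/without complications, mild vs moderate or
severe liver disease, malignancy vs metastatic solid tumour) only the more
severe member contributes when both are coded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bundle import ClaimsBundle, month_to_index


def _span(prefix: str, lo: int, hi: int) -> list[str]:
    return [f"{prefix}{i:02d}" for i in range(lo, hi + 1)]


#: category -> (weight, ICD-10 stem list), Quan 2005 coding.
CHARLSON_CATEGORIES: dict[str, tuple[int, list[str]]] = {
    "myocardial_infarction": (1, ["I21", "I22", "I252"]),
    "congestive_heart_failure": (
        1,
        ["I099", "I110", "I130", "I132", "I255", "I420", "I425", "I426", "I427",
         "I428", "I429", "I43", "I50", "P290"],
    ),
    "peripheral_vascular": (
        1,
        ["I70", "I71", "I731", "I738", "I739", "I771", "I790", "I792", "K551",
         "K558", "K559", "Z958", "Z959"],
    ),
    "cerebrovascular": (1, ["G45", "G46", "H340"] + _span("I", 60, 69)),
    "dementia": (1, ["F00", "F01", "F02", "F03", "F051", "G30", "G311"]),
    "chronic_pulmonary": (
        1,
        ["I278", "I279", "J684", "J701", "J703"] + _span("J", 40, 47) + _span("J", 60, 67),
    ),
    "rheumatic": (
        1,
        ["M05", "M06", "M315", "M32", "M33", "M34", "M351", "M353", "M360"],
    ),
    "peptic_ulcer": (1, ["K25", "K26", "K27", "K28"]),
    "mild_liver": (
        1,
        ["B18", "K700", "K701", "K702", "K703", "K709", "K713", "K714", "K715",
         "K717", "K73", "K74", "K760", "K762", "K763", "K764", "K768", "K769", "Z944"],
    ),
    "diabetes_uncomplicated": (
        1,
        [f"E{b}{s}" for b in (10, 11, 12, 13, 14) for s in (0, 1, 6, 8, 9)],
    ),
    "diabetes_complicated": (
        2,
        [f"E{b}{s}" for b in (10, 11, 12, 13, 14) for s in (2, 3, 4, 5, 7)],
    ),
    "hemiplegia": (
        2,
        ["G041", "G114", "G801", "G802", "G81", "G82", "G830", "G831", "G832",
         "G833", "G834", "G839"],
    ),
    "renal": (
        2,
        ["I120", "I131", "N18", "N19", "N250", "Z490", "Z491", "Z492", "Z940", "Z992"]
        + [f"N03{s}" for s in range(2, 8)]
        + [f"N05{s}" for s in range(2, 8)],
    ),
    "malignancy": (
        2,
        _span("C", 0, 26) + _span("C", 30, 34) + _span("C", 37, 41) + ["C43"]
        + _span("C", 45, 58) + _span("C", 60, 76) + ["C81", "C82", "C83", "C84",
        "C85", "C88", "C90", "C91", "C92", "C93", "C94", "C95", "C96", "C97"],
    ),
    "moderate_severe_liver": (
        3,
        ["I850", "I859", "I864", "I982", "K704", "K711", "K721", "K729", "K765",
         "K766", "K767"],
    ),
    "metastatic_solid_tumour": (6, ["C77", "C78", "C79", "C80"]),
    "aids_hiv": (6, ["B20", "B21", "B22", "B24"]),
}

#: (milder, more severe) pairs: the milder is suppressed when both present.
_HIERARCHY = [
    ("diabetes_uncomplicated", "diabetes_complicated"),
    ("mild_liver", "moderate_severe_liver"),
    ("malignancy", "metastatic_solid_tumour"),
]


def charlson_categories(codes: list[str] | set[str]) -> set[str]:
    """Comorbidity categories present in a set of normalised ICD-10 codes."""
    present = set()
    for name, (_, stems) in CHARLSON_CATEGORIES.items():
        for code in codes:
            if any(code.startswith(s) for s in stems):
                present.add(name)
                break
    for milder, severe in _HIERARCHY:
        if severe in present:
            present.discard(milder)
    return present


def charlson_score(codes: list[str] | set[str]) -> int:
    """Weighted Charlson index from a set of normalised ICD-10 codes."""
    return sum(CHARLSON_CATEGORIES[c][0] for c in charlson_categories(codes))


def charlson_index(patient_id: str, bundle: ClaimsBundle, as_of: pd.Timestamp) -> int:
    """Charlson index for one patient from diagnosis months strictly before ``as_of``.

    Claims diagnoses carry month granularity, so "before" is resolved at
    the month level: months strictly before the calendar month of
    ``as_of`` count (the same convention the cohort exclusions use for
    diagnosis history).
    """
    as_of = pd.Timestamp(as_of)
    dx = bundle.diagnoses
    mine = dx[dx["patient_id"] == patient_id]
    if not len(mine):
        return 0
    idx = month_to_index(mine["month"])
    cutoff = as_of.year * 12 + as_of.month - 1
    return charlson_score(set(mine.loc[idx < cutoff, "icd10"]))


def charlson_index_all(bundle: ClaimsBundle, as_of: pd.Series) -> pd.Series:
    """Vectorised Charlson index at a per-patient ``as_of`` date.

    Parameters
    ----------
    as_of
        Series of dates indexed by patient_id (e.g. each cohort member's
        t0). Returns an equally indexed integer Series.
    """
    dx = bundle.diagnoses
    out = pd.Series(0, index=as_of.index, dtype=np.int64)
    if not len(dx):
        return out
    merged = dx.merge(
        as_of.rename("as_of"), left_on="patient_id", right_index=True, how="inner"
    ).reset_index(drop=True)
    midx = month_to_index(merged["month"])
    cutoff = merged["as_of"].dt.year * 12 + merged["as_of"].dt.month - 1
    merged = merged[midx < cutoff]
    scores = merged.groupby("patient_id")["icd10"].agg(lambda s: charlson_score(set(s)))
    out.loc[scores.index] = scores.astype(np.int64)
    return out
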