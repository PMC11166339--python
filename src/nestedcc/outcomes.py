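"""Case ascertainment: upper-GI bleeding events inside the at-risk window.

A cohort member becomes a case at the earliest procedure claim that is
(A) a gastroscopy or hemostatic procedure dated strictly after t0 and no
later than the member's follow-up end, and (B) accompanied by an
upper-GI-bleeding diagnosis recorded for the same patient in the same
calendar month as the procedure. One case per patient (the first);
same-day gastroscopy + hemostasis collapse to one record with the
gastroscopy code reported.
"""

from __future__ import annotations

import pandas as pd

from .bundle import ClaimsBundle, date_to_month_index, month_to_index
from .cohort import match_prefixes


def identify_cases(cohort: pd.DataFrame, bundle: ClaimsBundle) -> pd.DataFrame:
    """Return one row per case: patient_id, index_date, qualifying_code,
    qualifying_dx, plus the member's t0 and index offset in days.

    Events after the follow-up end (which already reflects censoring at
    high-risk drug initiation) never qualify, nor does a procedure on t0
    itself: the at-risk window is (t0, followup_end].
    """
    cl = bundle.codelists
    pr = bundle.procedures
    qual_codes = set(cl.gastroscopy) | set(cl.hemostasis)
    proc = pr[pr["treatment_code"].isin(qual_codes)]
    cols = ["patient_id", "index_date", "qualifying_code", "qualifying_dx", "t0", "offset_days"]
    if not len(proc) or not len(cohort):
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})

    member = cohort.set_index("patient_id")
    proc = proc.merge(
        member[["t0", "followup_end"]], left_on="patient_id", right_index=True, how="inner"
    ).reset_index(drop=True)
    proc = proc[
        (proc["service_date"] > proc["t0"]) & (proc["service_date"] <= proc["followup_end"])
    ]
    if not len(proc):
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})

    dx = bundle.diagnoses
    ugib = dx[match_prefixes(dx["icd10"], cl.ugib)]
    ugib_months = pd.DataFrame(
        {
            "patient_id": ugib["patient_id"],
            "month_idx": month_to_index(ugib["month"]),
            "qualifying_dx": ugib["icd10"],
        }
    ).drop_duplicates(subset=["patient_id", "month_idx"])

    proc = proc.assign(month_idx=date_to_month_index(proc["service_date"]))
    hits = proc.merge(ugib_months, on=["patient_id", "month_idx"], how="inner")
    if not len(hits):
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})

    # earliest service date wins; same-day ties report the gastroscopy code
    hits["is_gastroscopy"] = hits["treatment_code"].isin(cl.gastroscopy)
    hits = hits.sort_values(
        ["patient_id", "service_date", "is_gastroscopy"],
        ascending=[True, True, False],
        kind="mergesort",
    )
    first = hits.groupby("patient_id", sort=True).first().reset_index()
    out = pd.DataFrame(
        {
            "patient_id": first["patient_id"],
            "index_date": first["service_date"],
            "qualifying_code": first["treatment_code"],
            "qualifying_dx": first["qualifying_dx"],
            "t0": first["t0"],
        }
    )
    out["offset_days"] = (out["index_date"] - out["t0"]).dt.days
    return out
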