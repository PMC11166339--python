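"""Hand-constructed miniature claims bundles with documented expectations.

Each fixture isolates one rule of the design — an exclusion criterion,
the episode gap boundary, the same-calendar-month linkage, the day-after
entry event window, or an exposure archetype — and records the expected
downstream behaviour in :data:`FIXTURE_EXPECTATIONS` so tests can assert
classification exactly. All fixtures use a single subject patient "F1"
(plus helper patients where matching needs them).

Expectation keys used (any subset per fixture):

* ``t0`` — expected entry date ("YYYY-MM-DD"), or None for no candidate
* ``excluded_by`` — first-triggering exclusion criterion number (0 = retained)
* ``followup_end`` — expected follow-up end date
* ``rebamipide_at_t0`` — expected entry co-prescription flag
* ``is_case`` / ``index_date`` — outcome ascertainment
* ``category_at`` — (evaluation date, expected exposure category)
"""

from __future__ import annotations

import pandas as pd

from .bundle import ClaimsBundle, annotate_drug_columns
from .codes import CodeLists

_T0 = "2015-03-10"  # canonical entry date used by most fixtures


class _Builder:
    def __init__(self) -> None:
        self.pat: list[dict] = []
        self.dx: list[dict] = []
        self.rx: list[dict] = []
        self.pr: list[dict] = []

    def patient(self, pid: str = "F1", sex: str = "female", birth: str = "1948-06-01") -> "_Builder":
        self.pat.append(
            {
                "patient_id": pid,
                "sex": sex,
                "birth_date": pd.Timestamp(birth),
                "coverage_start": pd.Timestamp("2013-04-01"),
                "coverage_end": pd.NaT,
            }
        )
        return self

    def diag(self, month: str, icd10: str, pid: str = "F1") -> "_Builder":
        self.dx.append({"patient_id": pid, "month": month, "icd10": icd10})
        return self

    def fill(self, date: str, code: str, tablets: int, dose: float, pid: str = "F1") -> "_Builder":
        self.rx.append(
            {
                "patient_id": pid,
                "dispense_date": pd.Timestamp(date),
                "drug_code": code,
                "tablets": tablets,
                "total_dose_mg": dose,
            }
        )
        return self

    def proc(self, date: str, code: str, pid: str = "F1") -> "_Builder":
        self.pr.append({"patient_id": pid, "service_date": pd.Timestamp(date), "treatment_code": code})
        return self

    def history(self, pid: str = "F1", month: str = "2014-01") -> "_Builder":
        """Benign record long before entry, satisfying criterion (1)."""
        return self.diag(month, "I10", pid=pid)

    def nsaid_entry(self, date: str = _T0, pid: str = "F1", tablets: int = 28,
                    dx_code: str = "M17") -> "_Builder":
        """A qualifying entry: loxoprofen fill + same-month OA diagnosis."""
        self.diag(date[:7], dx_code, pid=pid)
        return self.fill(date, "LOXOPROFEN60", tablets, tablets * 60.0, pid=pid)

    def build(self) -> ClaimsBundle:
        cl = CodeLists()
        patients = pd.DataFrame(self.pat)
        dx_cols = {"patient_id": pd.Series(dtype=object), "month": pd.Series(dtype=object),
                   "icd10": pd.Series(dtype=object)}
        diagnoses = pd.DataFrame(self.dx) if self.dx else pd.DataFrame(dx_cols)
        rx_cols = {"patient_id": pd.Series(dtype=object),
                   "dispense_date": pd.Series(dtype="datetime64[ns]"),
                   "drug_code": pd.Series(dtype=object),
                   "tablets": pd.Series(dtype="int64"),
                   "total_dose_mg": pd.Series(dtype=float)}
        prescriptions = pd.DataFrame(self.rx) if self.rx else pd.DataFrame(rx_cols)
        pr_cols = {"patient_id": pd.Series(dtype=object),
                   "service_date": pd.Series(dtype="datetime64[ns]"),
                   "treatment_code": pd.Series(dtype=object)}
        procedures = pd.DataFrame(self.pr) if self.pr else pd.DataFrame(pr_cols)
        prescriptions = annotate_drug_columns(prescriptions, cl)
        bundle = ClaimsBundle(
            patients=patients, diagnoses=diagnoses,
            prescriptions=prescriptions, procedures=procedures, codelists=cl,
        )
        bundle.check_invariants()
        return bundle


def _day(offset: int, base: str = _T0) -> str:
    return (pd.Timestamp(base) + pd.Timedelta(days=offset)).strftime("%Y-%m-%d")


def _fx_excl1_no_history() -> tuple[_Builder, dict]:
    b = _Builder().patient()
    b.diag("2015-02", "I10")  # only 30-ish days of history: inside the window
    b.nsaid_entry()
    return b, {"t0": _T0, "excluded_by": 1}


def _fx_excl2_prior_nsaid() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.fill(_day(-40), "LOXOPROFEN60", 14, 840.0)  # no OA dx in that month
    b.nsaid_entry()
    return b, {"t0": _T0, "excluded_by": 2}


def _fx_excl3_prior_ulcer() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.diag("2015-01", "K25")  # ulcer history inside the 90-day window's months
    b.nsaid_entry()
    return b, {"t0": _T0, "excluded_by": 3}


def _fx_excl4_highrisk_window() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.fill(_day(-30), "WARFARIN", 28, 28.0)
    b.nsaid_entry()
    return b, {"t0": _T0, "excluded_by": 4}


def _fx_excl5_prior_gastroscopy() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.proc("2014-06-15", "160093810")
    b.nsaid_entry()
    return b, {"t0": _T0, "excluded_by": 5}


def _fx_excl6_gastro_window() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.fill(_day(-30), "PPI", 28, 280.0)
    b.nsaid_entry()
    return b, {"t0": _T0, "excluded_by": 6}


def _fx_excl7_ppi_at_t0() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.fill(_T0, "PPI", 28, 280.0)
    b.nsaid_entry()
    return b, {"t0": _T0, "excluded_by": 7}


def _fx_retained_reb_t0() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.nsaid_entry()
    b.fill(_T0, "REBAMIPIDE100", 28, 2800.0)
    return b, {"t0": _T0, "excluded_by": 0, "rebamipide_at_t0": True,
               "followup_end": _day(180)}


def _fx_no_dx_month() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.fill(_T0, "LOXOPROFEN60", 28, 1680.0)
    b.diag("2015-04", "M17")  # diagnosis only the following month
    return b, {"t0": None}


def _fx_t0_second_fill() -> tuple[_Builder, dict]:
    # first fill lacks a same-month indication; the qualifying fill is months
    # later, far enough that criterion (2)'s window no longer sees the first
    b = _Builder().patient().history(month="2013-06")
    b.fill("2014-01-05", "LOXOPROFEN60", 28, 1680.0)
    b.nsaid_entry("2014-06-02", dx_code="M54")
    return b, {"t0": "2014-06-02", "excluded_by": 0}


def _fx_gap181() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.nsaid_entry()
    b.fill(_day(181), "LOXOPROFEN60", 28, 1680.0)  # 181-day gap: new episode
    return b, {"t0": _T0, "excluded_by": 0, "followup_end": _day(180)}


def _fx_gap180() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.nsaid_entry()
    b.fill(_day(180), "LOXOPROFEN60", 28, 1680.0)  # exactly 180: chained
    return b, {"t0": _T0, "excluded_by": 0, "followup_end": _day(360)}


def _fx_chain_90_110() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.nsaid_entry()
    b.fill(_day(90), "LOXOPROFEN60", 28, 1680.0)
    b.fill(_day(200), "LOXOPROFEN60", 28, 1680.0)
    return b, {"t0": _T0, "excluded_by": 0, "followup_end": _day(380)}


def _fx_censor_warfarin_day50() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.nsaid_entry()
    b.fill(_day(50), "WARFARIN", 28, 28.0)
    return b, {"t0": _T0, "excluded_by": 0, "followup_end": _day(49)}


def _fx_case_same_month() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.nsaid_entry("2016-04-15")
    b.proc("2016-05-20", "160093810")
    b.diag("2016-05", "K250")
    return b, {"t0": "2016-04-15", "excluded_by": 0, "is_case": True,
               "index_date": "2016-05-20"}


def _fx_case_dx_next_month() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.nsaid_entry("2016-04-15")
    b.proc("2016-05-20", "160093810")
    b.diag("2016-06", "K250")
    return b, {"t0": "2016-04-15", "excluded_by": 0, "is_case": False}


def _fx_event_on_t0() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.nsaid_entry("2016-04-15")
    b.proc("2016-04-15", "160093810")  # on entry day: outside (t0, end]
    b.diag("2016-04", "K250")
    return b, {"t0": "2016-04-15", "excluded_by": 0, "is_case": False}


def _fx_hemostasis_case() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.nsaid_entry("2016-04-15")
    b.proc("2016-05-20", "150164850")
    b.diag("2016-05", "K262")
    return b, {"t0": "2016-04-15", "excluded_by": 0, "is_case": True,
               "index_date": "2016-05-20"}


def _fx_non_user() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.nsaid_entry(tablets=28)
    b.fill(_day(30), "LOXOPROFEN60", 28, 1680.0)
    return b, {"t0": _T0, "excluded_by": 0,
               "category_at": (_day(60), "non_user")}


def _fx_continuous_pair() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.nsaid_entry(tablets=28)
    b.fill(_T0, "REBAMIPIDE100", 28, 2800.0)
    b.fill(_day(30), "LOXOPROFEN60", 28, 1680.0)
    b.fill(_day(30), "REBAMIPIDE100", 28, 2800.0)
    return b, {"t0": _T0, "excluded_by": 0,
               "category_at": (_day(60), "continuous_user")}


def _fx_irregular_tid() -> tuple[_Builder, dict]:
    # NSAID two tablets a day, rebamipide three a day: counts never match
    b = _Builder().patient().history()
    b.nsaid_entry(tablets=28)  # 14 days x 2/day
    b.fill(_T0, "REBAMIPIDE100", 42, 4200.0)  # 14 days x 3/day
    return b, {"t0": _T0, "excluded_by": 0,
               "category_at": (_day(60), "irregular_user")}


def _fx_irregular_late() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.nsaid_entry(tablets=28)
    b.fill(_day(30), "LOXOPROFEN60", 28, 1680.0)
    b.fill(_day(30), "REBAMIPIDE100", 28, 2800.0)  # starts at second fill
    return b, {"t0": _T0, "excluded_by": 0, "rebamipide_at_t0": False,
               "category_at": (_day(60), "irregular_user")}


def _fx_irregular_interrupt() -> tuple[_Builder, dict]:
    b = _Builder().patient().history()
    b.nsaid_entry(tablets=28)
    b.fill(_T0, "REBAMIPIDE100", 28, 2800.0)
    b.fill(_day(30), "LOXOPROFEN60", 28, 1680.0)  # no rebamipide here
    return b, {"t0": _T0, "excluded_by": 0,
               "category_at": (_day(60), "irregular_user")}


def _fx_reb_in_grace() -> tuple[_Builder, dict]:
    # rebamipide after the last NSAID fill does not break continuity
    b = _Builder().patient().history()
    b.nsaid_entry(tablets=28)
    b.fill(_T0, "REBAMIPIDE100", 28, 2800.0)
    b.fill(_day(40), "REBAMIPIDE100", 28, 2800.0)
    return b, {"t0": _T0, "excluded_by": 0,
               "category_at": (_day(60), "continuous_user")}


def _fx_reb_only_mid_therapy() -> tuple[_Builder, dict]:
    # a rebamipide-only date while NSAID therapy is still running breaks it
    b = _Builder().patient().history()
    b.nsaid_entry(tablets=28)
    b.fill(_T0, "REBAMIPIDE100", 28, 2800.0)
    b.fill(_day(15), "REBAMIPIDE100", 28, 2800.0)
    b.fill(_day(30), "LOXOPROFEN60", 28, 1680.0)
    b.fill(_day(30), "REBAMIPIDE100", 28, 2800.0)
    return b, {"t0": _T0, "excluded_by": 0,
               "category_at": (_day(60), "irregular_user")}


_FIXTURES = {
    name[4:]: fn
    for name, fn in list(globals().items())
    if name.startswith("_fx_")
}

#: fixture name -> documented expected downstream behaviour
FIXTURE_EXPECTATIONS: dict[str, dict] = {name: fn()[1] for name, fn in _FIXTURES.items()}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def make_fixture_bundle(name: str) -> ClaimsBundle:
    """Build the named fixture bundle; see :data:`FIXTURE_EXPECTATIONS`."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {fixture_names()}")
    builder, _ = _FIXTURES[name]()
    return builder.build()
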