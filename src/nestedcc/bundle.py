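"""Long-format claims tables: in-memory container, validation and CSV I/O.

A :class:`ClaimsBundle` holds the four tables every pipeline stage
consumes, as pandas DataFrames:

``patients``
    patient_id, sex ({male, female}), birth_date, coverage_start,
    coverage_end (NaT = coverage still open).
``diagnoses``
    patient_id, month ("YYYY-MM" string; claims diagnoses carry calendar
    month granularity only), icd10 (normalised, dots stripped).
``prescriptions``
    patient_id, dispense_date, drug_code, tablets (>= 1),
    total_dose_mg (mg of active ingredient in the dispensing), plus the
    derived columns drug_class and nsaid_type from the configured map.
``procedures``
    patient_id, service_date, treatment_code.

On-disk format: four UTF-8 CSV files with ISO-8601 dates; an empty
coverage_end field is the open-coverage sentinel. Reading is validating:
rows breaking a type invariant are rejected and reported with their row
number; a malformed header raises :class:`SchemaError`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codes import CodeLists, is_valid_icd10, normalize_icd10

_MONTH_RE = re.compile(r"^\d{4}-(0[1-9]|1[0-2])$")

PATIENT_COLS = ["patient_id", "sex", "birth_date", "coverage_start", "coverage_end"]
DIAGNOSIS_COLS = ["patient_id", "month", "icd10"]
PRESCRIPTION_COLS = ["patient_id", "dispense_date", "drug_code", "tablets", "total_dose_mg"]
PROCEDURE_COLS = ["patient_id", "service_date", "treatment_code"]

#: Default study observation window (calendar bounds on claim dates).
DEFAULT_STUDY_START = pd.Timestamp("2013-04-01")
DEFAULT_STUDY_END = pd.Timestamp("2020-12-31")


class SchemaError(ValueError):
    """A table file is missing a declared column."""


@dataclass
class ValidationReport:
    """Row-level diagnostics from reading/validating a bundle.

    ``errors`` holds (table, row_number, message) for every rejected row
    (row numbers are 1-based data rows, header excluded); ``warnings``
    holds non-fatal notes such as unmapped drug codes.
    """

    errors: list[tuple[str, int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_read: dict[str, int] = field(default_factory=dict)
    n_rejected: dict[str, int] = field(default_factory=dict)

    def summary(self) -> str:
        lines = []
        for table in sorted(self.n_read):
            lines.append(
                f"{table}: {self.n_read[table]} rows read, "
                f"{self.n_rejected.get(table, 0)} rejected"
            )
        for table, row, msg in self.errors[:50]:
            lines.append(f"  {table} row {row}: {msg}")
        lines.extend(f"  warning: {w}" for w in self.warnings)
        return "\n".join(lines)


def month_to_index(month: pd.Series | str) -> pd.Series | int:
    """Map "YYYY-MM" to a monotone integer month index (year*12 + month-1)."""
    if isinstance(month, str):
        y, m = month.split("-")
        return int(y) * 12 + int(m) - 1
    # fixed-format parse through datetime64[M]: months since 1970-01
    arr = month.to_numpy(dtype="U7").astype("datetime64[M]").astype(np.int64)
    return pd.Series(arr + 1970 * 12, index=month.index)


def date_to_month_index(dates: pd.Series) -> pd.Series:
    """Month index of a datetime series, aligned with :func:`month_to_index`."""
    return dates.dt.year * 12 + (dates.dt.month - 1)


@dataclass
class ClaimsBundle:
    """The four claims tables for a study population plus the study window."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    procedures: pd.DataFrame
    codelists: CodeLists = field(default_factory=CodeLists)
    study_start: pd.Timestamp = DEFAULT_STUDY_START
    study_end: pd.Timestamp = DEFAULT_STUDY_END
    report: ValidationReport = field(default_factory=ValidationReport)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def check_invariants(self) -> None:
        """Raise ValueError on a structural invariant violation.

        Checks referential integrity (every record's patient exists),
        coverage ordering, and that event dates fall inside the study
        window. Birth dates and coverage bounds may predate the window.
        """
        ids = set(self.patients["patient_id"])
        for name in ("diagnoses", "prescriptions", "procedures"):
            table = getattr(self, name)
            if len(table) and not set(table["patient_id"]).issubset(ids):
                raise ValueError(f"{name}: patient_id not present in patients table")
        pat = self.patients
        if len(pat):
            closed = pat["coverage_end"].notna()
            if (pat.loc[closed, "coverage_start"] > pat.loc[closed, "coverage_end"]).any():
                raise ValueError("patients: coverage_start > coverage_end")
            if (pat["birth_date"] >= pat["coverage_start"]).any():
                raise ValueError("patients: birth_date >= coverage_start")
        lo, hi = self.study_start, self.study_end
        if len(self.prescriptions):
            d = self.prescriptions["dispense_date"]
            if ((d < lo) | (d > hi)).any():
                raise ValueError("prescriptions: dispense_date outside study window")
        if len(self.procedures):
            d = self.procedures["service_date"]
            if ((d < lo) | (d > hi)).any():
                raise ValueError("procedures: service_date outside study window")
        if len(self.diagnoses):
            mi = month_to_index(self.diagnoses["month"])
            lo_m = lo.year * 12 + lo.month - 1
            hi_m = hi.year * 12 + hi.month - 1
            if ((mi < lo_m) | (mi > hi_m)).any():
                raise ValueError("diagnoses: month outside study window")


def _empty_frames() -> dict[str, pd.DataFrame]:
    return {
        "patients": pd.DataFrame(
            {
                "patient_id": pd.Series(dtype=str),
                "sex": pd.Series(dtype=str),
                "birth_date": pd.Series(dtype="datetime64[ns]"),
                "coverage_start": pd.Series(dtype="datetime64[ns]"),
                "coverage_end": pd.Series(dtype="datetime64[ns]"),
            }
        ),
        "diagnoses": pd.DataFrame(
            {
                "patient_id": pd.Series(dtype=str),
                "month": pd.Series(dtype=str),
                "icd10": pd.Series(dtype=str),
            }
        ),
        "prescriptions": pd.DataFrame(
            {
                "patient_id": pd.Series(dtype=str),
                "dispense_date": pd.Series(dtype="datetime64[ns]"),
                "drug_code": pd.Series(dtype=str),
                "tablets": pd.Series(dtype=np.int64),
                "total_dose_mg": pd.Series(dtype=float),
                "drug_class": pd.Series(dtype=str),
                "nsaid_type": pd.Series(dtype=object),
            }
        ),
        "procedures": pd.DataFrame(
            {
                "patient_id": pd.Series(dtype=str),
                "service_date": pd.Series(dtype="datetime64[ns]"),
                "treatment_code": pd.Series(dtype=str),
            }
        ),
    }


def annotate_drug_columns(prescriptions: pd.DataFrame, codelists: CodeLists) -> pd.DataFrame:
    """Attach drug_class / nsaid_type columns from the configured drug map."""
    class_map = {code: cls for code, (cls, _) in codelists.drug_map.items()}
    type_map = {code: nt for code, (_, nt) in codelists.drug_map.items()}
    out = prescriptions.copy()
    codes = out["drug_code"].astype(str)
    out["drug_class"] = codes.map(class_map).fillna("other")
    out["nsaid_type"] = codes.map(type_map)
    return out


def _parse_dates(
    df: pd.DataFrame, col: str, table: str, report: ValidationReport, required: bool = True
) -> tuple[pd.Series, pd.Series]:
    raw = df[col].astype(str).str.strip()
    blank = (raw == "") | raw.str.lower().isin({"nan", "none", "nat"})
    parsed = pd.to_datetime(raw.where(~blank), format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & ~blank if not required else parsed.isna() & ~blank
    if required:
        bad = bad | blank
    for idx in df.index[bad]:
        report.errors.append((table, int(idx) + 1, f"unparseable {col}: {df.loc[idx, col]!r}"))
    return parsed, bad


def read_claims_bundle(
    paths: dict[str, str | Path],
    codelists: CodeLists | None = None,
    study_start: pd.Timestamp = DEFAULT_STUDY_START,
    study_end: pd.Timestamp = DEFAULT_STUDY_END,
) -> ClaimsBundle:
    """Read and validate the four claims tables.

    Parameters
    ----------
    paths
        Mapping with keys ``patients``, ``diagnoses``, ``prescriptions``,
        ``procedures`` naming the CSV files.
    codelists
        Code configuration; drives drug classification of prescriptions.

    Rows violating a type invariant (bad date, tablets < 1, malformed
    ICD-10, unknown sex, orphan patient_id) are dropped and listed in
    ``bundle.report``; a missing column raises :class:`SchemaError`.
    """
    codelists = codelists or CodeLists()
    report = ValidationReport()
    frames = {}
    expected = {
        "patients": PATIENT_COLS,
        "diagnoses": DIAGNOSIS_COLS,
        "prescriptions": PRESCRIPTION_COLS,
        "procedures": PROCEDURE_COLS,
    }
    for table, cols in expected.items():
        df = pd.read_csv(paths[table], dtype=str, keep_default_na=False)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{table}: missing column(s) {missing}")
        df = df[cols].reset_index(drop=True)
        report.n_read[table] = len(df)
        frames[table] = df

    # -- patients
    pat = frames["patients"]
    bad = pd.Series(False, index=pat.index)
    sex = pat["sex"].str.strip().str.lower()
    bad_sex = ~sex.isin({"male", "female"})
    for idx in pat.index[bad_sex]:
        report.errors.append(("patients", int(idx) + 1, f"unknown sex {pat.loc[idx, 'sex']!r}"))
    bad |= bad_sex
    birth, b1 = _parse_dates(pat, "birth_date", "patients", report)
    cov_s, b2 = _parse_dates(pat, "coverage_start", "patients", report)
    cov_e, b3 = _parse_dates(pat, "coverage_end", "patients", report, required=False)
    bad |= b1 | b2 | b3
    order_ok = (birth < cov_s) & (cov_e.isna() | (cov_s <= cov_e))
    bad_order = ~order_ok & ~bad
    for idx in pat.index[bad_order]:
        report.errors.append(("patients", int(idx) + 1, "birth/coverage dates out of order"))
    bad |= bad_order
    patients = pd.DataFrame(
        {
            "patient_id": pat["patient_id"].str.strip(),
            "sex": sex,
            "birth_date": birth,
            "coverage_start": cov_s,
            "coverage_end": cov_e,
        }
    )[~bad].reset_index(drop=True)
    report.n_rejected["patients"] = int(bad.sum())
    known_ids = set(patients["patient_id"])

    def _orphans(df: pd.DataFrame, table: str) -> pd.Series:
        orphan = ~df["patient_id"].str.strip().isin(known_ids)
        for idx in df.index[orphan]:
            report.errors.append(
                (table, int(idx) + 1, f"unknown patient_id {df.loc[idx, 'patient_id']!r}")
            )
        return orphan

    # -- diagnoses
    dx = frames["diagnoses"]
    icd = dx["icd10"].map(normalize_icd10)
    bad_icd = ~icd.map(is_valid_icd10)
    for idx in dx.index[bad_icd]:
        report.errors.append(("diagnoses", int(idx) + 1, f"invalid ICD-10 {dx.loc[idx, 'icd10']!r}"))
    bad_month = ~dx["month"].str.strip().str.match(_MONTH_RE)
    for idx in dx.index[bad_month]:
        report.errors.append(("diagnoses", int(idx) + 1, f"invalid month {dx.loc[idx, 'month']!r}"))
    bad = bad_icd | bad_month | _orphans(dx, "diagnoses")
    diagnoses = pd.DataFrame(
        {"patient_id": dx["patient_id"].str.strip(), "month": dx["month"].str.strip(), "icd10": icd}
    )[~bad].reset_index(drop=True)
    report.n_rejected["diagnoses"] = int(bad.sum())

    # -- prescriptions
    rx = frames["prescriptions"]
    disp, bad_d = _parse_dates(rx, "dispense_date", "prescriptions", report)
    tablets = pd.to_numeric(rx["tablets"], errors="coerce")
    bad_t = tablets.isna() | (tablets < 1) | (tablets != tablets.round())
    for idx in rx.index[bad_t]:
        report.errors.append(
            ("prescriptions", int(idx) + 1, f"invalid tablets {rx.loc[idx, 'tablets']!r}")
        )
    dose = pd.to_numeric(rx["total_dose_mg"], errors="coerce")
    bad_dose = dose.isna() | (dose < 0)
    for idx in rx.index[bad_dose]:
        report.errors.append(
            ("prescriptions", int(idx) + 1, f"invalid total_dose_mg {rx.loc[idx, 'total_dose_mg']!r}")
        )
    bad = bad_d | bad_t | bad_dose | _orphans(rx, "prescriptions")
    prescriptions = pd.DataFrame(
        {
            "patient_id": rx["patient_id"].str.strip(),
            "dispense_date": disp,
            "drug_code": rx["drug_code"].str.strip(),
            "tablets": tablets,
            "total_dose_mg": dose,
        }
    )[~bad].reset_index(drop=True)
    prescriptions["tablets"] = prescriptions["tablets"].astype(np.int64)
    prescriptions = annotate_drug_columns(prescriptions, codelists)
    unknown = sorted(set(prescriptions.loc[prescriptions["drug_class"] == "other", "drug_code"]))
    unknown = [c for c in unknown if c not in codelists.drug_map]
    if unknown:
        report.warnings.append(f"unmapped drug codes classified as 'other': {unknown}")
    report.n_rejected["prescriptions"] = int(bad.sum())

    # -- procedures
    pr = frames["procedures"]
    svc, bad_s = _parse_dates(pr, "service_date", "procedures", report)
    empty_code = pr["treatment_code"].str.strip() == ""
    for idx in pr.index[empty_code]:
        report.errors.append(("procedures", int(idx) + 1, "empty treatment_code"))
    bad = bad_s | empty_code | _orphans(pr, "procedures")
    procedures = pd.DataFrame(
        {
            "patient_id": pr["patient_id"].str.strip(),
            "service_date": svc,
            "treatment_code": pr["treatment_code"].str.strip(),
        }
    )[~bad].reset_index(drop=True)
    report.n_rejected["procedures"] = int(bad.sum())

    bundle = ClaimsBundle(
        patients=patients,
        diagnoses=diagnoses,
        prescriptions=prescriptions,
        procedures=procedures,
        codelists=codelists,
        study_start=pd.Timestamp(study_start),
        study_end=pd.Timestamp(study_end),
        report=report,
    )
    bundle.check_invariants()
    return bundle


def write_claims_bundle(bundle: ClaimsBundle, paths: dict[str, str | Path]) -> None:
    """Write the four tables as CSV; inverse of :func:`read_claims_bundle`.

    Open coverage_end is written as an empty field. A round-trip through
    write/read reproduces the bundle exactly (dates, codes, counts).
    """
    pat = bundle.patients.copy()
    for col in ("birth_date", "coverage_start", "coverage_end"):
        pat[col] = pat[col].dt.strftime("%Y-%m-%d")
    pat["coverage_end"] = pat["coverage_end"].fillna("")
    pat[PATIENT_COLS].to_csv(paths["patients"], index=False)

    bundle.diagnoses[DIAGNOSIS_COLS].to_csv(paths["diagnoses"], index=False)

    rx = bundle.prescriptions.copy()
    rx["dispense_date"] = rx["dispense_date"].dt.strftime("%Y-%m-%d")
    rx[PRESCRIPTION_COLS].to_csv(paths["prescriptions"], index=False)

    pr = bundle.procedures.copy()
    pr["service_date"] = pr["service_date"].dt.strftime("%Y-%m-%d")
    pr[PROCEDURE_COLS].to_csv(paths["procedures"], index=False)


def default_paths(directory: str | Path) -> dict[str, Path]:
    """Conventional file names for the four tables inside ``directory``."""
    d = Path(directory)
    return {
        "patients": d / "patients.csv",
        "diagnoses": d / "diagnoses.csv",
        "prescriptions": d / "prescriptions.csv",
        "procedures": d / "procedures.csv",
    }


def bundles_equal(a: ClaimsBundle, b: ClaimsBundle) -> bool:
    """Exact equality of the four tables (used by round-trip tests)."""
    try:
        pd.testing.assert_frame_equal(a.patients, b.patients)
        pd.testing.assert_frame_equal(a.diagnoses, b.diagnoses)
        pd.testing.assert_frame_equal(
            a.prescriptions.drop(columns=["drug_class", "nsaid_type"]),
            b.prescriptions.drop(columns=["drug_class", "nsaid_type"]),
        )
        pd.testing.assert_frame_equal(a.procedures, b.procedures)
    except AssertionError:
        return False
    return True
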