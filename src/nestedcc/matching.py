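"""Incidence-density (risk-set) sampling of matched controls.

For each case, controls are drawn from cohort members still at risk at
the case's duration offset d = index_date - t0 (their own follow-up
covers d and their own event, if any, occurs strictly later), matched on
sex, age (caliper), and the NSAID exposure profile accumulated over each
member's first d days: total tablet count and per-drug total dose of the
five individually tracked NSAIDs. Up to ``max_controls`` eligible members
are drawn uniformly without replacement; members may serve as controls in
several sets and may later become cases themselves.

Comparisons are duration-aligned: a control's exposure is cumulated to
the case's time at risk on the control's own clock, which also satisfies
the follow-up matching caliper exactly (the caliper is still recorded in
the audit columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import ClaimsBundle
from .codes import NSAID_TYPES

#: Dose columns carried through matching, one per tracked NSAID.
DOSE_COLS = [f"dose_{t}_mg" for t in NSAID_TYPES]

_OFFSET_STRIDE = 1 << 20  # > any credible follow-up length in days


@dataclass(frozen=True)
class MatchingCriteria:
    """Matching rules for control selection.

    Tablets: exact equality when the case's cumulative total is at most
    ``tablets_exact_max``, otherwise a relative caliper. Dose: identical
    zero/nonzero pattern across the tracked NSAIDs and a relative caliper
    on each nonzero total. Both default calipers are configurable.
    """

    age_caliper_years: float = 5.0
    followup_caliper_days: int = 180
    max_controls: int = 10
    tablets_rel_tol: float = 0.20
    tablets_exact_max: int = 10
    dose_rel_tol: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_controls < 1:
            raise ValueError("max_controls must be >= 1")
        if self.age_caliper_years <= 0 or self.followup_caliper_days <= 0:
            raise ValueError("calipers must be positive")


class ExposureIndex:
    """Cumulative NSAID exposure (tablets, per-drug mg) as step functions.

    Compressed sparse layout over cohort members: fills at integer day
    offsets from each member's t0, with running totals, supporting a
    vectorised "cumulate to offset d" query across many members at once.
    """

    def __init__(self, cohort: pd.DataFrame, bundle: ClaimsBundle):
        self.patient_ids = cohort["patient_id"].to_numpy()
        self.pos_by_pid = {pid: i for i, pid in enumerate(self.patient_ids)}
        n = len(cohort)
        t0 = cohort.set_index("patient_id")["t0"]

        rx = bundle.prescriptions
        nsaid = rx[rx["drug_class"] == "nsaid"].merge(
            t0.rename("t0"), left_on="patient_id", right_index=True, how="inner"
        ).reset_index(drop=True)
        nsaid = nsaid[nsaid["dispense_date"] >= nsaid["t0"]]
        pos = nsaid["patient_id"].map(self.pos_by_pid).to_numpy(dtype=np.int64)
        offs = (nsaid["dispense_date"] - nsaid["t0"]).dt.days.to_numpy(dtype=np.int64)
        order = np.lexsort((offs, pos))
        pos, offs = pos[order], offs[order]
        tablets = nsaid["tablets"].to_numpy(dtype=np.int64)[order]
        type_idx = (
            nsaid["nsaid_type"].map({t: i for i, t in enumerate(NSAID_TYPES)})
            .to_numpy(dtype=np.int64)[order]
        )
        dose = nsaid["total_dose_mg"].to_numpy(dtype=float)[order]

        self.keys = pos * _OFFSET_STRIDE + offs
        self.indptr = np.searchsorted(pos, np.arange(n + 1))
        # running totals within each member (cumsum reset at member starts)
        cum_tab = np.cumsum(tablets)
        dose_mat = np.zeros((len(pos), len(NSAID_TYPES)))
        if len(pos):
            dose_mat[np.arange(len(pos)), type_idx] = dose
        cum_dose = np.cumsum(dose_mat, axis=0)
        starts = self.indptr[:-1]
        base_tab = np.zeros(n, dtype=np.int64)
        base_dose = np.zeros((n, len(NSAID_TYPES)))
        has = self.indptr[1:] > starts
        prev = starts[has] - 1
        base_tab[has] = np.where(prev >= 0, cum_tab[np.maximum(prev, 0)], 0)
        base_dose[has] = np.where(prev[:, None] >= 0, cum_dose[np.maximum(prev, 0)], 0.0)
        self._cum_tab = cum_tab
        self._cum_dose = cum_dose
        self._base_tab = base_tab
        self._base_dose = base_dose

    def cumulate(self, positions: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
        """Total tablets and per-drug dose over [t0, t0 + d] for each member."""
        positions = np.asarray(positions, dtype=np.int64)
        q = positions * _OFFSET_STRIDE + int(d)
        p = np.searchsorted(self.keys, q, side="right")
        start = self.indptr[positions]
        has_fill = p > start
        pm = np.maximum(p - 1, 0)
        tabs = np.where(has_fill, self._cum_tab[pm] - self._base_tab[positions], 0)
        doses = np.where(
            has_fill[:, None],
            self._cum_dose[pm] - self._base_dose[positions],
            0.0,
        )
        return tabs, doses


def cumulate_exposure_to(
    entry: pd.Series | dict, bundle: ClaimsBundle, as_of_days: int
) -> tuple[int, dict[str, float]]:
    """Scalar convenience form: one member's exposure at a day offset.

    Returns (total NSAID tablets, {nsaid_type: total mg}) over
    [t0, t0 + as_of_days], both boundaries inclusive.
    """
    pid, t0 = entry["patient_id"], pd.Timestamp(entry["t0"])
    rx = bundle.prescriptions
    mine = rx[
        (rx["patient_id"] == pid)
        & (rx["drug_class"] == "nsaid")
        & (rx["dispense_date"] >= t0)
        & (rx["dispense_date"] <= t0 + pd.Timedelta(days=as_of_days))
    ]
    doses = {t: 0.0 for t in NSAID_TYPES}
    for _, row in mine.iterrows():
        doses[row["nsaid_type"]] += float(row["total_dose_mg"])
    return int(mine["tablets"].sum()), doses


@dataclass
class SamplingLog:
    """Which cases were matched, and why any were dropped."""

    n_cases: int = 0
    n_matched: int = 0
    dropped: list[str] = field(default_factory=list)  # patient_ids with 0 eligibles
    n_eligible: dict[str, int] = field(default_factory=dict)


def sample_all_controls(
    cases: pd.DataFrame,
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    criteria: MatchingCriteria | None = None,
) -> tuple[pd.DataFrame, SamplingLog]:
    """Build every matched set; returns a long frame plus a sampling log.

    The frame has one row per member (case first within each set) with
    columns: set_id, role, patient_id, t0, offset_days, evaluation_date,
    index_date (case's calendar event date), sex, age_at_t0,
    followup_days, total_tablets, per-drug dose columns, n_eligible,
    plus the case's own attributes repeated for auditing
    (case_age_at_t0, case_total_tablets, case_followup_at_index).

    Cases are processed in (index_date, patient_id) order with a single
    generator seeded from ``criteria.seed``: re-running reproduces the
    sets exactly.
    """
    criteria = criteria or MatchingCriteria()
    rng = np.random.default_rng(criteria.seed)
    coh = cohort.reset_index(drop=True)
    index = ExposureIndex(coh, bundle)

    pids = coh["patient_id"].to_numpy()
    sex = (coh["sex"] == "male").to_numpy()
    age = coh["age_at_t0"].to_numpy(dtype=float)
    fup = coh["followup_days"].to_numpy(dtype=np.int64)
    event_offset = np.full(len(coh), np.iinfo(np.int64).max, dtype=np.int64)
    case_pos = {}
    for _, c in cases.iterrows():
        p = index.pos_by_pid.get(c["patient_id"])
        if p is not None:
            event_offset[p] = c["offset_days"]
            case_pos[c["patient_id"]] = p

    ordered = cases.sort_values(["index_date", "patient_id"], kind="mergesort")
    log = SamplingLog(n_cases=len(ordered))
    rows: list[dict] = []
    set_id = 0
    t0_arr = coh["t0"].to_numpy()

    for _, c in ordered.iterrows():
        cp = case_pos.get(c["patient_id"])
        if cp is None:  # case not in (possibly restricted) cohort
            continue
        d = int(c["offset_days"])
        at_risk = (event_offset > d) & (fup >= d)
        at_risk[cp] = False
        demo = (sex == sex[cp]) & (np.abs(age - age[cp]) <= criteria.age_caliper_years)
        cand = np.flatnonzero(at_risk & demo)
        case_tabs, case_dose = index.cumulate(np.array([cp]), d)
        case_tabs = int(case_tabs[0])
        case_dose = case_dose[0]
        if len(cand):
            tabs, doses = index.cumulate(cand, d)
            if case_tabs <= criteria.tablets_exact_max:
                tab_ok = tabs == case_tabs
            else:
                tab_ok = np.abs(tabs - case_tabs) <= criteria.tablets_rel_tol * case_tabs
            pat_ok = (doses > 0) == (case_dose > 0)[None, :]
            tol = criteria.dose_rel_tol * case_dose
            dose_ok = np.abs(doses - case_dose[None, :]) <= tol[None, :]
            dose_ok = np.where((case_dose > 0)[None, :], dose_ok, True)
            ok = tab_ok & pat_ok.all(axis=1) & dose_ok.all(axis=1)
            eligible = cand[ok]
            elig_tabs = tabs[ok]
            elig_doses = doses[ok]
        else:
            eligible = cand
            elig_tabs = np.empty(0, dtype=np.int64)
            elig_doses = np.empty((0, len(NSAID_TYPES)))
        log.n_eligible[c["patient_id"]] = int(len(eligible))
        if len(eligible) == 0:
            log.dropped.append(c["patient_id"])
            continue
        k = min(criteria.max_controls, len(eligible))
        pick = rng.choice(len(eligible), size=k, replace=False)
        pick.sort()

        def member_row(pos: int, role: str, tabs_i: int, dose_i: np.ndarray) -> dict:
            row = {
                "set_id": set_id,
                "role": role,
                "patient_id": pids[pos],
                "t0": t0_arr[pos],
                "offset_days": d,
                "evaluation_date": t0_arr[pos] + np.timedelta64(d, "D"),
                "index_date": c["index_date"],
                "sex": "male" if sex[pos] else "female",
                "age_at_t0": age[pos],
                "followup_days": int(fup[pos]),
                "total_tablets": int(tabs_i),
                "n_eligible": int(len(eligible)),
                "case_age_at_t0": age[cp],
                "case_total_tablets": case_tabs,
                "case_followup_at_index": d,
            }
            for j, colname in enumerate(DOSE_COLS):
                row[colname] = float(dose_i[j])
            return row

        rows.append(member_row(cp, "case", case_tabs, case_dose))
        for i in pick:
            rows.append(member_row(int(eligible[i]), "control", int(elig_tabs[i]), elig_doses[i]))
        log.n_matched += 1
        set_id += 1

    frame = pd.DataFrame(rows)
    if len(frame):
        extra = coh.set_index("patient_id")["index_nsaid_type"]
        frame["index_nsaid_type"] = frame["patient_id"].map(extra)
    return frame, log
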