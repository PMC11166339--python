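"""Rebamipide co-prescription pattern: Non- / Continuous- / Irregular-user.

Classification looks at the window from a member's t0 to their
evaluation date (a case's own index date; a control's duration-aligned
date). Rules, applied per dispense date (same-day rows summed):

* **non_user** — no rebamipide dispensed in the window.
* **continuous_user** — rebamipide dispensed on t0; every NSAID dispense
  date in the window has a same-day rebamipide dispense with an equal
  tablet count; and no rebamipide-only date occurs while NSAID therapy
  is still active (a rebamipide fill after the last NSAID fill of the
  window, during the trailing grace period, does not break continuity).
* **irregular_user** — everything else (late start, tablet mismatch,
  interrupted refills, rebamipide-only fills, ...).

The three labels partition all members. A relaxed mode comparing
cumulative totals instead of per-date counts is available for
sensitivity exploration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bundle import ClaimsBundle

CATEGORIES = ("non_user", "continuous_user", "irregular_user")


def _daily_totals(rx: pd.DataFrame, drug_class: str) -> pd.DataFrame:
    sub = rx[rx["drug_class"] == drug_class]
    return (
        sub.groupby(["patient_id", "dispense_date"], sort=True)["tablets"]
        .sum()
        .reset_index()
    )


def _classify_one(
    nsaid_dates: np.ndarray,
    nsaid_tabs: np.ndarray,
    reb_dates: np.ndarray,
    reb_tabs: np.ndarray,
    t0: np.datetime64,
    evaluation_date: np.datetime64,
    per_date: bool = True,
) -> tuple[str, dict]:
    # compare in integer (ns) space: mixed datetime/py-int comparisons are
    # unreliable once numpy scalars leave array land via tolist()
    nsaid_i = nsaid_dates.astype("datetime64[ns]").astype(np.int64)
    reb_i = reb_dates.astype("datetime64[ns]").astype(np.int64)
    t0 = np.datetime64(t0, "ns").astype(np.int64)
    evaluation_date = np.datetime64(evaluation_date, "ns").astype(np.int64)
    in_w = (nsaid_i >= t0) & (nsaid_i <= evaluation_date)
    nd, nt = nsaid_i[in_w], nsaid_tabs[in_w]
    in_w = (reb_i >= t0) & (reb_i <= evaluation_date)
    rd, rt = reb_i[in_w], reb_tabs[in_w]
    info = {
        "cum_nsaid_tablets": int(nt.sum()),
        "cum_rebamipide_tablets": int(rt.sum()),
        "rebamipide_at_t0": bool((rd == t0).any()),
        "n_fills_matched": 0,
    }
    if len(rd) == 0:
        return "non_user", info
    if not info["rebamipide_at_t0"]:
        return "irregular_user", info
    if not per_date:  # relaxed mode: cumulative totals only
        if int(rt.sum()) == int(nt.sum()):
            info["n_fills_matched"] = len(nd)
            return "continuous_user", info
        return "irregular_user", info
    reb_by_date = dict(zip(rd.tolist(), rt.tolist()))
    matched = 0
    for date, tabs in zip(nd.tolist(), nt.tolist()):
        if reb_by_date.get(date) != tabs:
            info["n_fills_matched"] = matched
            return "irregular_user", info
        matched += 1
    info["n_fills_matched"] = matched
    last_nsaid = nd.max() if len(nd) else t0
    nsaid_dates_set = set(nd.tolist())
    for date in rd.tolist():
        if date <= last_nsaid and date not in nsaid_dates_set:
            return "irregular_user", info
    return "continuous_user", info


def classify_exposure(
    patient_id: str,
    t0: pd.Timestamp,
    evaluation_date: pd.Timestamp,
    bundle: ClaimsBundle,
    per_date: bool = True,
) -> tuple[str, dict]:
    """Classify one member; returns (category, supporting counts)."""
    t0, evaluation_date = pd.Timestamp(t0), pd.Timestamp(evaluation_date)
    if t0 > evaluation_date:
        raise ValueError("evaluation_date precedes t0")
    rx = bundle.prescriptions
    mine = rx[rx["patient_id"] == patient_id]
    nsaid = _daily_totals(mine, "nsaid")
    reb = _daily_totals(mine, "rebamipide")
    return _classify_one(
        nsaid["dispense_date"].to_numpy(),
        nsaid["tablets"].to_numpy(),
        reb["dispense_date"].to_numpy(),
        reb["tablets"].to_numpy(),
        np.datetime64(t0, "ns"),
        np.datetime64(evaluation_date, "ns"),
        per_date=per_date,
    )


def classify_matched_sets(
    sets: pd.DataFrame, bundle: ClaimsBundle, per_date: bool = True
) -> pd.DataFrame:
    """Append exposure columns to a matched-set long frame.

    Each member is classified over [their t0, their evaluation_date].
    Adds: category, cum_nsaid_tablets, cum_rebamipide_tablets,
    rebamipide_at_t0, n_fills_matched.
    """
    if not len(sets):
        out = sets.copy()
        out["category"] = pd.Series(dtype=str)
        return out
    members = set(sets["patient_id"])
    rx = bundle.prescriptions
    rx = rx[rx["patient_id"].isin(members)]
    nsaid = _daily_totals(rx, "nsaid")
    reb = _daily_totals(rx, "rebamipide")

    def bucket(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for pid, grp in df.groupby("patient_id", sort=False):
            out[pid] = (grp["dispense_date"].to_numpy(), grp["tablets"].to_numpy())
        return out

    nsaid_by, reb_by = bucket(nsaid), bucket(reb)
    empty = (np.empty(0, dtype="datetime64[ns]"), np.empty(0, dtype=np.int64))

    cats, infos = [], []
    for pid, t0, ev in zip(
        sets["patient_id"], sets["t0"].to_numpy(), sets["evaluation_date"].to_numpy()
    ):
        nd, nt = nsaid_by.get(pid, empty)
        rd, rt = reb_by.get(pid, empty)
        cat, info = _classify_one(nd, nt, rd, rt, t0, ev, per_date=per_date)
        cats.append(cat)
        infos.append(info)
    out = sets.copy()
    out["category"] = cats
    for key in ("cum_nsaid_tablets", "cum_rebamipide_tablets", "rebamipide_at_t0", "n_fills_matched"):
        out[key] = [i[key] for i in infos]
    return out
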