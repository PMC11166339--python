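"""Risk-set sampling: exposure accumulation, eligibility, audits, determinism."""

import numpy as np
import pandas as pd
import pytest

from nestedcc import (
    MatchingCriteria,
    build_cohort,
    cumulate_exposure_to,
    identify_cases,
    sample_all_controls,
)
from nestedcc.fixtures import _Builder, _day
from nestedcc.matching import DOSE_COLS, ExposureIndex


def _loxo_bundle():
    b = _Builder().patient().history()
    b.nsaid_entry(tablets=30)  # 30 tablets x 60 mg on t0
    b.fill(_day(30), "LOXOPROFEN60", 30, 1800.0)
    b.fill(_day(70), "CELECOXIB100", 14, 1400.0)
    return b.build()


def test_cumulate_exposure_hand_summed():
    bundle = _loxo_bundle()
    entry = {"patient_id": "F1", "t0": pd.Timestamp("2015-03-10")}
    tabs, doses = cumulate_exposure_to(entry, bundle, 60)
    assert tabs == 60
    assert doses["loxoprofen"] == 3600.0 and doses["celecoxib"] == 0.0
    # boundary: day 0 includes the t0 fill only
    tabs0, doses0 = cumulate_exposure_to(entry, bundle, 0)
    assert tabs0 == 30 and doses0["loxoprofen"] == 1800.0
    # mixed history once the celecoxib fill enters the window
    tabs70, doses70 = cumulate_exposure_to(entry, bundle, 70)
    assert tabs70 == 74 and doses70["celecoxib"] == 1400.0


def test_exposure_index_agrees_with_scalar_path(small_bundle):
    cohort, _ = build_cohort(small_bundle)
    idx = ExposureIndex(cohort, small_bundle)
    rng = np.random.default_rng(3)
    sample = rng.choice(len(cohort), size=25, replace=False)
    for d in (0, 30, 200):
        tabs, doses = idx.cumulate(sample, d)
        for j, pos in enumerate(sample[:10]):
            entry = cohort.iloc[pos]
            t_exp, d_exp = cumulate_exposure_to(entry, small_bundle, d)
            assert tabs[j] == t_exp
            assert doses[j].sum() == pytest.approx(sum(d_exp.values()))


@pytest.fixture(scope="module")
def sampled(small_bundle):
    cohort, _ = build_cohort(small_bundle)
    cases = identify_cases(cohort, small_bundle)
    criteria = MatchingCriteria(seed=99)
    sets, log = sample_all_controls(cases, cohort, small_bundle, criteria)
    return cohort, cases, criteria, sets, log


def test_every_control_satisfies_every_matching_rule(sampled):
    """Audit the emitted sets against the rules, not the implementation."""
    cohort, cases, criteria, sets, log = sampled
    assert len(sets)
    for set_id, grp in sets.groupby("set_id"):
        case = grp[grp["role"] == "case"].iloc[0]
        ctrls = grp[grp["role"] == "control"]
        assert 1 <= len(ctrls) <= criteria.max_controls
        assert case["patient_id"] not in set(ctrls["patient_id"])
        assert (ctrls["sex"] == case["sex"]).all()
        assert (np.abs(ctrls["age_at_t0"] - case["age_at_t0"]) <= 5).all()
        # at risk at the case's duration offset (subsumes the +/-180 d caliper)
        assert (ctrls["followup_days"] >= case["offset_days"]).all()
        # tablet rule
        if case["total_tablets"] <= criteria.tablets_exact_max:
            assert (ctrls["total_tablets"] == case["total_tablets"]).all()
        else:
            tol = criteria.tablets_rel_tol * case["total_tablets"]
            assert (np.abs(ctrls["total_tablets"] - case["total_tablets"]) <= tol).all()
        # dose rule: same nonzero pattern, relative caliper on nonzero totals
        for col in DOSE_COLS:
            cd = case[col]
            if cd > 0:
                assert (ctrls[col] > 0).all()
                assert (np.abs(ctrls[col] - cd) <= criteria.dose_rel_tol * cd).all()
            else:
                assert (ctrls[col] == 0).all()


def test_controls_not_yet_cases_at_sampling_time(sampled):
    cohort, cases, criteria, sets, log = sampled
    case_offsets = cases.set_index("patient_id")["offset_days"]
    ctrls = sets[sets["role"] == "control"]
    future = ctrls["patient_id"].map(case_offsets)
    # controls that later become cases must do so strictly after the offset
    later = future.notna()
    assert (future[later] > ctrls.loc[later, "offset_days"]).all()


def test_same_seed_reproduces_sets_different_seed_resamples(small_bundle, sampled):
    cohort, cases, criteria, sets, log = sampled
    sets2, _ = sample_all_controls(cases, cohort, small_bundle, criteria)
    pd.testing.assert_frame_equal(sets, sets2)
    other = MatchingCriteria(seed=criteria.seed + 1)
    sets3, log3 = sample_all_controls(cases, cohort, small_bundle, other)
    # eligibility is seed-independent; only the draw changes
    assert log3.n_eligible == log.n_eligible
    assert log3.dropped == log.dropped


def test_cap_rule_and_eligibility_counts(sampled):
    _, _, criteria, sets, log = sampled
    per_set = sets[sets["role"] == "control"].groupby("set_id").size()
    assert (per_set <= criteria.max_controls).all()
    # where >= 10 candidates were eligible the set is filled to exactly 10
    filled = sets[sets["role"] == "case"].set_index("set_id")
    for set_id, row in filled.iterrows():
        if row["n_eligible"] >= criteria.max_controls:
            assert per_set[set_id] == criteria.max_controls
        else:
            assert per_set[set_id] == row["n_eligible"]


def test_controls_reused_and_future_cases_eligible():
    """Risk-set semantics: members serve in several sets, and a later case
    is a valid control for an earlier one (but never after its own event)."""
    b = _Builder()
    for i, pid in enumerate(["A", "B", "C", "D", "E"]):
        b.patient(pid=pid).history(pid=pid)
        b.nsaid_entry(pid=pid, tablets=28)
    # A bleeds at day 40, B at day 60; C, D, E stay event-free
    b.proc(_day(40), "160093810", pid="A").diag(_day(40)[:7], "K250", pid="A")
    b.proc(_day(60), "160093810", pid="B").diag(_day(60)[:7], "K250", pid="B")
    bundle = b.build()
    cohort, _ = build_cohort(bundle)
    cases = identify_cases(cohort, bundle)
    assert set(cases["patient_id"]) == {"A", "B"}
    sets, log = sample_all_controls(cases, cohort, bundle, MatchingCriteria(seed=0, max_controls=5))
    by_case = {
        grp[grp["role"] == "case"].iloc[0]["patient_id"]: set(grp[grp["role"] == "control"]["patient_id"])
        for _, grp in sets.groupby("set_id")
    }
    assert by_case["A"] == {"B", "C", "D", "E"}  # B not yet a case at day 40
    assert by_case["B"] == {"C", "D", "E"}  # A already a case at day 60
    reused = set(by_case["A"]) & set(by_case["B"])
    assert reused == {"C", "D", "E"}


def test_unmatchable_cases_are_dropped_and_logged(small_bundle):
    cohort, _ = build_cohort(small_bundle)
    cases = identify_cases(cohort, small_bundle)
    # an impossibly tight tablet rule leaves most cases without controls
    strict = MatchingCriteria(seed=1, tablets_rel_tol=0.0, tablets_exact_max=10**9)
    sets, log = sample_all_controls(cases, cohort, small_bundle, strict)
    assert log.n_matched + len(log.dropped) == log.n_cases
    if len(sets):
        assert set(log.dropped).isdisjoint(sets[sets["role"] == "case"]["patient_id"])
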