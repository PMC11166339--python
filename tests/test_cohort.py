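"""Cohort entry, exclusion cascade and follow-up construction."""

import numpy as np
import pandas as pd
import pytest

from nestedcc import (
    FIXTURE_EXPECTATIONS,
    apply_exclusions,
    build_cohort,
    find_candidate_t0,
    fixture_names,
    make_fixture_bundle,
)

ENTRY_FIXTURES = [n for n, e in FIXTURE_EXPECTATIONS.items() if "t0" in e]


@pytest.mark.parametrize("name", ENTRY_FIXTURES)
def test_fixture_entry_dates(name):
    """t0 is the earliest NSAID fill with a same-month indication code."""
    bundle = make_fixture_bundle(name)
    expected = FIXTURE_EXPECTATIONS[name]
    cand = find_candidate_t0(bundle)
    mine = cand[cand["patient_id"] == "F1"]
    if expected["t0"] is None:
        assert len(mine) == 0
    else:
        assert len(mine) == 1
        assert mine.iloc[0]["t0"] == pd.Timestamp(expected["t0"])


EXCLUSION_FIXTURES = [n for n, e in FIXTURE_EXPECTATIONS.items() if "excluded_by" in e]


@pytest.mark.parametrize("name", EXCLUSION_FIXTURES)
def test_fixture_exclusion_cascade(name):
    """Each fixture triggers exactly its documented first criterion."""
    bundle = make_fixture_bundle(name)
    expected = FIXTURE_EXPECTATIONS[name]
    cand = find_candidate_t0(bundle)
    flagged, report = apply_exclusions(cand, bundle)
    row = flagged[flagged["patient_id"] == "F1"].iloc[0]
    assert row["excluded_by"] == expected["excluded_by"]
    assert report.n_retained + sum(report.counts.values()) == report.n_candidates


FOLLOWUP_FIXTURES = [n for n, e in FIXTURE_EXPECTATIONS.items() if "followup_end" in e]


@pytest.mark.parametrize("name", FOLLOWUP_FIXTURES)
def test_fixture_followup_ends(name):
    """Gap/grace chaining and high-risk censoring produce the traced dates."""
    bundle = make_fixture_bundle(name)
    expected = FIXTURE_EXPECTATIONS[name]
    cohort, _ = build_cohort(bundle)
    row = cohort[cohort["patient_id"] == "F1"].iloc[0]
    assert row["followup_end"] == pd.Timestamp(expected["followup_end"])
    if "rebamipide_at_t0" in expected:
        assert bool(row["rebamipide_at_t0"]) is expected["rebamipide_at_t0"]


def test_t0_minimal_among_qualifying_dates_brute_force(small_bundle):
    """find_candidate_t0 agrees with a per-patient brute-force scan."""
    cand = find_candidate_t0(small_bundle).set_index("patient_id")["t0"]
    rx = small_bundle.prescriptions
    dx = small_bundle.diagnoses
    oa_stems = tuple(small_bundle.codelists.oa_backpain)
    oa_months = {
        (pid, m)
        for pid, m, code in zip(dx["patient_id"], dx["month"], dx["icd10"])
        if code.startswith(oa_stems)
    }
    nsaid = rx[rx["drug_class"] == "nsaid"]
    some = nsaid["patient_id"].drop_duplicates().head(300)
    for pid in some:
        fills = nsaid[nsaid["patient_id"] == pid]["dispense_date"]
        qualifying = [
            d for d in fills if (pid, d.strftime("%Y-%m")) in oa_months
        ]
        if qualifying:
            assert cand[pid] == min(qualifying)
        else:
            assert pid not in cand.index


def test_exclusion_report_invariant_to_row_order(small_bundle):
    cand = find_candidate_t0(small_bundle)
    _, report_fwd = apply_exclusions(cand, small_bundle)
    shuffled = cand.sample(frac=1.0, random_state=5).reset_index(drop=True)
    _, report_rev = apply_exclusions(shuffled, small_bundle)
    assert report_fwd.counts == report_rev.counts
    assert report_fwd.n_retained == report_rev.n_retained


def test_followup_bounds_and_age(small_bundle):
    cohort, _ = build_cohort(small_bundle)
    assert (cohort["followup_end"] >= cohort["t0"]).all()
    assert (cohort["followup_end"] <= small_bundle.study_end).all()
    assert (cohort["age_at_t0"] > 0).all()
    censored = cohort[cohort["censor_date"].notna()]
    assert (censored["followup_end"] <= censored["censor_date"]).all()


def test_one_entry_per_patient(small_bundle):
    cohort, _ = build_cohort(small_bundle)
    assert cohort["patient_id"].is_unique


def test_retained_and_excluded_match_generator_intent(small_bundle, small_truth):
    cohort, _ = build_cohort(small_bundle)
    eligible = small_truth[small_truth["cohort_eligible"]]
    assert set(cohort["patient_id"]) == set(eligible["patient_id"])
    merged = cohort.merge(eligible, on="patient_id", suffixes=("", "_true"))
    assert (merged["t0"] == merged["t0_true"]).all()
    assert (merged["followup_end"] == merged["followup_end_true"]).all()


def test_charlson_threshold_shrinks_cohort(small_bundle):
    full, _ = build_cohort(small_bundle)
    restricted, _ = build_cohort(small_bundle, charlson_max=1)
    assert 0 < len(restricted) < len(full)
    assert set(restricted["patient_id"]) <= set(full["patient_id"])
    assert (restricted["charlson_at_t0"] < 1).all()


def test_unknown_fixture_name_raises():
    with pytest.raises(KeyError):
        make_fixture_bundle("does_not_exist")
    assert len(fixture_names()) >= 20
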