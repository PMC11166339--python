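"""Synthetic claims generator with known ground truth.

Emulates the data-generating process the analysis assumes: a population
of insured patients, a subset of whom become new NSAID users for
osteoarthritis / back pain (entry date t0 = first fill, with a
same-month indication diagnosis), refill episodes with gaps that
occasionally straddle the 180-day chaining rule, rebamipide
co-prescription following one of three archetypes, censoring at
high-risk drug initiation, and upper-GI-bleeding events drawn from a
piecewise-constant per-day hazard: the baseline rate multiplied by the
rate ratio of the co-prescription category *as expressed in the claims
up to that day*. A late-start irregular user is indistinguishable from
a non-user until their first refill, and an interrupted user from a
continuous user, so the hazard carries the pre-deviation rate over that
span and the irregular rate after; the category a classifier reads off
the history at any index date is then exactly the category whose rate
generated events at that time. In the rare-event regime the odds ratio
from incidence-density sampling estimates the configured hazard ratios,
which is what parameter-recovery tests exploit.

Archetypes
----------
* ``non_user`` — never co-prescribed rebamipide.
* ``continuous_user`` — rebamipide on every NSAID fill date from t0 with
  a matching tablet count.
* ``irregular_user`` — one of three sub-mechanisms, drawn with equal
  probability among patients with at least two fills: late start
  (rebamipide begins at the second fill), tablet mismatch from t0 (the
  classic "NSAID twice daily, rebamipide three times daily" pattern),
  or an interrupted refill (rebamipide skipped at the second fill).
  Single-fill irregular users always use the mismatch mechanism, the
  only one observable in a one-fill window.

Every detected event emits a gastroscopy claim (plus a hemostatic
procedure claim for a fraction of cases) and an upper-GI-bleeding
diagnosis in the same calendar month, mirroring the case definition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .bundle import ClaimsBundle, DEFAULT_STUDY_END, DEFAULT_STUDY_START, annotate_drug_columns
from .codes import CodeLists, DEFAULT_MG_PER_TABLET, NSAID_CODE_BY_TYPE

AGE_BANDS = ("<=64", "65-74", "75-84", ">=85")
_AGE_RANGES = {"<=64": (40.0, 65.0), "65-74": (65.0, 75.0), "75-84": (75.0, 85.0), ">=85": (85.0, 96.0)}
ARCHETYPES = ("non_user", "continuous_user", "irregular_user")

_BACKGROUND_DX = ("I10", "J069", "M791")
_OA_CODES = ("M54", "M17", "M16", "M19", "M18")
_OA_PROBS = (0.60, 0.30, 0.03, 0.05, 0.02)
_UGIB_CODES = ("K250", "K252", "K260", "K290", "K922")
_UGIB_PROBS = (0.55, 0.15, 0.15, 0.10, 0.05)


class SimulationConfig(BaseModel):
    """Study conditions for the synthetic population.

    Defaults mirror the study this pipeline models: an elderly,
    sex-balanced orthopaedic population, loxoprofen-dominated NSAID mix,
    archetype shares near the observed control distribution, protective
    continuous-use hazard ratio 0.65 and harmful irregular-use ratio
    2.57, and a baseline hazard yielding roughly 0.5% cumulative
    bleeding incidence over an episode.
    """

    n_patients: int = Field(gt=0)
    seed: int = 0
    age_distribution: dict[str, float] = {
        "<=64": 0.125, "65-74": 0.335, "75-84": 0.395, ">=85": 0.145
    }
    sex_ratio: float = Field(default=0.5, ge=0.0, le=1.0)  # fraction male
    p_oa_backpain_user: float = Field(default=0.8, ge=0.0, le=1.0)
    nsaid_type_probs: dict[str, float] = {
        "loxoprofen": 0.70, "celecoxib": 0.22, "diclofenac": 0.05,
        "meloxicam": 0.02, "ibuprofen": 0.01,
    }
    tablets_per_day_probs: dict[int, float] = {1: 0.25, 2: 0.50, 3: 0.25}
    days_per_fill_probs: dict[int, float] = {7: 0.30, 14: 0.35, 30: 0.25, 60: 0.10}
    p_long_refill_gap: float = Field(default=0.12, ge=0.0, le=1.0)
    long_gap_range_days: tuple[int, int] = (150, 260)  # straddles the 180-day rule
    mean_extra_fills: float = Field(default=3.5, gt=0.0)
    max_fills: int = Field(default=12, ge=1)
    exposure_archetype_probs: dict[str, float] = {
        "non_user": 0.48, "continuous_user": 0.39, "irregular_user": 0.13
    }
    baseline_bleed_hazard_per_day: float = Field(default=1.6e-5, gt=0.0)
    true_or_continuous: float = Field(default=0.65, gt=0.0)
    true_or_irregular: float = Field(default=2.57, gt=0.0)
    p_prior_ulcer: float = Field(default=0.03, ge=0.0, le=1.0)
    p_highrisk_drug_start_per_day: float = Field(default=1.5e-4, ge=0.0)
    p_event_detected: float = Field(default=1.0, ge=0.0, le=1.0)
    p_hemostasis_claim: float = Field(default=0.2, ge=0.0, le=1.0)
    p_comorbidity: float = Field(default=0.10, ge=0.0, le=1.0)
    study_start: pd.Timestamp = DEFAULT_STUDY_START
    study_end: pd.Timestamp = DEFAULT_STUDY_END
    gap_days: int = 180
    grace_days: int = 180

    model_config = {"arbitrary_types_allowed": True}

    @model_validator(mode="after")
    def _check_distributions(self) -> "SimulationConfig":
        for name in ("age_distribution", "nsaid_type_probs", "tablets_per_day_probs",
                     "days_per_fill_probs", "exposure_archetype_probs"):
            probs = getattr(self, name)
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name}: negative probability")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}: probabilities must sum to 1")
        if set(self.exposure_archetype_probs) != set(ARCHETYPES):
            raise ValueError("exposure_archetype_probs must cover the three archetypes")
        return self


def _categorical(rng: np.random.Generator, probs: dict, n: int) -> np.ndarray:
    keys = list(probs.keys())
    idx = rng.choice(len(keys), size=n, p=list(probs.values()))
    return np.array(keys, dtype=object)[idx]


def simulate_bundle(config: SimulationConfig) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Generate a claims bundle and its ground truth.

    Deterministic for a fixed seed. The ground-truth frame has one row
    per patient: archetype (and sub-mechanism), true t0, follow-up end
    mirroring the 180-day gap/grace and censoring rules, event date (NaT
    if none), whether the event generated claims, and whether the
    patient should survive cohort exclusion (``cohort_eligible``) and be
    ascertained as a case (``expected_case``).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    day = pd.Timedelta(days=1)
    start_num = cfg.study_start.to_datetime64().astype("datetime64[D]").astype(int)
    end_num = cfg.study_end.to_datetime64().astype("datetime64[D]").astype(int)

    pid = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    male = rng.random(n) < cfg.sex_ratio
    is_user = rng.random(n) < cfg.p_oa_backpain_user

    band = _categorical(rng, cfg.age_distribution, n)
    lo = np.array([_AGE_RANGES[b][0] for b in band])
    hi = np.array([_AGE_RANGES[b][1] for b in band])
    age = lo + rng.random(n) * (hi - lo)

    # entry dates leave >=270 d of observable history and room for follow-up
    t0_lo = start_num + 270
    t0_hi = end_num - 550
    t0_num = rng.integers(t0_lo, t0_hi + 1, size=n)
    birth_num = t0_num - np.round(age * 365.25).astype(int)

    archetype = _categorical(rng, cfg.exposure_archetype_probs, n)
    archetype[~is_user] = "none"
    nsaid_type = _categorical(rng, cfg.nsaid_type_probs, n)
    tpd = _categorical(rng, cfg.tablets_per_day_probs, n).astype(int)
    days_fill = _categorical(rng, cfg.days_per_fill_probs, n).astype(int)
    n_fills = 1 + rng.poisson(cfg.mean_extra_fills, size=n)
    n_fills = np.clip(n_fills, 1, cfg.max_fills)

    # refill gaps: supply-driven jitter, with an occasional long interruption
    mf = cfg.max_fills
    jitter = rng.integers(-3, 31, size=(n, mf))
    gaps = np.maximum(days_fill[:, None] + jitter, 7)
    long_mask = rng.random((n, mf)) < cfg.p_long_refill_gap
    glo, ghi = cfg.long_gap_range_days
    gaps = np.where(long_mask, rng.integers(glo, ghi + 1, size=(n, mf)), gaps)
    gaps[:, 0] = 0
    fill_num = t0_num[:, None] + np.cumsum(gaps, axis=1)
    fill_valid = (np.arange(mf)[None, :] < n_fills[:, None]) & (fill_num <= end_num) & is_user[:, None]

    # episode chain mirrors the gap rule: break at the first gap > gap_days
    chain_break = (gaps > cfg.gap_days) & fill_valid
    in_chain = fill_valid & (np.cumsum(chain_break, axis=1) == 0)
    last_chain_num = np.where(in_chain, fill_num, np.iinfo(np.int64).min).max(axis=1)
    last_chain_num = np.where(is_user, last_chain_num, 0)

    natural_end = np.minimum(last_chain_num + cfg.grace_days, end_num)

    # high-risk drug initiation (censoring)
    if cfg.p_highrisk_drug_start_per_day > 0:
        hr_wait = rng.exponential(1.0 / cfg.p_highrisk_drug_start_per_day, size=n)
    else:
        hr_wait = np.full(n, np.inf)
    hr_days = np.ceil(np.where(np.isfinite(hr_wait), hr_wait, 0.0)).astype(np.int64)
    hr_num = t0_num + hr_days
    has_hr = is_user & np.isfinite(hr_wait) & (hr_num <= end_num)
    censor_num = np.where(has_hr, hr_num - 1, np.iinfo(np.int64).max)
    followup_num = np.minimum(natural_end, censor_num)
    followup_days = followup_num - t0_num
    censor_cause = np.where(
        has_hr & (censor_num < natural_end), "high_risk",
        np.where(natural_end >= end_num, "study_end", "grace_end"),
    )

    # irregular sub-mechanisms (drawn before events; equal thirds among
    # multi-fill patients — single-fill irregulars can only express mismatch)
    sub = np.array([""] * n, dtype=object)
    irr = archetype == "irregular_user"
    sub[irr] = rng.choice(["late_start", "tablet_mismatch", "interrupted"], size=int(irr.sum()))
    sub[irr & (n_fills < 2)] = "tablet_mismatch"

    # bleeding events: the hazard follows the co-prescription pattern as it
    # is *expressed* in the claims, so the category a classifier reads off
    # the history at any index date is the category whose rate generated
    # the event. Late-start and interrupted irregular users therefore carry
    # their pre-deviation rate (non-user / continuous respectively) until
    # the first refill reveals the deviation, and the irregular rate after.
    base = cfg.baseline_bleed_hazard_per_day
    lam_pre = np.full(n, base)
    lam_post = np.full(n, base)
    cont = archetype == "continuous_user"
    lam_pre[cont] = lam_post[cont] = base * cfg.true_or_continuous
    lam_pre[sub == "tablet_mismatch"] = base * cfg.true_or_irregular
    lam_post[sub == "tablet_mismatch"] = base * cfg.true_or_irregular
    lam_pre[sub == "late_start"] = base  # reads as non-user before the refill
    lam_post[sub == "late_start"] = base * cfg.true_or_irregular
    lam_pre[sub == "interrupted"] = base * cfg.true_or_continuous
    lam_post[sub == "interrupted"] = base * cfg.true_or_irregular
    # deviation is expressed at the first refill (offset of fill 2), when emitted
    if mf > 1:
        first_refill = np.where(fill_valid[:, 1], gaps[:, 1], np.iinfo(np.int64).max)
    else:
        first_refill = np.full(n, np.iinfo(np.int64).max)
    switch = np.where(
        (sub == "late_start") | (sub == "interrupted"),
        np.maximum(first_refill - 1, 0).astype(float),
        np.inf,
    )
    e_std = rng.exponential(1.0, size=n)
    h_pre = lam_pre * switch  # cumulative hazard available before the switch
    with np.errstate(invalid="ignore"):  # inf - inf on the unselected branch
        event_wait = np.where(
            e_std <= h_pre, e_std / lam_pre, switch + (e_std - h_pre) / lam_post
        )
    event_offset = np.ceil(event_wait).astype("int64", casting="unsafe", copy=False)
    has_event = is_user & (event_offset >= 1) & (event_offset <= followup_days)
    event_num = np.where(has_event, t0_num + event_offset, 0)
    detected = has_event & (rng.random(n) < cfg.p_event_detected)
    with_hemostasis = detected & (rng.random(n) < cfg.p_hemostasis_claim)

    prior_ulcer = is_user & (rng.random(n) < cfg.p_prior_ulcer)
    comorbid = rng.random(n) < cfg.p_comorbidity

    # ---- claims rows -----------------------------------------------------
    def to_dates(nums: np.ndarray) -> np.ndarray:
        return nums.astype("datetime64[D]").astype("datetime64[ns]")

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": np.where(male, "male", "female"),
            "birth_date": to_dates(birth_num),
            "coverage_start": np.full(n, cfg.study_start.to_datetime64()),
            "coverage_end": pd.Series([pd.NaT] * n, dtype="datetime64[ns]"),
        }
    )
    patients["coverage_start"] = patients["coverage_start"].astype("datetime64[ns]")

    # NSAID fills
    rows = np.nonzero(fill_valid)
    f_pid = pid[rows[0]]
    f_num = fill_num[rows]
    f_tabs = (tpd * days_fill)[rows[0]]
    f_type = nsaid_type[rows[0]]
    f_code = np.array([NSAID_CODE_BY_TYPE[t] for t in f_type], dtype=object)
    f_mg = np.array([DEFAULT_MG_PER_TABLET[c] for c in f_code])
    rx_frames = [
        pd.DataFrame(
            {
                "patient_id": f_pid,
                "dispense_date": to_dates(f_num),
                "drug_code": f_code,
                "tablets": f_tabs.astype(np.int64),
                "total_dose_mg": f_tabs * f_mg,
            }
        )
    ]

    # rebamipide co-prescription per archetype
    arch_row = archetype[rows[0]]
    sub_row = sub[rows[0]]
    fill_rank = rows[1]  # 0-based fill index within patient
    reb_mask = (arch_row == "continuous_user")
    reb_mask |= (sub_row == "late_start") & (fill_rank >= 1)
    reb_mask |= (sub_row == "tablet_mismatch")
    reb_mask |= (sub_row == "interrupted") & (fill_rank != 1)
    reb_tabs = f_tabs.copy()
    mm = sub_row == "tablet_mismatch"
    tpd_row = tpd[rows[0]]
    dfill_row = days_fill[rows[0]]
    reb_tabs[mm] = dfill_row[mm] * np.where(tpd_row[mm] < 3, 3, 2)
    rx_frames.append(
        pd.DataFrame(
            {
                "patient_id": f_pid[reb_mask],
                "dispense_date": to_dates(f_num[reb_mask]),
                "drug_code": "REBAMIPIDE100",
                "tablets": reb_tabs[reb_mask].astype(np.int64),
                "total_dose_mg": reb_tabs[reb_mask] * 100.0,
            }
        )
    )

    # high-risk drug initiations
    if has_hr.any():
        rx_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid[has_hr],
                    "dispense_date": to_dates(hr_num[has_hr]),
                    "drug_code": "WARFARIN",
                    "tablets": np.int64(28),
                    "total_dose_mg": 28.0,
                }
            )
        )
    prescriptions = pd.concat(rx_frames, ignore_index=True)

    # ---- diagnoses -------------------------------------------------------
    def month_str(nums: np.ndarray) -> np.ndarray:
        d = nums.astype("datetime64[D]")
        return np.datetime_as_string(d, unit="M")

    dx_frames = []
    # background history for everyone (well before any entry window)
    bg_num = np.where(
        is_user,
        t0_num - rng.integers(120, 400, size=n),
        start_num + rng.integers(0, 365, size=n),
    )
    bg_num = np.maximum(bg_num, start_num)
    bg_code = rng.choice(np.array(_BACKGROUND_DX, dtype=object), size=n)
    dx_frames.append(pd.DataFrame({"patient_id": pid, "month": month_str(bg_num), "icd10": bg_code}))
    # chronic comorbidities (Charlson material), before entry
    if comorbid.any():
        cm_num = np.where(is_user, t0_num, start_num + 365) - rng.integers(60, 300, size=n)
        cm_num = np.maximum(cm_num, start_num)
        cm_code = rng.choice(np.array(["E119", "I50", "J449"], dtype=object), size=n, p=[0.5, 0.25, 0.25])
        dx_frames.append(
            pd.DataFrame(
                {"patient_id": pid[comorbid], "month": month_str(cm_num[comorbid]), "icd10": cm_code[comorbid]}
            )
        )
    # prior ulcer history (exclusion criterion 3)
    if prior_ulcer.any():
        pu_num = np.maximum(t0_num - rng.integers(60, 300, size=n), start_num)
        dx_frames.append(
            pd.DataFrame({"patient_id": pid[prior_ulcer], "month": month_str(pu_num[prior_ulcer]), "icd10": "K25"})
        )
    # indication coded in the entry month and sporadically at refills
    oa_code = rng.choice(np.array(_OA_CODES, dtype=object), size=n, p=_OA_PROBS)
    user_idx = np.nonzero(is_user)[0]
    dx_frames.append(
        pd.DataFrame(
            {"patient_id": pid[user_idx], "month": month_str(t0_num[user_idx]), "icd10": oa_code[user_idx]}
        )
    )
    recode = rng.random(len(f_pid)) < 0.6
    dx_frames.append(
        pd.DataFrame(
            {"patient_id": f_pid[recode], "month": month_str(f_num[recode]), "icd10": oa_code[rows[0]][recode]}
        )
    )
    # bleeding diagnosis in the event month for detected events
    ugib_code = rng.choice(np.array(_UGIB_CODES, dtype=object), size=n, p=_UGIB_PROBS)
    if detected.any():
        dx_frames.append(
            pd.DataFrame(
                {"patient_id": pid[detected], "month": month_str(event_num[detected]), "icd10": ugib_code[detected]}
            )
        )
    diagnoses = pd.concat(dx_frames, ignore_index=True).drop_duplicates().reset_index(drop=True)

    # ---- procedures ------------------------------------------------------
    pr_frames = []
    if detected.any():
        pr_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid[detected],
                    "service_date": to_dates(event_num[detected]),
                    "treatment_code": "160093810",
                }
            )
        )
    if with_hemostasis.any():
        pr_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid[with_hemostasis],
                    "service_date": to_dates(event_num[with_hemostasis]),
                    "treatment_code": "150164850",
                }
            )
        )
    if pr_frames:
        procedures = pd.concat(pr_frames, ignore_index=True)
    else:
        procedures = pd.DataFrame(
            {
                "patient_id": pd.Series(dtype=object),
                "service_date": pd.Series(dtype="datetime64[ns]"),
                "treatment_code": pd.Series(dtype=object),
            }
        )

    codelists = CodeLists()
    prescriptions = annotate_drug_columns(prescriptions, codelists)
    bundle = ClaimsBundle(
        patients=patients,
        diagnoses=diagnoses,
        prescriptions=prescriptions,
        procedures=procedures,
        codelists=codelists,
        study_start=cfg.study_start,
        study_end=cfg.study_end,
    )
    bundle.check_invariants()

    cohort_eligible = is_user & ~prior_ulcer
    t0_dates = to_dates(t0_num)
    t0_dates[~is_user] = np.datetime64("NaT")
    fup_dates = to_dates(followup_num)
    fup_dates[~is_user] = np.datetime64("NaT")
    ev_dates = to_dates(event_num)
    ev_dates[~has_event] = np.datetime64("NaT")
    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "is_user": is_user,
            "archetype": archetype,
            "sub_mechanism": sub,
            "t0": t0_dates,
            "followup_end": fup_dates,
            "followup_days": np.where(is_user, followup_days, 0),
            "censor_cause": np.where(is_user, censor_cause, ""),
            "event_date": ev_dates,
            "event_detected": detected,
            # offset (days from t0) at which a late-start / interrupted
            # deviation becomes visible in the claims; inf = never expressed
            "mechanism_offset": np.where(
                (sub == "late_start") | (sub == "interrupted"),
                np.where(first_refill < np.iinfo(np.int64).max, first_refill.astype(float), np.inf),
                0.0,
            ),
            "cohort_eligible": cohort_eligible,
            "expected_case": cohort_eligible & detected,
            "age_at_t0": age,
            "sex": np.where(male, "male", "female"),
            "nsaid_type": np.where(is_user, nsaid_type, ""),
        }
    )
    return bundle, truth
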