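# Methods

This note documents the statistical model, the rules the pipeline
implements, the synthetic data generator's assumptions, and the
numerical and design choices a maintainer would want to know.

## Design and estimand

The package implements a nested case-control study with
incidence-density (risk-set) sampling inside a new-user cohort. Controls
are sampled from the members still at risk at each case's event time, so
the matched odds ratio estimates the incidence rate ratio without any
rare-disease assumption. Matched sets are analysed by conditional
logistic regression, with the matched-set identifier as the only
stratification variable: matching factors (sex, age, follow-up duration,
NSAID quantity/type profile) are balanced by design and are not entered
again as covariates. The exposure of interest is the rebamipide
co-prescription pattern from cohort entry to the index date, as a
three-level factor with Non-user as the fixed reference.

## Cohort rules

* **Entry (t0)** — the earliest NSAID dispense in a calendar month that
  also carries an osteoarthritis (M16–M19) or back-pain (M54) diagnosis.
  One entry per patient. Diagnoses carry month granularity only, which
  is the resolution of the claims model; "same month" linkage is exact.
* **Look-back window** — the 90 days before entry (dispense-level dates;
  criterion-specific spans where the rule says "before t0" or "any
  history"). The seven exclusions are evaluated in their enumerated order
  and a candidate is counted only under the first criterion that fires,
  so the report reads as a selection cascade.
* **Month-granularity conventions** — a diagnosis month is dated at its
  first day when a rule needs a day-level comparison (criterion 1);
  diagnosis *history* rules (criterion 3, Charlson) count months
  strictly before the calendar month of the reference date. Counting
  the entry month itself would let a same-month outcome code
  (K250 ⊂ K25) retroactively exclude the earliest cases, contradicting
  the outcome window that opens the day after entry.
* **Follow-up** — NSAID fills are chained while consecutive fills are at
  most 180 days apart (a 181-day gap starts a new, ignored episode);
  follow-up ends 180 days after the last chained fill, truncated at the
  study end and at the day before the first post-entry dispense of an
  anticoagulant, antiplatelet, steroid or bisphosphonate.
* **Age** — (t0 − birth date)/365.25, in fractional years.

## Outcome and sampling

A case is the earliest procedure claim in (t0, follow-up end] bearing a
gastroscopy or hemostasis treatment code with an upper-GI-bleeding
ICD-10 code recorded in the same calendar month; same-day ties report
the gastroscopy code. Events after censoring never qualify.

Control eligibility for a case at duration offset d (= index date − t0):
any other cohort member whose follow-up covers d and whose own event, if
any, occurs strictly after d — i.e. the textbook risk set on the
time-since-entry axis. Duration alignment makes the follow-up matching
caliper (±180 days) hold identically; it is still recorded in the audit
columns. Additional matching: same sex; |age difference| ≤ 5 years;
cumulative NSAID tablets to offset d equal when the case's total is ≤ 10
tablets, otherwise within ±20%; per-drug cumulative dose with the same
zero/nonzero pattern and each nonzero total within ±25%. The dose and
tablet calipers are package defaults (configurable): exact matching on
continuous dose would make 10 controls per case infeasible, and the
design this models demonstrably did not match doses exactly (case and
control dose distributions differ). Up to 10 eligible members are drawn
uniformly without replacement per set; members may serve repeatedly
across sets and later become cases. Cases with zero eligible controls
are dropped and logged.

## Exposure classification

Over [t0, evaluation date], with same-day dispensings summed per date:
Non-user if no rebamipide was dispensed; Continuous-user if rebamipide
was dispensed on t0, every NSAID fill date has a same-day rebamipide
dispense with an equal tablet count, and no rebamipide-only date occurs
while NSAID therapy is active (rebamipide after the last NSAID fill of
the window — i.e. during the trailing grace period — is tolerated);
Irregular-user otherwise. The per-date rule is deliberate: the
archetypal misuse pattern (NSAID twice daily, rebamipide three times
daily) is invisible to cumulative totals at some windows; a relaxed
cumulative mode exists for sensitivity exploration. Same-date pairing is
strict; a one-day pharmacy split would read as irregular, and is noted
as a limitation.

## Conditional logistic regression

The conditional likelihood for 1:M sets, one case per stratum s:
ℓ(β) = Σₛ [x_case·β − log Σ_{j∈s} exp(x_j·β)]. Score and observed
information are analytic; strata whose covariate rows are all identical
are dropped (counted in `n_strata_dropped`) since they contribute a
constant. Maximisation is Newton–Raphson from β = 0 with step-halving
(up to 40 halvings per step), convergence at max |score| < 1e-8 within
50 iterations; the covariance is the inverse information at the optimum.
Coefficients whose indicator column shows no variation in informative
strata are reported inestimable (NaN) rather than fitted. Divergence of
|β| beyond 15 raises an explicit complete-separation error, as does a
singular information matrix. Wald 95% intervals are the default
reporting style; profile-likelihood intervals are available
(`profile_ci`) via likelihood-ratio inversion with bisection. Crude ORs
use the 2×2 cross-product against the reference row with Woolf
intervals, exp(ln OR ± 1.96·√Σ 1/cell); a zero cell raises instead of
silently applying a continuity correction.

The 1:1 binary special case reduces to the discordant-pair ratio
exactly; tests verify this, plus agreement with finite differences, a
dense grid search, the Mantel–Haenszel pooled OR and an external
conditional-logit implementation.

## The synthetic claims generator

The generator is first-class, tested code: it defines the conditions
under which every downstream claim about the pipeline is demonstrated.

What it emulates, and the defaults (all configurable in
`SimulationConfig`):

* **Population** — sex-balanced; age mixture 12.5% ≤ 64, 33.5% 65–74,
  39.5% 75–84, 14.5% ≥ 85 (uniform within band), mirroring the elderly
  orthopaedic control distribution of the modelled study; 80% of
  patients become NSAID new users with an indication diagnosis coded in
  the entry month.
* **Dispensing** — NSAID type mix 70/22/5/2/1% across loxoprofen,
  celecoxib, diclofenac, meloxicam, ibuprofen; 1–3 tablets/day; 7–60
  days per fill; mean 4.5 fills; refill gaps follow the days supplied
  plus jitter, with a 12% chance of a 150–260-day interruption so the
  180-day chaining rule is exercised on both sides of the boundary.
* **Archetypes** — 48% non-user, 39% continuous, 13% irregular (the
  observed control mix); irregular users express one of three
  sub-mechanisms with equal probability: late start (rebamipide from the
  second fill), tablet mismatch from t0 (three-a-day rebamipide against
  fewer NSAID tablets), or an interrupted refill (rebamipide skipped at
  the second fill). Single-fill irregular users can only express
  mismatch and are assigned it.
* **Events** — per-day hazard, baseline 1.6e-5/day (≈ 0.5% cumulative
  incidence over a typical episode, matching the case-candidate rate the
  modelled study reports), multiplied by the rate ratio of the category
  *expressed in the claims up to that day*: 1 for a non-user pattern,
  0.65 (default `true_or_continuous`) for a continuous pattern, 2.57
  (default `true_or_irregular`) for an expressed irregular pattern.
  Late-start and interrupted users therefore carry their pre-deviation
  rate until the first refill reveals the deviation. This choice makes
  the generative model causally coherent — two patients with identical
  claims histories have identical hazards — and makes the category a
  classifier reads at any index date exactly the category whose rate
  generated events then, which is also how the design being modelled
  defines exposure. Detected events (probability 1 by default) emit a
  gastroscopy claim, a hemostatic claim with probability 0.2, and a
  same-month bleeding diagnosis.
* **Censoring and exclusions** — high-risk drug initiation at 1.5e-4/day
  (≈ 5%/year); 3% prior-ulcer history exercising exclusion 3; 10%
  chronic comorbidity codes feeding the Charlson sensitivity analyses.

What it does **not** emulate: dose titration or switching between NSAID
types within a patient; enrollment gaps and plan switching; diagnostic
miscoding and rule-out codes; bleeding from causes unrelated to therapy;
hazard variation over age or season; care-seeking differences between
archetypes (confounding is absent by construction). Passing
parameter-recovery tests therefore demonstrate that the pipeline
estimates what the design intends under its own assumptions — not that
real claims data would be free of confounding or misclassification.

## Problem sizes and experiment conventions

Parameter recovery runs the full pipeline on 50 replicates of 50,000
patients (≈ 190 cases each) and requires 95% Wald CI coverage of both
true log-rate-ratios in ≥ 90% of replicates with median point estimates
within 0.10 on the log scale. Null calibration (both ratios 1.0) uses 50
replicates of 20,000 patients — the quantity checked is a rejection
rate, which does not need the larger cohort — and requires |z| > 1.96 in
at most 10% of coefficient tests. The acceptance script reports medians
over 15 replicates of 50,000 patients. All randomness derives from
explicit seeds; the control sampler uses a fixed offset substream of the
root seed so stages are independently reproducible.

## Known limitations

* Exposure misclassification before an irregular deviation is expressed
  is inherent to the negatively-defined Irregular category (as in the
  design being modelled); the generator's expressed-category hazard
  makes the estimand well defined despite it.
* The strict same-day pairing rule for rebamipide may over-call
  irregularity on real data where dispensings split across days.
* Criterion 2 accepts any osteoarthritis/back-pain code in the dispense
  month, not specifically the entry diagnosis; "medical records" in
  criterion 1 means any claim type. Both readings are configurable
  points in the code, flagged rather than silently assumed.
* No exact conditional inference for sparse strata and no robust
  variance; sets are assumed complete (claims have no missingness by
  construction).
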