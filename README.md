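# nestedcc

Nested case-control analysis of drug co-prescription safety in
longitudinal medical claims data.

## The problem

Gastroprotective drugs such as rebamipide are routinely co-prescribed
with NSAIDs to prevent upper gastrointestinal bleeding, but their
real-world effectiveness in low-risk patients has to be estimated from
routinely collected claims. The natural design is a **nested
case-control study with incidence-density sampling**: build a new-user
cohort of NSAID initiators from dispensing and diagnosis records, find
the members who bleed, and compare each case's co-prescription pattern
with that of matched controls drawn from the members still at risk at
the case's event time. The odds ratio from this sampling scheme
estimates the incidence rate ratio.

`nestedcc` implements that design end to end, for epidemiologists who
work with long-format claims tables:

* **Cohort construction** — entry (t0) at the first NSAID dispense with
  a same-calendar-month osteoarthritis / back-pain diagnosis; seven
  new-user exclusion criteria over a 90-day look-back; follow-up built
  from refill episodes (fills chained while ≤ 180 days apart, plus a
  180-day grace period) and censored the day before the first dispense
  of anticoagulants, antiplatelets, steroids or bisphosphonates.
* **Outcome ascertainment** — a case is a gastroscopy or hemostatic
  procedure claim strictly after t0 and within follow-up, with an
  upper-GI-bleeding ICD-10 code recorded in the same calendar month.
* **Risk-set sampling** — up to 10 controls per case, drawn uniformly
  from members at risk at the case's time-since-entry, matched on sex,
  age (±5 years) and the NSAID exposure profile accumulated to that
  offset (total tablets; per-drug total dose of loxoprofen, celecoxib,
  diclofenac, meloxicam and ibuprofen).
* **Exposure classification** — each member's rebamipide pattern over
  [t0, index date] is labelled Non-user (never co-prescribed),
  Continuous-user (co-prescribed from t0 at every NSAID fill with a
  matching tablet count) or Irregular-user (anything else).
* **Matched analysis** — a hand-implemented conditional logistic
  regression for 1:M matched sets. With one case per stratum s and
  indicator covariates x, the conditional likelihood is

  L(β) = ∏ₛ exp(x_case β) / Σ_{j∈s} exp(x_j β),

  maximised by Newton–Raphson with analytic score and information;
  Wald and profile-likelihood CIs; crude ORs with Woolf intervals;
  subgroup refits (age, index NSAID) and Charlson-restricted
  sensitivity cohorts (Quan ICD-10 coding, original weights).
* **Synthetic claims generator** — populations with known ground truth
  (archetype mix, refill behaviour, configurable rate ratios for
  continuous and irregular use) so every stage is testable without any
  real data, which for this design is not publicly distributable.

## A worked example

```python
from nestedcc import SimulationConfig, simulate_bundle, run_study

bundle, truth = simulate_bundle(SimulationConfig(n_patients=30_000, seed=3))
result = run_study(bundle)
print(result.exposure_table.report())
```

prints (seed 3):

```
Prescription status  Case  (%)    Control  (%)   Crude OR (95% CI)   Adjusted OR (95% CI)
non_user               55 (45.1)    548 (46.6)  1 (reference)   1 (reference)
continuous_user        35 (28.7)    483 (41.1)  0.72 (0.46-1.12)   0.71 (0.46-1.11)
irregular_user         32 (26.2)    145 (12.3)  2.20 (1.37-3.53)   2.26 (1.38-3.69)
```

The generator's true rate ratios here are 0.65 (continuous vs non-use)
and 2.57 (irregular vs non-use); the adjusted column is the conditional
logistic estimate over the 122 matched sets, and its 95% Wald intervals
cover those truths. Continuous co-prescription reads as protective;
an irregular pattern flags elevated risk, partly because rebamipide
started in response to early symptoms lands in that category.

The crude machinery reproduces published-table arithmetic directly — see
`examples/04_crude_from_published_counts.py`, which turns the 3×2 counts
93/724, 52/597, 70/195 into crude ORs 0.68 (0.47–0.97) and 2.79.

Each `examples/*.py` script covers one capability (simulation, cohort
construction, the matched analysis, crude tables, subgroups and
sensitivity cohorts) and prints what the numbers mean. A thin CLI wraps
the same stages for shell use:

```bash
nestedcc simulate out/ --n-patients 10000 --seed 1
nestedcc run-all config.yaml out/
```

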