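"""Subgroup analyses and the comorbidity-restricted sensitivity cohort.

Subgroups split whole matched sets by the case's age (< 65 / >= 65) or
index NSAID; the sensitivity analysis re-runs the pipeline excluding
members with a Charlson comorbidity index of 1 or more at entry.
"""

from nestedcc import SimulationConfig, simulate_bundle, run_study, run_subgroup

bundle, _ = simulate_bundle(SimulationConfig(n_patients=30_000, seed=5))
result = run_study(bundle)
print("main analysis:")
print(result.exposure_table.report())

for name, res in run_subgroup(result.matched_sets, "age").items():
    print(f"\nsubgroup {name} ({res.table.n_cases} cases):")
    print(res.report())

strict = run_study(bundle, charlson_max=1)
print(f"\nCharlson < 1 sensitivity cohort: {len(strict.cohort)} members "
      f"(vs {len(result.cohort)}), {len(strict.cases)} cases")
if strict.exposure_table is not None:
    print(strict.exposure_table.report())

# Subgroup estimates scatter around the common truth with wider CIs;
# the comorbidity restriction removes ~13% of members and should leave
# the matched odds ratios essentially unchanged, as in the study design.
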