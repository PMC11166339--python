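"""Generate a synthetic claims population and inspect its structure.

The generator emulates a claims database of new NSAID users for
osteoarthritis / back pain: refill episodes, rebamipide co-prescription
archetypes, censoring drugs, and upper-GI-bleeding events whose hazard
follows the expressed co-prescription pattern.
"""

from nestedcc import SimulationConfig, simulate_bundle

cfg = SimulationConfig(n_patients=5000, seed=1)
bundle, truth = simulate_bundle(cfg)

users = truth[truth["is_user"]]
print(f"patients: {bundle.n_patients}, NSAID new users: {len(users)}")
print(f"prescription rows: {len(bundle.prescriptions)}")
print("archetype mix among users:")
print(users["archetype"].value_counts(normalize=True).round(3).to_string())
print(f"true bleeding events: {users['event_date'].notna().sum()} "
      f"({100 * users['event_date'].notna().mean():.2f}% of users)")

# The archetype mix mirrors the control distribution of the study this
# pipeline models (~48% never co-prescribed, ~39% continuous, ~13% irregular),
# and the event fraction sits near the 0.5% case-candidate rate it reports.
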