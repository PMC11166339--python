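"""Full nested case-control analysis on a synthetic population.

Cases (gastroscopy / hemostasis claim + same-month bleeding diagnosis)
are matched to up to 10 risk-set controls on sex, age and NSAID exposure
profile; members are classified Non- / Continuous- / Irregular-user by
their rebamipide pattern; a hand-implemented conditional logistic
regression estimates the matched odds ratios.
"""

from nestedcc import SimulationConfig, simulate_bundle, run_study

# ground truth: continuous co-prescription protects (OR 0.65),
# irregular co-prescription signals risk (OR 2.57)
bundle, truth = simulate_bundle(SimulationConfig(n_patients=30_000, seed=3))
result = run_study(bundle)

print(f"cohort {len(result.cohort)}, cases {len(result.cases)}, "
      f"matched sets {result.sampling_log.n_matched} "
      f"(dropped {len(result.sampling_log.dropped)} without eligible controls)\n")
print(result.exposure_table.report())

fit = result.fit
print(f"\nCLR diagnostics: converged={fit.converged} in {fit.iterations} "
      f"iterations, {fit.n_strata_dropped} concordant sets dropped")

# The adjusted odds ratios estimate the generator's true rate ratios
# (0.65 and 2.57); with ~100 cases a single replicate's CI is wide, and
# the Wald intervals should cover the truths about 95% of the time.
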