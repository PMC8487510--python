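"""Fit the longitudinal GRM to a small synthetic cohort by MCMC.

A deliberately small run (200 subjects, short chains) to show the
workflow; recovery experiments at n=500+ with longer chains live in the
test suite and acceptance script.
"""

from adlirt import (
    GeneratorConfig,
    McmcConfig,
    convergence_diagnostics,
    generate_dataset,
    run_mcmc,
    summarize_posterior,
)

dataset, truth = generate_dataset(GeneratorConfig(n_subjects=200, n_visits=4, seed=7))
chains = run_mcmc(dataset, McmcConfig(n_burnin=1000, n_keep=1000, n_chains=2, seed=11))

summary = summarize_posterior(chains)
structural = summary[summary.level == "structural"]
print(structural.to_string(index=False, float_format=lambda v: f"{v:8.3f}"))

diag = convergence_diagnostics(chains)
print(f"\nmax structural R-hat: {diag.rhat.max():.3f}")
print(f"true mu = {truth.mu}, posterior mean mu = "
      f"{float(chains.pooled('mu').mean()):.3f}")
# Posterior means should track the generating item parameters and mean
# slope; widen the chains and the cohort for tighter recovery.
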