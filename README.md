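# adlirt

Longitudinal item response theory for the Katz activities-of-daily-living
(ADL) scale: the hierarchical order in which elderly people lose basic
self-care abilities, and their disability trajectories in the years before
death.

The package is aimed at biostatisticians and epidemiologists working with
end-of-life disability panels (e.g. the CLHLS cohort, whose raw data is
agreement-gated). Because such data cannot ship with code, the package
includes a first-class synthetic cohort generator with a known generating
truth, so every stage of the analysis is validated by parameter recovery.

## Model

Each of the six Katz items (bathing, dressing, toileting, transferring,
continence, feeding) is scored 0 (no limitation), 1 (partial), 2 (totally
limited). Responses follow Samejima's graded response model with cumulative
logistic curves

```
P(Y_sti ≥ k | θ_st) = logistic(α_i θ_st − κ_ik),   k ∈ {partial, total}
```

where α_i > 0 is the item discrimination and κ_i,partial < κ_i,total are
ordered difficulty thresholds on the latent disability scale (larger θ =
more disabled; smaller κ = ability lost earlier). The latent trait is linear
in time since first interview,

```
θ_st = γ0_s + γ1_s t,     γ1_s = γ1′_s + Z_s β,
γ0_s ~ N(0, 1),           γ1′_s ~ N(μ, σ_slope²),
```

with Z_s the standardized covariates (sex, baseline age, residence,
education, marital status) and μ the population mean decline per year.
Estimation is Bayesian via an adaptive Metropolis-within-Gibbs sampler; the
N(0,1) prior on γ0_s anchors the latent scale.

Sorting the 12 posterior-mean thresholds yields the ADL **loss hierarchy**;
κ_total − κ_partial per item is the **threshold gap**. For trajectories the
per-visit posterior mean θ is rescaled to [−3, 3], indexed by years before
death, and fitted with a random-intercept/random-slope mixed model
(maximum likelihood) to produce covariate-adjusted group curves.

## Worked example

```python
from adlirt import entries_from_item_parameters, rank_thresholds, threshold_gap
from adlirt.data_model import KatzItem
from adlirt.reference import REFERENCE_ITEM_PARAMS

entries = entries_from_item_parameters(REFERENCE_ITEM_PARAMS)
ranked = rank_thresholds(entries)
print(ranked[0].label, ranked[0].kappa)   # bathing_partial -1.396
print(ranked[-1].label, ranked[-1].kappa) # continence_total 3.647
print(threshold_gap(entries, KatzItem.TOILETING))  # 4.252
```

Loss of ability begins with partial limitation in bathing (κ = −1.396) and
ends with total loss of continence (κ = 3.647). Toileting's gap of 4.252
latent units is the widest: it stays at partial limitation across most of
the severity continuum, while dressing's gap (0.759) is the narrowest.

The `examples/` directory holds one short script per capability —
simulation, item response curves, hierarchy extraction, MCMC fitting,
trajectory modelling — each printing the numbers it computes. A thin CLI
(`adlirt simulate | fit-lirt | hierarchy | trajectory | run-all |
validate-config`) wraps the same functions for shell use.

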