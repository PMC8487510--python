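"""Reference estimates from the CLHLS decedent cohort.

Posterior means (with posterior SDs and 95% credible bounds) for the
six Katz items from a Bayesian longitudinal graded-response analysis of
28,345 Chinese adults aged 60+ followed until death, together with the
cohort's baseline marginals.  These numbers serve two roles:

* default generating truth for the synthetic-panel module, so that
  simulated cohorts resemble the real end-of-life disability process;
* inputs for worked examples (threshold gaps, loss hierarchy,
  discrimination bands) that exercise the analysis modules on published
  values without access to the restricted survey data.
"""

from __future__ import annotations

from .data_model import KATZ_ITEMS, KatzItem
from .grm import ItemParameters

__all__ = [
    "REFERENCE_ALPHA",
    "REFERENCE_KAPPA",
    "REFERENCE_ITEM_PARAMS",
    "REFERENCE_SLOPE_MU",
    "REFERENCE_SLOPE_BETA",
    "COHORT",
    "reference_item_parameters",
]

# Discrimination posterior means (alpha): (mean, sd, q2.5, q97.5)
REFERENCE_ALPHA: dict[KatzItem, tuple[float, float, float, float]] = {
    KatzItem.BATHING: (1.291, 0.003, 1.261, 1.317),
    KatzItem.DRESSING: (2.877, 0.007, 2.810, 2.917),
    KatzItem.TOILETING: (4.124, 0.015, 3.984, 4.286),
    KatzItem.TRANSFERRING: (3.682, 0.007, 3.565, 3.783),
    KatzItem.CONTINENCE: (1.125, 0.003, 1.077, 1.168),
    KatzItem.FEEDING: (2.137, 0.004, 2.071, 2.197),
}

# Difficulty posterior means (kappa): {item: {level: (mean, sd, q2.5, q97.5)}}
# Orientation: P(Y >= k) = logistic(alpha * theta - kappa_k); smaller kappa
# means the ability is lost earlier on the disability continuum.
REFERENCE_KAPPA: dict[KatzItem, dict[str, tuple[float, float, float, float]]] = {
    KatzItem.BATHING: {
        "partial": (-1.396, 0.003, -1.433, -1.364),
        "total": (-0.374, 0.003, -0.406, -0.366),
    },
    KatzItem.DRESSING: {
        "partial": (-0.277, 0.004, -0.315, -0.238),
        "total": (0.482, 0.004, 0.441, 0.520),
    },
    KatzItem.TOILETING: {
        "partial": (-0.904, 0.006, -0.953, -0.843),
        "total": (3.348, 0.009, 3.238, 3.478),
    },
    KatzItem.TRANSFERRING: {
        "partial": (-0.053, 0.004, -0.082, -0.017),
        "total": (3.454, 0.008, 3.325, 3.562),
    },
    KatzItem.CONTINENCE: {
        "partial": (1.371, 0.003, 1.324, 1.409),
        "total": (3.647, 0.013, 3.535, 3.739),
    },
    KatzItem.FEEDING: {
        "partial": (0.917, 0.005, 0.884, 0.962),
        "total": (3.440, 0.004, 3.351, 3.521),
    },
}

# Population mean of the subject slope deviations (latent units / year).
REFERENCE_SLOPE_MU = 0.857

# Slope regression coefficients in covariate order
# (sex, age_std, residence, education_std, marital); binaries coded
# sex 0=male/1=female, residence 0=urban/1=rural, marital 0=spouse/1=none.
REFERENCE_SLOPE_BETA = (0.102, 0.889, -0.591, -0.730, 0.056)

# Baseline cohort composition (decedents aged 60+ with >=1 Katz record).
COHORT = {
    "n_candidates": 28_390,
    "n_incomplete_covariates": 45,
    "n_included": 28_345,
    "n_female": 17_065,
    "n_male": 11_280,
    "n_rural": 17_897,
    "n_urban": 10_448,
    "n_no_spouse": 22_901,
    "n_spouse": 5_444,
    "female_frac": 0.602,
    "rural_frac": 0.631,
    "no_spouse_frac": 0.808,
    "age_mean": 91.3,
    "age_sd": 9.6,
    "education_mean": 1.4,
    "education_sd": 2.9,
    "median_followup_years": 3.0,
    "max_followup_years": 19.0,
}


def reference_item_parameters() -> dict[KatzItem, ItemParameters]:
    """Posterior-mean item parameters for all six Katz items."""
    return {
        item: ItemParameters(
            item=item,
            alpha=REFERENCE_ALPHA[item][0],
            kappa_partial=REFERENCE_KAPPA[item]["partial"][0],
            kappa_total=REFERENCE_KAPPA[item]["total"][0],
        )
        for item in KATZ_ITEMS
    }


REFERENCE_ITEM_PARAMS: dict[KatzItem, ItemParameters] = reference_item_parameters()
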