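"""Bayesian estimation of the longitudinal graded-response model.

The latent disability of subject *s* at time *t* (years since first
interview) is

    theta_{s,t} = gamma0_s + gamma1_s * t,
    gamma1_s = gamma1'_s + Z_s beta,

with gamma0_s ~ N(0, 1) anchoring the latent scale, the slope deviation
gamma1'_s ~ N(mu, slope_sd²) pooled hierarchically, and Z_s the
standardized covariate vector (sex, age, residence, education, marital
status).  Item responses follow the graded-response model of
:mod:`adlirt.grm`.  Posterior sampling uses an adaptive
Metropolis-within-Gibbs kernel (see :mod:`adlirt._mcmc`); summaries are
posterior means, posterior SDs (reported as SE) and central 95%
credible intervals, mirroring the conventional reporting format.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import arviz as az
import numpy as np
import pandas as pd

from ._mcmc import (
    ChainResult,
    PackedPanel,
    PriorSettings,
    SamplerSettings,
    pack_panel,
    run_chain,
)
from .data_model import (
    COVARIATE_NAMES,
    KATZ_ITEMS,
    KatzItem,
    PanelDataset,
    ValidationError,
    covariate_matrix,
)
from .grm import ItemParameters, panel_loglik

__all__ = [
    "LirtParameters",
    "McmcConfig",
    "McmcChains",
    "PriorSettings",
    "log_prior",
    "log_posterior",
    "run_mcmc",
    "summarize_posterior",
    "convergence_diagnostics",
    "STRUCTURAL_PARAMETERS",
]

#: Names of the structural (non-subject-level) parameter chains.
STRUCTURAL_PARAMETERS: tuple[str, ...] = tuple(
    [f"alpha[{it.value}]" for it in KATZ_ITEMS]
    + [f"kappa_partial[{it.value}]" for it in KATZ_ITEMS]
    + [f"kappa_total[{it.value}]" for it in KATZ_ITEMS]
    + ["mu"]
    + [f"beta[{name}]" for name in COVARIATE_NAMES]
    + ["slope_sd"]
)


@dataclass
class LirtParameters:
    """One full parameter state of the longitudinal GRM."""

    items: dict[KatzItem, ItemParameters]
    gamma0: np.ndarray
    gamma1_raw: np.ndarray
    mu: float
    beta: np.ndarray
    slope_sd: float

    def gamma1(self, Z: np.ndarray) -> np.ndarray:
        """Total subject slopes gamma1 = gamma1' + Z beta."""
        return self.gamma1_raw + Z @ np.asarray(self.beta, float)


@dataclass
class McmcConfig:
    """Sampler protocol: burn-in, retained draws, thinning, chains.

    The defaults (4000 burn-in, 1000 kept, thin 1) match the standard
    protocol for this model; recovery experiments configure their own
    lengths.  Proposal adaptation runs during burn-in only.
    """

    n_burnin: int = 4000
    n_keep: int = 1000
    thin: int = 1
    n_chains: int = 2
    seed: int = 0
    store_subject_draws: bool = False
    sampler: SamplerSettings = field(default_factory=SamplerSettings)

    def validate(self) -> "McmcConfig":
        if self.n_burnin < 0 or self.n_keep <= 0:
            raise ValidationError("n_burnin must be >= 0 and n_keep > 0")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        return self


@dataclass
class McmcChains:
    """Retained draws plus subject-level posterior mean accumulators.

    ``structural`` maps parameter name → array of shape
    ``(n_chains, n_keep)``.  Subject-level states (gamma0, gamma1,
    gamma1', theta per visit) are tracked as chain-pooled posterior
    means; full per-subject draws are stored only when requested.
    """

    structural: dict[str, np.ndarray]
    subject_ids: list[str]
    gamma0_mean: np.ndarray
    gamma1_mean: np.ndarray
    gamma1_raw_mean: np.ndarray
    theta_mean: dict[tuple[str, float], float]
    gamma0_draws: Optional[np.ndarray]  # (n_chains, n_keep, n_subjects)
    gamma1_draws: Optional[np.ndarray]
    accept_rates: dict[str, float]
    config: McmcConfig

    @property
    def n_chains(self) -> int:
        return next(iter(self.structural.values())).shape[0]

    @property
    def n_keep(self) -> int:
        return next(iter(self.structural.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        return self.structural[name].reshape(-1)

    def item_parameters(self) -> dict[KatzItem, ItemParameters]:
        """Posterior-mean item parameters."""
        return {
            it: ItemParameters(
                item=it,
                alpha=float(self.pooled(f"alpha[{it.value}]").mean()),
                kappa_partial=float(self.pooled(f"kappa_partial[{it.value}]").mean()),
                kappa_total=float(self.pooled(f"kappa_total[{it.value}]").mean()),
            )
            for it in KATZ_ITEMS
        }


def _norm_logpdf(x: np.ndarray | float, mean: float | np.ndarray, sd: float) -> float:
    x = np.asarray(x, float)
    return float(
        np.sum(-0.5 * ((x - mean) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi))
    )


def log_prior(params: LirtParameters, prior: Optional[PriorSettings] = None) -> float:
    """Joint log prior density of a parameter state.

    Structure: gamma0_s ~ N(0, 1); gamma1'_s ~ N(mu, slope_sd²)
    (hierarchical); alpha_i ~ LogNormal(0, 1); kappa_partial_i ~
    N(0, 10²) with the threshold gap delta_i ~ LogNormal(0, 1); mu and
    each beta_j ~ N(0, 10²); slope_sd ~ HalfNormal(5).  Returns ``-inf``
    outside the support (non-positive alpha, delta or slope_sd).
    """
    prior = prior or PriorSettings()
    if params.slope_sd <= 0:
        return -math.inf
    total = 0.0
    for it in KATZ_ITEMS:
        p = params.items[it]
        if p.alpha <= 0 or p.kappa_total <= p.kappa_partial:
            return -math.inf
        la = math.log(p.alpha)
        ld = math.log(p.kappa_total - p.kappa_partial)
        # LogNormal(0, s) density at x: N(log x; 0, s) / x
        total += _norm_logpdf(la, 0.0, prior.alpha_logsd) - la
        total += _norm_logpdf(p.kappa_partial, 0.0, prior.kappa_sd)
        total += _norm_logpdf(ld, 0.0, prior.delta_logsd) - ld
    total += _norm_logpdf(params.gamma0, 0.0, prior.gamma0_sd)
    total += _norm_logpdf(params.gamma1_raw, params.mu, params.slope_sd)
    total += _norm_logpdf(params.mu, 0.0, prior.mu_sd)
    total += _norm_logpdf(np.asarray(params.beta, float), 0.0, prior.beta_sd)
    # HalfNormal(scale): 2 * N(x; 0, scale) on x > 0
    total += _norm_logpdf(params.slope_sd, 0.0, prior.slope_sd_scale) + math.log(2.0)
    return total


def log_posterior(
    params: LirtParameters,
    dataset: PanelDataset,
    prior: Optional[PriorSettings] = None,
) -> float:
    """Log prior plus panel log-likelihood at reconstructed theta.

    The dataset must have standardized covariates; subject order in
    ``params.gamma0`` / ``gamma1_raw`` follows ``dataset.subjects``.
    """
    lp = log_prior(params, prior)
    if not math.isfinite(lp):
        return lp
    Z = covariate_matrix(dataset)
    gamma1 = params.gamma1(Z)
    thetas = {
        (s.subject_id, t): float(params.gamma0[i] + gamma1[i] * t)
        for i, s in enumerate(dataset.subjects)
        for t in s.visits
    }
    return lp + panel_loglik(params.items, thetas, dataset)


def run_mcmc(
    dataset: PanelDataset,
    config: Optional[McmcConfig] = None,
    prior: Optional[PriorSettings] = None,
) -> McmcChains:
    """Sample the posterior with adaptive Metropolis-within-Gibbs.

    Reproducible bit-for-bit given ``config.seed`` (chains use
    independent streams spawned from it).  Raises on an empty dataset or
    a non-finite log-posterior at the initial state.
    """
    config = (config or McmcConfig()).validate()
    prior = prior or PriorSettings()
    if dataset.n_subjects == 0:
        raise ValidationError("cannot fit an empty dataset")
    panel = pack_panel(dataset)

    results: list[ChainResult] = []
    streams = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for chain_seq in streams:
        rng = np.random.default_rng(chain_seq)
        results.append(
            run_chain(
                panel,
                n_burnin=config.n_burnin,
                n_keep=config.n_keep,
                thin=config.thin,
                rng=rng,
                prior=prior,
                settings=config.sampler,
                store_subject_draws=config.store_subject_draws,
            )
        )

    structural: dict[str, np.ndarray] = {}
    for k, it in enumerate(KATZ_ITEMS):
        structural[f"alpha[{it.value}]"] = np.stack([r.alpha[:, k] for r in results])
        structural[f"kappa_partial[{it.value}]"] = np.stack(
            [r.kappa_partial[:, k] for r in results]
        )
        structural[f"kappa_total[{it.value}]"] = np.stack(
            [r.kappa_total[:, k] for r in results]
        )
    structural["mu"] = np.stack([r.mu for r in results])
    for j, name in enumerate(COVARIATE_NAMES):
        structural[f"beta[{name}]"] = np.stack([r.beta[:, j] for r in results])
    structural["slope_sd"] = np.stack([r.slope_sd for r in results])

    n_chains = len(results)
    gamma0_mean = np.mean([r.gamma0_mean for r in results], axis=0)
    gamma1_mean = np.mean([r.gamma1_mean for r in results], axis=0)
    gamma1_raw_mean = np.mean([r.gamma1_raw_mean for r in results], axis=0)
    theta_pooled = np.mean([r.theta_mean for r in results], axis=0)
    theta_mean = {key: float(theta_pooled[i]) for i, key in enumerate(panel.visit_keys)}
    accept = {
        k: float(np.mean([r.accept_rates[k] for r in results]))
        for k in results[0].accept_rates
    }
    return McmcChains(
        structural=structural,
        subject_ids=panel.subject_ids,
        gamma0_mean=gamma0_mean,
        gamma1_mean=gamma1_mean,
        gamma1_raw_mean=gamma1_raw_mean,
        theta_mean=theta_mean,
        gamma0_draws=(
            np.stack([r.gamma0_draws for r in results]) if config.store_subject_draws else None
        ),
        gamma1_draws=(
            np.stack([r.gamma1_draws for r in results]) if config.store_subject_draws else None
        ),
        accept_rates=accept,
        config=config,
    )


ChainsLike = Union[McmcChains, Mapping[str, np.ndarray]]


def _chain_dict(chains: ChainsLike) -> dict[str, np.ndarray]:
    if isinstance(chains, McmcChains):
        return chains.structural
    out = {}
    for name, arr in chains.items():
        a = np.asarray(arr, float)
        out[name] = a[None, :] if a.ndim == 1 else a
    return out


def summarize_posterior(chains: ChainsLike, include_subject_level: bool = True) -> pd.DataFrame:
    """Posterior summary table: mean, SE, Q2.5, Q97.5, MC error.

    Chains are pooled; "se" is the posterior SD, quantiles use the
    linear-interpolation empirical rule, and ``mcse`` is a naive Monte
    Carlo standard error (posterior SD / sqrt(total draws)) included to
    disambiguate the two notions of "SE".  Subject-level states appear
    as flagged rows carrying chain-pooled posterior means only (their
    full draws are not retained by default).
    """
    cd = _chain_dict(chains)
    rows = []
    for name, arr in cd.items():
        pooled = arr.reshape(-1)
        if pooled.size < 10:
            raise ValidationError(
                f"need at least 10 retained draws to summarize, got {pooled.size}"
            )
        sd = float(pooled.std(ddof=1))
        rows.append(
            {
                "parameter": name,
                "level": "structural",
                "mean": float(pooled.mean()),
                "se": sd,
                "q2.5": float(np.percentile(pooled, 2.5)),
                "q97.5": float(np.percentile(pooled, 97.5)),
                "mcse": sd / math.sqrt(pooled.size),
            }
        )
    if include_subject_level and isinstance(chains, McmcChains):
        for i, sid in enumerate(chains.subject_ids):
            rows.append(
                {
                    "parameter": f"gamma0[{sid}]",
                    "level": "subject",
                    "mean": float(chains.gamma0_mean[i]),
                    "se": float("nan"),
                    "q2.5": float("nan"),
                    "q97.5": float("nan"),
                    "mcse": float("nan"),
                }
            )
            rows.append(
                {
                    "parameter": f"gamma1_raw[{sid}]",
                    "level": "subject",
                    "mean": float(chains.gamma1_raw_mean[i]),
                    "se": float("nan"),
                    "q2.5": float("nan"),
                    "q97.5": float("nan"),
                    "mcse": float("nan"),
                }
            )
    return pd.DataFrame(rows)


def convergence_diagnostics(chains: ChainsLike) -> pd.DataFrame:
    """Split-R̂ and bulk effective sample size per structural parameter.

    Emits a warning when any structural parameter has R̂ > 1.05 (or an
    undefined R̂, as for a constant chain).  Requires at least two
    chains or 200 draws.
    """
    cd = _chain_dict(chains)
    any_arr = next(iter(cd.values()))
    if any_arr.shape[0] < 2 and any_arr.shape[1] < 200:
        raise ValidationError("diagnostics need >=2 chains or >=200 draws")
    rows = []
    flagged = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset({k: v for k, v in cd.items()})
        # classic split-R-hat (not rank-normalized): diverges without bound
        # for separated chains, which makes failures easy to threshold
        rhat = az.rhat(ds, method="split")
        ess = az.ess(ds)
    for name in cd:
        r = float(rhat[name].values)
        e = float(ess[name].values)
        rows.append({"parameter": name, "rhat": r, "ess_bulk": e})
        if not math.isfinite(r) or r > 1.05:
            flagged.append((name, r))
    if flagged:
        warnings.warn(
            "possible non-convergence (R-hat > 1.05 or undefined) for: "
            + ", ".join(f"{n} ({r:.3f})" for n, r in flagged),
            stacklevel=2,
        )
    return pd.DataFrame(rows)
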