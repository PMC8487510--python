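"""Synthetic CLHLS-like Katz panels with a known generating truth.

The generator emulates a mixed-longitudinal cohort of decedents aged
60+: baseline covariates drawn to match the cohort marginals (60.2%
female, 63.1% rural, 80.8% without spouse, age ~ N(91.3, 9.6²)
truncated at 60, education ~ N(1.4, 2.9²) truncated at 0), wave visits
roughly every 3 years, follow-up truncated at death (wave-censored
median ≈ 3 years, capped at 19), and item responses drawn from the
longitudinal graded-response model

    theta_{s,t} = gamma0_s + (gamma1'_s + Z_s beta) * t,
    gamma0_s ~ N(0, intercept_sd²),   gamma1'_s ~ N(mu, slope_sd²),

with categories sampled from the GRM probabilities and responses set
missing completely at random at a configurable rate.

Death is independent of the latent trait given covariates, and the
exponential death-time law and visit jitter are simulation
conveniences that mimic the follow-up distribution only — see the
methods note for what this does and does not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .data_model import (
    KATZ_ITEMS,
    KatzItem,
    PanelDataset,
    ResponseRecord,
    Subject,
    SubjectCovariates,
    ValidationError,
    standardize_covariates,
)
from .grm import ItemParameters

__all__ = [
    "GeneratorConfig",
    "GeneratorTruth",
    "generate_covariates",
    "generate_visit_schedule",
    "generate_responses",
    "generate_dataset",
    "write_truth",
]


def _default_item_truth() -> dict[KatzItem, ItemParameters]:
    from .reference import reference_item_parameters

    return reference_item_parameters()


def _default_beta() -> tuple[float, ...]:
    from .reference import REFERENCE_SLOPE_BETA

    return tuple(REFERENCE_SLOPE_BETA)


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort.

    Defaults are the study conditions of the reference cohort: Table-1
    style marginals, item truth at the published posterior means, mean
    slope ``mu`` = 0.857 latent units/year with the published covariate
    coefficients, wave interval ~3 years and follow-up capped at 19
    years.  ``death_time_mean`` = 5.0 years was calibrated once so the
    wave-censored median follow-up is ≈ 3 years.  ``n_visits`` forces a
    fixed number of visits per subject (death is then placed after the
    last visit), which parameter-recovery studies use for a balanced
    design.
    """

    n_subjects: int = 1000
    female_frac: float = 0.602
    rural_frac: float = 0.631
    no_spouse_frac: float = 0.808
    age_mean: float = 91.3
    age_sd: float = 9.6
    edu_mean: float = 1.4
    edu_sd: float = 2.9
    wave_interval_mean: float = 3.0
    wave_interval_jitter: float = 0.5
    max_followup: float = 19.0
    death_time_mean: float = 5.0
    item_truth: dict[KatzItem, ItemParameters] = field(default_factory=_default_item_truth)
    mu: float = 0.857
    beta: tuple[float, ...] = field(default_factory=_default_beta)
    slope_sd: float = 0.3
    intercept_sd: float = 1.0
    missing_rate: float = 0.02
    n_visits: Optional[int] = None
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_subjects < 0:
            raise ValidationError(f"n_subjects must be >= 0, got {self.n_subjects}")
        for name in ("female_frac", "rural_frac", "no_spouse_frac", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("age_sd", "edu_sd", "wave_interval_jitter", "slope_sd", "intercept_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.max_followup <= 0:
            raise ValidationError(f"max_followup must be > 0, got {self.max_followup}")
        if self.death_time_mean <= 0:
            raise ValidationError("death_time_mean must be > 0")
        if self.wave_interval_mean <= 0:
            raise ValidationError("wave_interval_mean must be > 0")
        if len(self.beta) != 5:
            raise ValidationError("beta must have 5 entries")
        for item in KATZ_ITEMS:
            if item not in self.item_truth:
                raise ValidationError(f"item_truth missing {item.value}")
            self.item_truth[item]  # dataclass invariants checked at construction
        if self.n_visits is not None and self.n_visits < 1:
            raise ValidationError("n_visits must be >= 1 when set")
        return self


@dataclass
class GeneratorTruth:
    """The generating parameters and latent states of a simulated panel."""

    item_params: dict[KatzItem, ItemParameters]
    mu: float
    beta: np.ndarray
    slope_sd: float
    intercept_sd: float
    subject_ids: list[str]
    gamma0: np.ndarray
    gamma1_raw: np.ndarray
    gamma1: np.ndarray
    theta: dict[tuple[str, float], float]


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    """Rejection-sampled normal truncated below at ``lower``."""
    if sd == 0:
        if mean < lower:
            raise ValidationError(f"degenerate truncated normal: mean {mean} < lower {lower}")
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out < lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < lower
    return out


def generate_covariates(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> list[SubjectCovariates]:
    """Draw baseline covariates with the configured marginals.

    Binaries are independent Bernoulli draws; age is normal truncated
    below at 60 (study entry age), education normal truncated at 0.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_subjects
    sex = (rng.random(n) < config.female_frac).astype(int)
    residence = (rng.random(n) < config.rural_frac).astype(int)
    marital = (rng.random(n) < config.no_spouse_frac).astype(int)
    age = _truncated_normal(rng, config.age_mean, config.age_sd, 60.0, n)
    edu = _truncated_normal(rng, config.edu_mean, config.edu_sd, 0.0, n)
    return [
        SubjectCovariates(
            sex=int(sex[i]),
            residence=int(residence[i]),
            marital=int(marital[i]),
            age_baseline=float(age[i]),
            education=float(edu[i]),
        )
        for i in range(n)
    ]


def generate_visit_schedule(
    config: GeneratorConfig,
    covariates: Sequence[SubjectCovariates],
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[list[float], float]]:
    """Per-subject ``(visits, death_time)``, visits strictly before death.

    Every subject has a baseline visit at t = 0.  Death is exponential
    (mean ``death_time_mean``) capped at ``max_followup``; subsequent
    visits fall every ``wave_interval_mean`` ± jitter (floored at 0.5
    years) while still before death.  With ``n_visits`` set, exactly
    that many visits are scheduled and death follows the last one.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    out: list[tuple[list[float], float]] = []
    for _ in range(len(covariates)):
        if config.n_visits is not None:
            visits = [0.0]
            t = 0.0
            for _ in range(config.n_visits - 1):
                t += max(
                    rng.normal(config.wave_interval_mean, config.wave_interval_jitter), 0.5
                )
                visits.append(t)
            death = visits[-1] + max(
                rng.normal(config.wave_interval_mean, config.wave_interval_jitter), 0.5
            )
        else:
            death = min(rng.exponential(config.death_time_mean), config.max_followup)
            if death <= 0:
                death = 1e-3
            visits = [0.0]
            t = 0.0
            while True:
                t += max(
                    rng.normal(config.wave_interval_mean, config.wave_interval_jitter), 0.5
                )
                if t >= death:
                    break
                visits.append(t)
        out.append((visits, float(death)))
    return out


def _simulate_responses(
    config: GeneratorConfig,
    subjects: Sequence[Subject],
    rng: np.random.Generator,
) -> tuple[list[ResponseRecord], GeneratorTruth]:
    n = len(subjects)
    # Standardized covariate design for the slope regression.
    from .data_model import covariate_matrix

    if n >= 2:
        ds = PanelDataset(subjects=list(subjects), responses=[])
        standardize_covariates(ds)
        Z = covariate_matrix(ds)
    else:
        Z = np.zeros((n, 5))
    beta = np.asarray(config.beta, float)

    gamma0 = rng.normal(0.0, config.intercept_sd, n)
    gamma1_raw = rng.normal(config.mu, config.slope_sd, n)
    gamma1 = gamma1_raw + (Z @ beta if n else np.zeros(0))

    alphas = np.array([config.item_truth[it].alpha for it in KATZ_ITEMS])
    kps = np.array([config.item_truth[it].kappa_partial for it in KATZ_ITEMS])
    kts = np.array([config.item_truth[it].kappa_total for it in KATZ_ITEMS])

    responses: list[ResponseRecord] = []
    theta_map: dict[tuple[str, float], float] = {}
    from scipy.special import expit

    for i, s in enumerate(subjects):
        for t in s.visits:
            theta = gamma0[i] + gamma1[i] * t
            theta_map[(s.subject_id, t)] = float(theta)
            x1 = alphas * theta - kps
            x2 = alphas * theta - kts
            p_ge1 = expit(x1)
            p_ge2 = expit(x2)
            u = rng.random(len(KATZ_ITEMS))
            cats = np.where(u < p_ge2, 2, np.where(u < p_ge1, 1, 0))
            miss = rng.random(len(KATZ_ITEMS)) < config.missing_rate
            for j, item in enumerate(KATZ_ITEMS):
                responses.append(
                    ResponseRecord(
                        subject_id=s.subject_id,
                        visit_time=t,
                        item=item,
                        category=None if miss[j] else int(cats[j]),
                    )
                )
    truth = GeneratorTruth(
        item_params=dict(config.item_truth),
        mu=config.mu,
        beta=beta,
        slope_sd=config.slope_sd,
        intercept_sd=config.intercept_sd,
        subject_ids=[s.subject_id for s in subjects],
        gamma0=gamma0,
        gamma1_raw=gamma1_raw,
        gamma1=gamma1,
        theta=theta_map,
    )
    return responses, truth


def generate_responses(
    config: GeneratorConfig,
    subjects: Sequence[Subject],
    rng: Optional[np.random.Generator] = None,
) -> PanelDataset:
    """Draw GRM responses for prepared subjects (with visit schedules)."""
    config.validate()
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    responses, _ = _simulate_responses(config, subjects, rng)
    return PanelDataset(subjects=list(subjects), responses=responses).validate()


def generate_dataset(config: GeneratorConfig) -> tuple[PanelDataset, GeneratorTruth]:
    """Full simulation: covariates → schedules → responses, plus truth.

    Deterministic given ``config.seed``; the returned panel passes
    :meth:`PanelDataset.validate` and has standardized covariates.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    covariates = generate_covariates(config, rng)
    schedules = generate_visit_schedule(config, covariates, rng)
    width = max(4, len(str(max(config.n_subjects, 1))))
    subjects = [
        Subject(
            subject_id=f"S{i:0{width}d}",
            covariates=covariates[i],
            death_time=schedules[i][1],
            visits=schedules[i][0],
        )
        for i in range(config.n_subjects)
    ]
    responses, truth = _simulate_responses(config, subjects, rng)
    dataset = PanelDataset(subjects=subjects, responses=responses).validate()
    return dataset, truth


def write_truth(truth: GeneratorTruth, path: str | Path) -> None:
    """Serialize the generating truth to JSON (for recovery studies)."""
    payload = {
        "mu": truth.mu,
        "beta": list(map(float, truth.beta)),
        "slope_sd": truth.slope_sd,
        "intercept_sd": truth.intercept_sd,
        "item_params": [
            {
                "item": it.value,
                "alpha": truth.item_params[it].alpha,
                "kappa_partial": truth.item_params[it].kappa_partial,
                "kappa_total": truth.item_params[it].kappa_total,
            }
            for it in KATZ_ITEMS
        ],
        "subject_ids": truth.subject_ids,
        "gamma0": list(map(float, truth.gamma0)),
        "gamma1_raw": list(map(float, truth.gamma1_raw)),
        "gamma1": list(map(float, truth.gamma1)),
        "theta": [
            {"subject_id": sid, "visit_time": t, "theta": v}
            for (sid, t), v in truth.theta.items()
        ],
    }
    Path(path).write_text(json.dumps(payload) + "\n")
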