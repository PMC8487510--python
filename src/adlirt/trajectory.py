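"""Disability trajectories before death from fitted latent scores.

Second pipeline stage: take the per-(subject, visit) posterior-mean
latent disability from the longitudinal GRM fit, rescale it affinely to
[−3, 3] (min → −3, max → 3, order preserving), index each visit by
years before death, and fit a linear mixed-effects model

    theta_{s,t} = X_{s,t} beta + b1_s + b2_s * t + e_{s,t},
    (b1_s, b2_s) ~ MVN(0, Sigma),   e ~ N(0, sigma²),

by maximum likelihood.  Fixed effects default to sex, residence,
marital status, standardized age and education, the sex×residence and
sex×marital interactions, and time.  Group mean trajectories over the
19 years preceding death are produced for the two standard groupings
(sex × residence: MU/FU/MR/FR, and sex × marital: MY/FY/MN/FN) with the
remaining covariates held at their sample means.

The latent score enters as if observed (its posterior uncertainty is
not propagated in this two-stage fit); see the methods note.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import PanelDataset, SubjectCovariates, ValidationError
from .lirt import McmcChains

__all__ = [
    "ScoredVisit",
    "MixedModelFit",
    "DEFAULT_FIXED_TERMS",
    "GROUPINGS",
    "extract_scored_visits",
    "fit_mixed_model",
    "group_trajectories",
]


@dataclass(frozen=True)
class ScoredVisit:
    """One visit with its rescaled disability score and time before death."""

    subject_id: str
    years_before_death: float
    theta_scaled: float
    covariates: SubjectCovariates

    def __post_init__(self) -> None:
        if self.years_before_death < 0:
            raise ValidationError("years_before_death must be >= 0")
        if not -3.0 - 1e-9 <= self.theta_scaled <= 3.0 + 1e-9:
            raise ValidationError("theta_scaled must lie in [-3, 3]")


#: Default fixed-effect terms.  "time" is years before death;
#: interaction terms multiply their factors.
DEFAULT_FIXED_TERMS: tuple[str, ...] = (
    "intercept",
    "time",
    "sex",
    "residence",
    "marital",
    "age_std",
    "education_std",
    "sex_x_residence",
    "sex_x_marital",
)

#: The two standard cross-groupings and their binary profiles.
GROUPINGS: dict[str, dict[str, dict[str, int]]] = {
    "sex_residence": {
        "MU": {"sex": 0, "residence": 0},
        "FU": {"sex": 1, "residence": 0},
        "MR": {"sex": 0, "residence": 1},
        "FR": {"sex": 1, "residence": 1},
    },
    "sex_marital": {
        "MY": {"sex": 0, "marital": 0},
        "FY": {"sex": 1, "marital": 0},
        "MN": {"sex": 0, "marital": 1},
        "FN": {"sex": 1, "marital": 1},
    },
}


def extract_scored_visits(
    theta_means: Union[McmcChains, Mapping[tuple[str, float], float]],
    dataset: PanelDataset,
    scale_to: tuple[float, float] = (-3.0, 3.0),
) -> list[ScoredVisit]:
    """Rescale posterior-mean latent scores and align to time before death.

    The affine map sends the pooled minimum to −3 and the maximum to +3
    (strictly monotone, rank preserving).  Errors if the scores have
    zero range or a visit falls on/after the recorded death.
    """
    thetas = (
        theta_means.theta_mean if isinstance(theta_means, McmcChains) else dict(theta_means)
    )
    if not thetas:
        raise ValidationError("no latent scores provided")
    values = np.array(list(thetas.values()), float)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise ValidationError("latent scores have zero range; cannot rescale")
    a, b = scale_to
    smap = dataset.subject_map()
    out: list[ScoredVisit] = []
    for (sid, t), theta in thetas.items():
        subj = smap.get(sid)
        if subj is None:
            raise ValidationError(f"score refers to unknown subject {sid!r}")
        if subj.death_time is None or t >= subj.death_time:
            raise ValidationError(
                f"subject {sid!r} has a visit at {t} on or after death"
            )
        scaled = a + (b - a) * (theta - lo) / (hi - lo)
        out.append(
            ScoredVisit(
                subject_id=sid,
                years_before_death=float(subj.death_time - t),
                theta_scaled=float(scaled),
                covariates=subj.covariates,
            )
        )
    return out


@dataclass
class MixedModelFit:
    """ML estimates of the random-intercept/random-slope model."""

    terms: tuple[str, ...]
    fixed_effects: dict[str, float]
    se: dict[str, float]
    Sigma: np.ndarray  # 2x2 random-effect covariance (intercept, slope)
    sigma2: float  # residual variance
    loglik: float
    converged: bool
    random_effects: bool


def _term_value(term: str, row: Mapping[str, float]) -> float:
    value = 1.0
    if term == "intercept":
        return 1.0
    for factor in term.split("_x_"):
        if factor not in row:
            raise ValidationError(f"unknown design factor {factor!r} in term {term!r}")
        value *= row[factor]
    return value


def _design(visits: Sequence[ScoredVisit], terms: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rows = []
    y = []
    groups = []
    for v in visits:
        c = v.covariates
        if not c.is_complete() or c.age_std is None or c.education_std is None:
            raise ValidationError(
                f"subject {v.subject_id!r} lacks complete standardized covariates"
            )
        base = {
            "time": v.years_before_death,
            "sex": float(c.sex),
            "residence": float(c.residence),
            "marital": float(c.marital),
            "age_std": float(c.age_std),
            "education_std": float(c.education_std),
        }
        rows.append([_term_value(t, base) for t in terms])
        y.append(v.theta_scaled)
        groups.append(v.subject_id)
    return np.asarray(rows, float), np.asarray(y, float), np.asarray(groups)


def _check_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise ValidationError("fewer observations than fixed-effect terms")
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * 1e-10 if diag.size else 0.0
    aliased = [terms[i] for i in range(len(terms)) if diag[i] <= tol]
    if aliased:
        raise ValidationError(f"rank-deficient design; aliased terms: {aliased}")


def fit_mixed_model(
    visits: Sequence[ScoredVisit],
    terms: Sequence[str] = DEFAULT_FIXED_TERMS,
    random_effects: bool = True,
) -> MixedModelFit:
    """Fit the trajectory model by maximum likelihood (not REML).

    With ``random_effects=False`` the random-effect covariance is fixed
    at zero and the fit reduces exactly to ordinary least squares.  A
    random slope requires repeated measurements: if every subject has a
    single visit the model is not identifiable and an error is raised.
    """
    if not visits:
        raise ValidationError("no scored visits to fit")
    terms = tuple(terms)
    X, y, groups = _design(visits, terms)
    _check_rank(X, terms)

    if not random_effects:
        res = sm.OLS(y, X).fit()
        k = X.shape[1]
        return MixedModelFit(
            terms=terms,
            fixed_effects=dict(zip(terms, map(float, res.params))),
            se=dict(zip(terms, map(float, res.bse))),
            Sigma=np.zeros((2, 2)),
            sigma2=float(res.scale),
            loglik=float(res.llf),
            converged=True,
            random_effects=False,
        )

    counts = pd.Series(groups).value_counts()
    if counts.max() < 2:
        raise ValidationError(
            "every subject has a single visit; the random slope variance "
            "is not identifiable"
        )
    times = X[:, terms.index("time")] if "time" in terms else np.array(
        [v.years_before_death for v in visits]
    )
    exog_re = np.column_stack([np.ones(len(y)), times])
    model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, method="lbfgs", maxiter=200)
        if not res.converged:
            res = model.fit(reml=False, method="powell", maxiter=500)
    if not res.converged:
        raise ValidationError(
            "mixed-model optimizer did not converge; "
            f"final log-likelihood {res.llf:.4f}"
        )
    k = X.shape[1]
    cov_re = np.asarray(res.cov_re, float)
    return MixedModelFit(
        terms=terms,
        fixed_effects=dict(zip(terms, map(float, res.params[:k]))),
        se=dict(zip(terms, map(float, res.bse[:k]))),
        Sigma=cov_re,
        sigma2=float(res.scale),
        loglik=float(res.llf),
        converged=bool(res.converged),
        random_effects=True,
    )


def predict_fixed(fit: MixedModelFit, row: Mapping[str, float]) -> float:
    """Population-mean prediction (random effects at zero)."""
    return float(sum(coef * _term_value(t, row) for t, coef in fit.fixed_effects.items()))


def group_trajectories(
    visits: Sequence[ScoredVisit],
    fit: MixedModelFit,
    grouping: str = "sex_residence",
    horizon: float = 19.0,
    step: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Model-implied and observed mean trajectories for 4 cross groups.

    For each group the fixed-effect prediction is evaluated over
    years-before-death in [0, horizon], with the grouping binaries set
    to the group profile and all other covariates held at their sample
    means over the scored visits.  Observed means are computed per
    integer year; an empty group is omitted with a warning.

    Returns ``{"curves": ..., "observed": ...}`` data frames with
    columns (group, years_before_death, mean_theta).
    """
    if grouping not in GROUPINGS:
        raise ValidationError(
            f"unknown grouping {grouping!r}; known: {sorted(GROUPINGS)}"
        )
    profiles = GROUPINGS[grouping]
    cov_rows = pd.DataFrame(
        {
            "sex": [float(v.covariates.sex) for v in visits],
            "residence": [float(v.covariates.residence) for v in visits],
            "marital": [float(v.covariates.marital) for v in visits],
            "age_std": [float(v.covariates.age_std) for v in visits],
            "education_std": [float(v.covariates.education_std) for v in visits],
        }
    )
    means = cov_rows.mean().to_dict()
    grid = np.arange(0.0, horizon + 1e-9, step)

    curve_rows = []
    obs_rows = []
    group_vars = set().union(*(p.keys() for p in profiles.values()))
    for label, profile in profiles.items():
        members = [
            v
            for v in visits
            if all(getattr(v.covariates, k) == val for k, val in profile.items())
        ]
        if not members:
            warnings.warn(f"group {label} is empty; curve omitted", stacklevel=2)
            continue
        row = dict(means)
        row.update({k: float(v) for k, v in profile.items()})
        for t in grid:
            row["time"] = float(t)
            curve_rows.append(
                {
                    "group": label,
                    "years_before_death": float(t),
                    "mean_theta": predict_fixed(fit, row),
                }
            )
        years = np.round([v.years_before_death for v in members]).astype(int)
        theta = np.array([v.theta_scaled for v in members])
        for yr in np.unique(years):
            obs_rows.append(
                {
                    "group": label,
                    "years_before_death": int(yr),
                    "mean_theta": float(theta[years == yr].mean()),
                }
            )
    return {
        "curves": pd.DataFrame(curve_rows),
        "observed": pd.DataFrame(obs_rows),
    }
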