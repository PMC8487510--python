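"""Latent-score rescaling and mixed-effects trajectory modelling."""

import numpy as np
import pytest

from adlirt.data_model import PanelDataset, SubjectCovariates, ValidationError
from adlirt.trajectory import (
    DEFAULT_FIXED_TERMS,
    MixedModelFit,
    ScoredVisit,
    extract_scored_visits,
    fit_mixed_model,
    group_trajectories,
)
from conftest import make_subject


def _dataset_for(sids_visits):
    subjects = [
        make_subject(sid, death=20.0, visits=tuple(ts)) for sid, ts in sids_visits.items()
    ]
    for s in subjects:
        s.covariates.age_std = 0.0
        s.covariates.education_std = 0.0
    return PanelDataset(subjects=subjects, responses=[])


def test_rescale_symmetric_and_two_point():
    ds = _dataset_for({"A": [0.0, 1.0, 2.0]})
    thetas = {("A", 0.0): -2.0, ("A", 1.0): 0.0, ("A", 2.0): 2.0}
    scored = {v.years_before_death: v.theta_scaled for v in extract_scored_visits(thetas, ds)}
    assert scored[20.0] == pytest.approx(-3.0)
    assert scored[19.0] == pytest.approx(0.0)
    assert scored[18.0] == pytest.approx(3.0)

    thetas = {("A", 0.0): 0.0, ("A", 1.0): 1.0}
    scored = [v.theta_scaled for v in extract_scored_visits(thetas, ds)]
    assert sorted(scored) == pytest.approx([-3.0, 3.0])


def test_rescale_preserves_rank():
    rng = np.random.default_rng(3)
    ts = list(np.sort(rng.uniform(0, 19, 100)))
    ds = _dataset_for({"A": ts})
    values = rng.normal(0, 2, 100)
    thetas = {("A", t): float(v) for t, v in zip(ts, values)}
    scored = extract_scored_visits(thetas, ds)
    # years_before_death is strictly decreasing in visit time, so sorting
    # by -years_before_death restores visit order without float round trips
    scaled = np.array(
        [v.theta_scaled for v in sorted(scored, key=lambda v: -v.years_before_death)]
    )
    assert (np.argsort(scaled) == np.argsort(values)).all()
    assert scaled.min() == pytest.approx(-3.0)
    assert scaled.max() == pytest.approx(3.0)


def test_rescale_errors():
    ds = _dataset_for({"A": [0.0, 1.0]})
    with pytest.raises(ValidationError, match="zero range"):
        extract_scored_visits({("A", 0.0): 1.0, ("A", 1.0): 1.0}, ds)
    with pytest.raises(ValidationError, match="death"):
        extract_scored_visits({("A", 25.0): 1.0, ("A", 0.0): 0.0}, ds)


def _covariates(rng):
    return SubjectCovariates(
        sex=int(rng.integers(0, 2)),
        residence=int(rng.integers(0, 2)),
        marital=int(rng.integers(0, 2)),
        age_baseline=90.0,
        education=1.0,
        age_std=float(rng.normal()),
        education_std=float(rng.normal()),
    )


def _row(v: ScoredVisit) -> dict:
    c = v.covariates
    return {
        "intercept": 1.0,
        "time": v.years_before_death,
        "sex": c.sex,
        "residence": c.residence,
        "marital": c.marital,
        "age_std": c.age_std,
        "education_std": c.education_std,
        "sex_x_residence": c.sex * c.residence,
        "sex_x_marital": c.sex * c.marital,
    }


TRUE_BETA = {
    "intercept": -0.8,
    "time": 0.06,
    "sex": 0.3,
    "residence": -0.2,
    "marital": 0.25,
    "age_std": 0.1,
    "education_std": -0.15,
    "sex_x_residence": 0.05,
    "sex_x_marital": -0.1,
}


def simulate_visits(rng, n=300, n_visits=5, Sigma=None, sigma2=0.25, rescale=True):
    """Random-slope data; scores min-max mapped to [-3, 3] as in the pipeline.

    Returns the visits plus the affine map (a, b) with y' = a + b*y, so a
    recovery test can transform the generating truth onto the fitted scale.
    """
    Sigma = np.zeros((2, 2)) if Sigma is None else Sigma
    L = np.zeros((2, 2)) if not Sigma.any() else np.linalg.cholesky(Sigma)
    raw = []
    for i in range(n):
        cov = _covariates(rng)
        b = L @ rng.standard_normal(2)
        for t in rng.uniform(0, 10, n_visits):
            v = ScoredVisit(f"S{i:04d}", float(t), 0.0, cov)
            y = sum(TRUE_BETA[k] * val for k, val in _row(v).items())
            y += b[0] + b[1] * t + rng.normal(0, np.sqrt(sigma2))
            raw.append((f"S{i:04d}", float(t), float(y), cov))
    ys = np.array([r[2] for r in raw])
    if rescale:
        slope = 6.0 / (ys.max() - ys.min())
        offset = -3.0 - slope * ys.min()
    else:
        slope, offset = 1.0, 0.0
    visits = [
        ScoredVisit(sid, t, offset + slope * y, cov) for sid, t, y, cov in raw
    ]
    return visits, offset, slope


def test_noiseless_fixed_effects_recovered_exactly():
    """With Sigma = 0 and no noise, OLS interpolates the coefficients."""
    rng = np.random.default_rng(5)
    visits, a, b = simulate_visits(rng, n=40, n_visits=3, sigma2=0.0)
    fit = fit_mixed_model(visits, random_effects=False)
    for term, coef in TRUE_BETA.items():
        expected = a + b * coef if term == "intercept" else b * coef
        assert fit.fixed_effects[term] == pytest.approx(expected, abs=1e-8)
    assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)


def test_sigma_zero_reduces_to_independent_ols():
    rng = np.random.default_rng(6)
    visits, _, _ = simulate_visits(rng, n=60, n_visits=3, sigma2=0.25)
    fit = fit_mixed_model(visits, random_effects=False)
    # independent OLS oracle via lstsq
    X = np.array([[_row(v)[t] for t in DEFAULT_FIXED_TERMS] for v in visits])
    y = np.array([v.theta_scaled for v in visits])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    for j, term in enumerate(DEFAULT_FIXED_TERMS):
        assert fit.fixed_effects[term] == pytest.approx(coef[j], abs=1e-6)


def test_single_visit_per_subject_unidentifiable():
    rng = np.random.default_rng(7)
    visits, _, _ = simulate_visits(rng, n=50, n_visits=1, sigma2=0.25)
    with pytest.raises(ValidationError, match="single visit"):
        fit_mixed_model(visits)


def test_rank_deficient_design_names_aliased_terms():
    rng = np.random.default_rng(8)
    visits, _, _ = simulate_visits(rng, n=30, n_visits=2, sigma2=0.25)
    with pytest.raises(ValidationError, match="aliased"):
        fit_mixed_model(visits, terms=DEFAULT_FIXED_TERMS + ("sex_x_marital",))


def test_mixed_model_recovery_within_3se():
    """ML recovers the generating fixed effects and random-effect structure."""
    rng = np.random.default_rng(9)
    Sigma = np.array([[0.25, 0.04], [0.04, 0.01]])
    visits, a, b = simulate_visits(rng, n=300, n_visits=5, Sigma=Sigma, sigma2=0.25)
    fit = fit_mixed_model(visits)
    assert fit.converged
    for term, coef in TRUE_BETA.items():
        expected = a + b * coef if term == "intercept" else b * coef
        z = abs(fit.fixed_effects[term] - expected) / fit.se[term]
        assert z < 3.0, f"{term}: z={z:.2f}"
    expected_sigma = b**2 * Sigma
    rel = np.abs(fit.Sigma - expected_sigma) / np.abs(expected_sigma)
    assert (rel < 0.3).all(), f"Sigma relative errors {rel}"
    assert abs(fit.sigma2 - b**2 * 0.25) / (b**2 * 0.25) < 0.3


def _constant_fit(coefs) -> MixedModelFit:
    terms = tuple(coefs)
    return MixedModelFit(
        terms=terms,
        fixed_effects=dict(coefs),
        se={t: 0.1 for t in terms},
        Sigma=np.zeros((2, 2)),
        sigma2=0.1,
        loglik=0.0,
        converged=True,
        random_effects=False,
    )


def test_group_trajectories_labels_and_equality():
    rng = np.random.default_rng(10)
    visits, _, _ = simulate_visits(rng, n=40, n_visits=3, sigma2=0.25)
    fit = _constant_fit(
        {
            "intercept": -0.5,
            "time": 0.05,
            "sex": 0.0,
            "residence": 0.0,
            "marital": 0.1,
            "age_std": 0.0,
            "education_std": 0.0,
            "sex_x_residence": 0.0,
            "sex_x_marital": 0.0,
        }
    )
    out = group_trajectories(visits, fit, grouping="sex_residence")
    curves = out["curves"]
    assert set(curves.group) == {"MU", "FU", "MR", "FR"}
    # sex and residence coefficients are zero → all four curves identical
    pivot = curves.pivot(index="years_before_death", columns="group", values="mean_theta")
    for g in ("FU", "MR", "FR"):
        assert np.allclose(pivot["MU"], pivot[g])

    out = group_trajectories(visits, fit, grouping="sex_marital")
    assert set(out["curves"].group) == {"MY", "FY", "MN", "FN"}


def test_group_trajectories_empty_group_warns():
    rng = np.random.default_rng(11)
    visits, _, _ = simulate_visits(rng, n=30, n_visits=2, sigma2=0.25)
    only_male = [v for v in visits if v.covariates.sex == 0]
    fit = _constant_fit({t: 0.0 for t in DEFAULT_FIXED_TERMS})
    with pytest.warns(UserWarning, match="empty"):
        out = group_trajectories(only_male, fit, grouping="sex_residence")
    assert set(out["curves"].group) <= {"MU", "MR"}


def test_group_means_invariant_to_subject_relabeling():
    rng = np.random.default_rng(12)
    visits, _, _ = simulate_visits(rng, n=30, n_visits=2, sigma2=0.25)
    relabeled = [
        ScoredVisit("X" + v.subject_id, v.years_before_death, v.theta_scaled, v.covariates)
        for v in visits
    ]
    fit = _constant_fit({t: 0.1 for t in DEFAULT_FIXED_TERMS})
    a = group_trajectories(visits, fit)["observed"]
    b = group_trajectories(relabeled, fit)["observed"]
    assert a.equals(b)
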