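"""Bayesian longitudinal GRM: priors, posterior, sampler, summaries."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from adlirt.data_model import KATZ_ITEMS, PanelDataset, ValidationError, standardize_covariates
from adlirt.grm import ItemParameters, panel_loglik
from adlirt.lirt import (
    STRUCTURAL_PARAMETERS,
    LirtParameters,
    McmcConfig,
    PriorSettings,
    convergence_diagnostics,
    log_posterior,
    log_prior,
    run_mcmc,
    summarize_posterior,
)
from conftest import make_panel, make_subject


def random_params(rng, n_subjects=4) -> LirtParameters:
    items = {
        it: ItemParameters(
            item=it,
            alpha=float(rng.uniform(0.2, 4.0)),
            kappa_partial=(kp := float(rng.uniform(-3, 2))),
            kappa_total=kp + float(rng.uniform(0.1, 3.0)),
        )
        for it in KATZ_ITEMS
    }
    return LirtParameters(
        items=items,
        gamma0=rng.normal(0, 1, n_subjects),
        gamma1_raw=rng.normal(0.5, 0.3, n_subjects),
        mu=float(rng.normal(0, 1)),
        beta=rng.normal(0, 0.5, 5),
        slope_sd=float(rng.uniform(0.1, 2.0)),
    )


def scipy_log_prior(p: LirtParameters, prior: PriorSettings) -> float:
    """Independent density oracle built from scipy.stats."""
    total = 0.0
    for it in KATZ_ITEMS:
        ip = p.items[it]
        total += stats.lognorm.logpdf(ip.alpha, s=prior.alpha_logsd)
        total += stats.norm.logpdf(ip.kappa_partial, scale=prior.kappa_sd)
        total += stats.lognorm.logpdf(
            ip.kappa_total - ip.kappa_partial, s=prior.delta_logsd
        )
    total += stats.norm.logpdf(p.gamma0).sum()
    total += stats.norm.logpdf(p.gamma1_raw, loc=p.mu, scale=p.slope_sd).sum()
    total += stats.norm.logpdf(p.mu, scale=prior.mu_sd)
    total += stats.norm.logpdf(np.asarray(p.beta), scale=prior.beta_sd).sum()
    total += stats.halfnorm.logpdf(p.slope_sd, scale=prior.slope_sd_scale)
    return float(total)


def test_log_prior_matches_scipy_oracle():
    rng = np.random.default_rng(0)
    prior = PriorSettings()
    for _ in range(20):
        p = random_params(rng)
        assert log_prior(p, prior) == pytest.approx(scipy_log_prior(p, prior), abs=1e-9)


def test_log_prior_support():
    rng = np.random.default_rng(1)
    p = random_params(rng)
    p.slope_sd = -0.5
    assert log_prior(p) == -math.inf
    with pytest.raises(ValidationError):
        ItemParameters(item=KATZ_ITEMS[0], alpha=1.0, kappa_partial=1.0, kappa_total=0.5)


def test_log_prior_gamma0_normalizing_constant():
    """All gamma0 at 0 contribute exactly n times the N(0,1) peak density."""
    rng = np.random.default_rng(2)
    p = random_params(rng, n_subjects=7)
    base = log_prior(p)
    p0 = random_params(rng, n_subjects=7)
    # isolate the gamma0 term by differencing two states equal elsewhere
    p0.items, p0.gamma1_raw, p0.mu, p0.beta, p0.slope_sd = (
        p.items,
        p.gamma1_raw,
        p.mu,
        p.beta,
        p.slope_sd,
    )
    p0.gamma0 = np.zeros(7)
    expected_delta = stats.norm.logpdf(np.zeros(7)).sum() - stats.norm.logpdf(p.gamma0).sum()
    assert log_prior(p0) - base == pytest.approx(expected_delta, abs=1e-9)


def _standardized_fixture():
    subjects = [
        make_subject("S1", age=85.0, education=0.0, death=8.0, visits=(0.0, 2.5)),
        make_subject("S2", sex=1, age=95.0, education=4.0, death=6.0, visits=(0.0, 3.0)),
        make_subject("S3", sex=1, residence=1, age=90.0, education=2.0, death=7.0, visits=(0.0,)),
    ]
    cats = {
        ("S1", 0.0): [0, 0, 0, 0, 0, 0],
        ("S1", 2.5): [1, 0, 1, 0, 0, 1],
        ("S2", 0.0): [1, 1, 0, 0, 0, 0],
        ("S2", 3.0): [2, 2, 1, 1, 1, 2],
        ("S3", 0.0): [2, 2, 2, 2, 2, 2],
    }
    panel = make_panel(subjects, cats)
    standardize_covariates(panel)
    return panel


def test_log_posterior_decomposes_into_prior_plus_likelihood():
    panel = _standardized_fixture()
    rng = np.random.default_rng(3)
    from adlirt.data_model import covariate_matrix

    Z = covariate_matrix(panel)
    for _ in range(5):
        p = random_params(rng, n_subjects=3)
        gamma1 = p.gamma1(Z)
        thetas = {
            (s.subject_id, t): float(p.gamma0[i] + gamma1[i] * t)
            for i, s in enumerate(panel.subjects)
            for t in s.visits
        }
        assert log_posterior(p, panel) - log_prior(p) == pytest.approx(
            panel_loglik(p.items, thetas, panel), abs=1e-9
        )


def test_log_posterior_direction_for_severe_subject():
    """Raising gamma0 of an all-totally-limited subject raises the posterior."""
    panel = _standardized_fixture()
    rng = np.random.default_rng(4)
    p = random_params(rng, n_subjects=3)
    p.gamma0 = np.zeros(3)
    lp0 = log_posterior(p, panel)
    p.gamma0 = np.array([0.0, 0.0, 1.5])  # S3 answered 2 everywhere
    assert log_posterior(p, panel) > lp0


def test_run_mcmc_deterministic_and_in_support():
    panel = _standardized_fixture()
    cfg = McmcConfig(n_burnin=100, n_keep=60, n_chains=2, seed=12)
    a = run_mcmc(panel, cfg)
    b = run_mcmc(panel, cfg)
    for name in STRUCTURAL_PARAMETERS:
        np.testing.assert_array_equal(a.structural[name], b.structural[name])
    for it in KATZ_ITEMS:
        assert (a.structural[f"alpha[{it.value}]"] > 0).all()
        assert (
            a.structural[f"kappa_total[{it.value}]"]
            > a.structural[f"kappa_partial[{it.value}]"]
        ).all()
    assert (a.structural["slope_sd"] > 0).all()


def test_run_mcmc_rejects_empty_dataset():
    with pytest.raises(ValidationError, match="empty"):
        run_mcmc(PanelDataset(subjects=[], responses=[]), McmcConfig(n_burnin=10, n_keep=10))


def test_summarize_posterior_contracts():
    const = {"x": np.full((2, 50), 3.25)}
    s = summarize_posterior(const)
    row = s.iloc[0]
    assert row["mean"] == 3.25
    assert row["se"] == 0.0
    assert row["q2.5"] == row["q97.5"] == 3.25

    draws = {"y": np.arange(1.0, 1001.0)[None, :]}
    s = summarize_posterior(draws)
    assert s.iloc[0]["q2.5"] == pytest.approx(25.975)
    assert s.iloc[0]["q97.5"] == pytest.approx(975.025)

    with pytest.raises(ValidationError, match="10"):
        summarize_posterior({"z": np.arange(5.0)[None, :]})


def test_summary_row_bookkeeping():
    panel = _standardized_fixture()
    chains = run_mcmc(panel, McmcConfig(n_burnin=50, n_keep=20, n_chains=2, seed=7))
    s = summarize_posterior(chains)
    structural = s[s.level == "structural"]
    assert len(structural) == 6 * 3 + 5 + 1 + 1
    subject_rows = s[s.level == "subject"]
    assert len(subject_rows) == 2 * panel.n_subjects


def test_convergence_diagnostics_behaviour():
    rng = np.random.default_rng(11)
    good = {"x": rng.standard_normal((2, 500))}
    d = convergence_diagnostics(good)
    assert 0.99 <= d.iloc[0]["rhat"] <= 1.03

    shifted = {"x": np.stack([rng.standard_normal(300), rng.standard_normal(300) + 10.0])}
    with pytest.warns(UserWarning, match="non-convergence"):
        d = convergence_diagnostics(shifted)
    assert d.iloc[0]["rhat"] > 2.0

    const = {"x": np.full((2, 300), 1.0)}
    with pytest.warns(UserWarning):
        d = convergence_diagnostics(const)
    assert math.isnan(d.iloc[0]["rhat"])

    with pytest.raises(ValidationError):
        convergence_diagnostics({"x": np.zeros((1, 50))})


def test_subject_permutation_leaves_posterior_similar():
    """Reordering subjects leaves structural posterior means statistically close."""
    from adlirt.synthetic import GeneratorConfig, generate_dataset

    ds, _ = generate_dataset(GeneratorConfig(n_subjects=40, n_visits=3, seed=19))
    cfg = McmcConfig(n_burnin=400, n_keep=300, n_chains=2, seed=21)
    a = run_mcmc(ds, cfg)
    perm = PanelDataset(subjects=list(reversed(ds.subjects)), responses=ds.responses)
    b = run_mcmc(perm, cfg)
    for it in KATZ_ITEMS:
        for block in ("alpha", "kappa_partial", "kappa_total"):
            name = f"{block}[{it.value}]"
            da, db = a.pooled(name), b.pooled(name)
            pooled_sd = max(float(da.std()), float(db.std()), 1e-6)
            assert abs(da.mean() - db.mean()) < 4 * pooled_sd
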