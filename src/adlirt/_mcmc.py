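"""Vectorized Metropolis-within-Gibbs engine for the longitudinal GRM.

The sampler works on a packed array representation of the panel.  Update
blocks per sweep:

1. item parameters — componentwise random-walk Metropolis on
   (log alpha_i, kappa_partial_i, log delta_i) with delta_i =
   kappa_total_i − kappa_partial_i, so the threshold order holds by
   construction;
2. subject intercepts gamma0 — one simultaneous per-subject proposal
   (subjects are conditionally independent given the structural
   parameters), prior N(0, 1);
3. subject total slopes gamma1 — same scheme, prior
   N(mu + Z beta, slope_sd²);
4. (mu, beta) — exact conjugate Gibbs draw from the normal linear model
   gamma1 ~ N(mu + Z beta, slope_sd²) with N(0, prior_sd²) priors;
5. log slope_sd — scalar Metropolis with a half-normal prior on
   slope_sd (log-scale proposal, Jacobian included).

Proposal scales adapt toward a target acceptance rate during burn-in
only, so retained draws come from a fixed kernel.  All randomness flows
from a single ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit, log_expit

from .data_model import (
    ITEM_INDEX,
    KATZ_ITEMS,
    PanelDataset,
    ValidationError,
    covariate_matrix,
)
from .grm import LOG_FLOOR

N_ITEMS = len(KATZ_ITEMS)


@dataclass
class PackedPanel:
    """Array view of a panel for fast likelihood evaluation."""

    subject_ids: list[str]
    Z: np.ndarray  # (n_subjects, 5) standardized design
    resp_subj: np.ndarray  # (m,) int subject index, non-missing responses only
    resp_time: np.ndarray  # (m,) float visit time
    resp_item: np.ndarray  # (m,) int item index
    resp_cat: np.ndarray  # (m,) int category 0/1/2
    visit_subj: np.ndarray  # (v,) subject index of each unique (subject, visit)
    visit_time: np.ndarray  # (v,) visit time of each unique (subject, visit)
    visit_keys: list[tuple[str, float]]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_responses(self) -> int:
        return int(self.resp_subj.size)


def pack_panel(dataset: PanelDataset) -> PackedPanel:
    """Convert a validated, standardized panel to packed arrays."""
    if dataset.n_subjects == 0:
        raise ValidationError("cannot fit an empty dataset")
    subject_ids = [s.subject_id for s in dataset.subjects]
    sidx = {sid: i for i, sid in enumerate(subject_ids)}
    Z = covariate_matrix(dataset)

    subj, time, item, cat = [], [], [], []
    visit_keys_set: dict[tuple[str, float], None] = {}
    for r in dataset.responses:
        visit_keys_set.setdefault((r.subject_id, r.visit_time))
        if r.category is None:
            continue
        subj.append(sidx[r.subject_id])
        time.append(r.visit_time)
        item.append(ITEM_INDEX[r.item])
        cat.append(r.category)
    visit_keys = list(visit_keys_set)
    return PackedPanel(
        subject_ids=subject_ids,
        Z=Z,
        resp_subj=np.asarray(subj, dtype=np.int64),
        resp_time=np.asarray(time, dtype=float),
        resp_item=np.asarray(item, dtype=np.int64),
        resp_cat=np.asarray(cat, dtype=np.int64),
        visit_subj=np.asarray([sidx[k[0]] for k in visit_keys], dtype=np.int64),
        visit_time=np.asarray([k[1] for k in visit_keys], dtype=float),
        visit_keys=visit_keys,
    )


def resp_loglik_arrays(
    a_r: np.ndarray,
    kp_r: np.ndarray,
    kt_r: np.ndarray,
    theta_r: np.ndarray,
    cat_r: np.ndarray,
) -> np.ndarray:
    """Per-response GRM log-likelihood, floored at LOG_FLOOR."""
    x1 = a_r * theta_r - kp_r
    x2 = a_r * theta_r - kt_r
    ll = np.empty_like(theta_r)
    m0 = cat_r == 0
    m1 = cat_r == 1
    m2 = cat_r == 2
    ll[m0] = log_expit(-x1[m0])
    ll[m2] = log_expit(x2[m2])
    pmid = expit(x1[m1]) - expit(x2[m1])
    with np.errstate(divide="ignore"):
        ll[m1] = np.log(np.maximum(pmid, 0.0))
    return np.maximum(ll, LOG_FLOOR)


@dataclass
class SamplerSettings:
    """Tuning knobs of the Metropolis-within-Gibbs kernel."""

    target_accept: float = 0.35
    adapt_interval: int = 25
    item_scale: float = 0.1
    subject_scale: float = 0.5
    lssd_scale: float = 0.2


@dataclass
class PriorSettings:
    """Weakly informative priors on the structural parameters."""

    alpha_logsd: float = 1.0  # alpha ~ LogNormal(0, alpha_logsd²)
    kappa_sd: float = 10.0  # kappa_partial ~ N(0, kappa_sd²)
    delta_logsd: float = 1.0  # kappa_total - kappa_partial ~ LogNormal(0, delta_logsd²)
    mu_sd: float = 10.0
    beta_sd: float = 10.0
    slope_sd_scale: float = 5.0  # slope_sd ~ HalfNormal(slope_sd_scale)
    gamma0_sd: float = 1.0  # fixed N(0,1) anchor of the latent scale


@dataclass
class ChainResult:
    """Raw output of one chain."""

    alpha: np.ndarray  # (n_keep, 6)
    kappa_partial: np.ndarray
    kappa_total: np.ndarray
    mu: np.ndarray  # (n_keep,)
    beta: np.ndarray  # (n_keep, 5)
    slope_sd: np.ndarray
    gamma0_mean: np.ndarray  # (n,)
    gamma1_mean: np.ndarray
    gamma1_raw_mean: np.ndarray
    theta_mean: np.ndarray  # (v,) posterior mean latent state per (subject, visit)
    gamma0_draws: Optional[np.ndarray]  # (n_keep, n) if stored
    gamma1_draws: Optional[np.ndarray]
    accept_rates: dict[str, float]


def run_chain(
    panel: PackedPanel,
    n_burnin: int,
    n_keep: int,
    thin: int,
    rng: np.random.Generator,
    prior: PriorSettings,
    settings: SamplerSettings,
    store_subject_draws: bool = False,
) -> ChainResult:
    n = panel.n_subjects
    m = panel.n_responses
    Z = panel.Z
    s_r = panel.resp_subj
    t_r = panel.resp_time
    i_r = panel.resp_item
    c_r = panel.resp_cat

    # --- state ---------------------------------------------------------
    la = np.zeros(N_ITEMS)  # log alpha (prior median alpha = 1)
    kp = np.zeros(N_ITEMS)
    ld = np.zeros(N_ITEMS)  # log delta (prior median delta = 1)
    g0 = np.zeros(n)
    g1 = np.zeros(n)
    mu = 0.0
    beta = np.zeros(5)
    lssd = 0.0  # log slope_sd

    alpha = np.exp(la)
    kt = kp + np.exp(ld)

    # gathered per-response parameter views
    a_r = alpha[i_r]
    kp_r = kp[i_r]
    kt_r = kt[i_r]
    theta_r = g0[s_r] + g1[s_r] * t_r
    ll_r = resp_loglik_arrays(a_r, kp_r, kt_r, theta_r, c_r)
    if not np.isfinite(ll_r.sum()):
        raise ValidationError("non-finite log-posterior at initialization")

    item_idx = [np.flatnonzero(i_r == i) for i in range(N_ITEMS)]

    # proposal scales + windowed acceptance counters
    sc_item = np.full((N_ITEMS, 3), settings.item_scale)
    sc_g0 = np.full(n, settings.subject_scale)
    sc_g1 = np.full(n, settings.subject_scale)
    sc_lssd = settings.lssd_scale
    acc_item = np.zeros((N_ITEMS, 3))
    acc_g0 = np.zeros(n)
    acc_g1 = np.zeros(n)
    acc_lssd = 0.0
    tot_g0 = 0
    tot_g1 = 0
    tot_lssd = 0
    # lifetime acceptance counters (post burn-in)
    keep_acc = {"item": 0.0, "item_n": 0.0, "g0": 0.0, "g0_n": 0.0, "g1": 0.0, "g1_n": 0.0}

    XtX = None
    X = np.column_stack([np.ones(n), Z])  # (n, 6) design for (mu, beta)
    XtX = X.T @ X
    prior_prec_mb = np.diag([1.0 / prior.mu_sd**2] + [1.0 / prior.beta_sd**2] * 5)

    n_iter = n_burnin + n_keep * thin
    kept = 0
    out_alpha = np.empty((n_keep, N_ITEMS))
    out_kp = np.empty((n_keep, N_ITEMS))
    out_kt = np.empty((n_keep, N_ITEMS))
    out_mu = np.empty(n_keep)
    out_beta = np.empty((n_keep, 5))
    out_ssd = np.empty(n_keep)
    g0_sum = np.zeros(n)
    g1_sum = np.zeros(n)
    g1raw_sum = np.zeros(n)
    theta_sum = np.zeros(panel.visit_subj.size)
    g0_draws = np.empty((n_keep, n)) if store_subject_draws else None
    g1_draws = np.empty((n_keep, n)) if store_subject_draws else None

    two_pi = 2.0 * np.pi

    def item_prior(j: int, value: float) -> float:
        # prior log-density in the sampling parameterization
        if j == 0:  # la ~ N(0, alpha_logsd²)
            return -0.5 * (value / prior.alpha_logsd) ** 2
        if j == 1:  # kp ~ N(0, kappa_sd²)
            return -0.5 * (value / prior.kappa_sd) ** 2
        return -0.5 * (value / prior.delta_logsd) ** 2  # ld ~ N(0, delta_logsd²)

    for it in range(n_iter):
        adapting = it < n_burnin

        # ---- block 1: item parameters --------------------------------
        for i in range(N_ITEMS):
            idx = item_idx[i]
            for j in range(3):
                cur = (la[i], kp[i], ld[i])[j]
                prop = cur + sc_item[i, j] * rng.standard_normal()
                la_p, kp_p, ld_p = la[i], kp[i], ld[i]
                if j == 0:
                    la_p = prop
                elif j == 1:
                    kp_p = prop
                else:
                    ld_p = prop
                a_new = np.exp(la_p)
                kt_new = kp_p + np.exp(ld_p)
                if idx.size:
                    ll_new = resp_loglik_arrays(
                        np.full(idx.size, a_new),
                        np.full(idx.size, kp_p),
                        np.full(idx.size, kt_new),
                        theta_r[idx],
                        c_r[idx],
                    )
                    dll = ll_new.sum() - ll_r[idx].sum()
                else:
                    ll_new = None
                    dll = 0.0
                logr = dll + item_prior(j, prop) - item_prior(j, cur)
                accepted = np.log(rng.random()) < logr
                if accepted:
                    acc_item[i, j] += 1
                    la[i], kp[i], ld[i] = la_p, kp_p, ld_p
                    alpha[i] = a_new
                    kt[i] = kt_new
                    if idx.size:
                        ll_r[idx] = ll_new
                        a_r[idx] = a_new
                        kp_r[idx] = kp_p
                        kt_r[idx] = kt_new
                if not adapting:
                    keep_acc["item_n"] += 1
                    keep_acc["item"] += 1.0 if accepted else 0.0

        # ---- block 2: gamma0 ------------------------------------------
        zb = Z @ beta
        prop_g0 = g0 + sc_g0 * rng.standard_normal(n)
        if m:
            theta_new = prop_g0[s_r] + g1[s_r] * t_r
            ll_new = resp_loglik_arrays(a_r, kp_r, kt_r, theta_new, c_r)
            cur_s = np.bincount(s_r, weights=ll_r, minlength=n)
            new_s = np.bincount(s_r, weights=ll_new, minlength=n)
        else:
            theta_new = theta_r
            ll_new = ll_r
            cur_s = np.zeros(n)
            new_s = np.zeros(n)
        logr = (
            new_s
            - cur_s
            + 0.5 * (g0**2 - prop_g0**2) / prior.gamma0_sd**2
        )
        acc = np.log(rng.random(n)) < logr
        g0 = np.where(acc, prop_g0, g0)
        if m:
            mask = acc[s_r]
            ll_r[mask] = ll_new[mask]
            theta_r[mask] = theta_new[mask]
        acc_g0 += acc
        tot_g0 += 1
        if not adapting:
            keep_acc["g0"] += acc.mean()
            keep_acc["g0_n"] += 1

        # ---- block 3: gamma1 (total slope) ----------------------------
        ssd = np.exp(lssd)
        slope_mean = mu + zb
        prop_g1 = g1 + sc_g1 * rng.standard_normal(n)
        if m:
            theta_new = g0[s_r] + prop_g1[s_r] * t_r
            ll_new = resp_loglik_arrays(a_r, kp_r, kt_r, theta_new, c_r)
            cur_s = np.bincount(s_r, weights=ll_r, minlength=n)
            new_s = np.bincount(s_r, weights=ll_new, minlength=n)
        else:
            theta_new = theta_r
            ll_new = ll_r
            cur_s = np.zeros(n)
            new_s = np.zeros(n)
        logr = (
            new_s
            - cur_s
            + 0.5 * ((g1 - slope_mean) ** 2 - (prop_g1 - slope_mean) ** 2) / ssd**2
        )
        acc = np.log(rng.random(n)) < logr
        g1 = np.where(acc, prop_g1, g1)
        if m:
            mask = acc[s_r]
            ll_r[mask] = ll_new[mask]
            theta_r[mask] = theta_new[mask]
        acc_g1 += acc
        tot_g1 += 1
        if not adapting:
            keep_acc["g1"] += acc.mean()
            keep_acc["g1_n"] += 1

        # ---- block 4: (mu, beta) exact Gibbs --------------------------
        ssd2 = np.exp(2.0 * lssd)
        A = XtX / ssd2 + prior_prec_mb
        b = X.T @ g1 / ssd2
        chol = np.linalg.cholesky(A)
        mean_mb = np.linalg.solve(A, b)
        draw = mean_mb + np.linalg.solve(chol.T, rng.standard_normal(6))
        mu = float(draw[0])
        beta = draw[1:]

        # ---- block 5: log slope_sd ------------------------------------
        resid = g1 - mu - Z @ beta
        ss = float(resid @ resid)

        def lssd_logpost(v: float) -> float:
            s = np.exp(v)
            # HalfNormal(scale) prior on ssd, plus log-Jacobian of the
            # log transform (+v).
            return (
                -n * v
                - 0.5 * ss / s**2
                - 0.5 * (s / prior.slope_sd_scale) ** 2
                + v
            )

        prop = lssd + sc_lssd * rng.standard_normal()
        tot_lssd += 1
        if np.log(rng.random()) < lssd_logpost(prop) - lssd_logpost(lssd):
            lssd = prop
            acc_lssd += 1

        # ---- adaptation (burn-in only) --------------------------------
        if adapting and (it + 1) % settings.adapt_interval == 0:
            w = settings.adapt_interval
            rate = acc_item / w
            sc_item *= np.exp(rate - settings.target_accept)
            np.clip(sc_item, 1e-3, 10.0, out=sc_item)
            acc_item[:] = 0
            rate0 = acc_g0 / tot_g0
            sc_g0 *= np.exp(0.7 * (rate0 - settings.target_accept))
            np.clip(sc_g0, 1e-3, 10.0, out=sc_g0)
            acc_g0[:] = 0
            tot_g0 = 0
            rate1 = acc_g1 / tot_g1
            sc_g1 *= np.exp(0.7 * (rate1 - settings.target_accept))
            np.clip(sc_g1, 1e-3, 10.0, out=sc_g1)
            acc_g1[:] = 0
            tot_g1 = 0
            sc_lssd *= float(np.exp(acc_lssd / tot_lssd - settings.target_accept))
            sc_lssd = float(np.clip(sc_lssd, 1e-3, 10.0))
            acc_lssd = 0.0
            tot_lssd = 0

        # ---- record ----------------------------------------------------
        if it >= n_burnin and (it - n_burnin) % thin == 0 and kept < n_keep:
            out_alpha[kept] = alpha
            out_kp[kept] = kp
            out_kt[kept] = kt
            out_mu[kept] = mu
            out_beta[kept] = beta
            out_ssd[kept] = np.exp(lssd)
            g0_sum += g0
            g1_sum += g1
            g1raw_sum += g1 - Z @ beta
            theta_sum += g0[panel.visit_subj] + g1[panel.visit_subj] * panel.visit_time
            if store_subject_draws:
                g0_draws[kept] = g0
                g1_draws[kept] = g1
            kept += 1

    denom = max(kept, 1)
    rates = {
        "item": keep_acc["item"] / max(keep_acc["item_n"], 1),
        "gamma0": keep_acc["g0"] / max(keep_acc["g0_n"], 1),
        "gamma1": keep_acc["g1"] / max(keep_acc["g1_n"], 1),
    }
    return ChainResult(
        alpha=out_alpha,
        kappa_partial=out_kp,
        kappa_total=out_kt,
        mu=out_mu,
        beta=out_beta,
        slope_sd=out_ssd,
        gamma0_mean=g0_sum / denom,
        gamma1_mean=g1_sum / denom,
        gamma1_raw_mean=g1raw_sum / denom,
        theta_mean=theta_sum / denom,
        gamma0_draws=g0_draws,
        gamma1_draws=g1_draws,
        accept_rates=rates,
    )
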