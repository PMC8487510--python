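"""Graded-response model: probabilities, log-likelihoods, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from adlirt.data_model import KATZ_ITEMS, KatzItem, ValidationError
from adlirt.grm import (
    LOG_FLOOR,
    ItemParameters,
    category_probs,
    cumulative_prob,
    item_parameters_from_json,
    item_parameters_to_json,
    panel_loglik,
    response_loglik,
)
from conftest import make_panel, make_subject

BATHING = KatzItem.BATHING


def params(alpha=1.0, kp=-1.0, kt=1.0, item=BATHING) -> ItemParameters:
    return ItemParameters(item=item, alpha=alpha, kappa_partial=kp, kappa_total=kt)


item_param_strategy = st.tuples(
    st.floats(min_value=0.05, max_value=8.0),
    st.floats(min_value=-5.0, max_value=5.0),
    st.floats(min_value=0.05, max_value=6.0),
).map(lambda t: params(alpha=t[0], kp=t[1], kt=t[1] + t[2]))


def test_cumulative_prob_values():
    assert cumulative_prob(1.0, 0.0, 0.0) == pytest.approx(0.5)
    # logistic at +1: 1 / (1 + e^-1)
    assert cumulative_prob(2.0, 1.0, 1.0) == pytest.approx(0.7310585786300049)
    assert cumulative_prob(1.0, 0.0, 50.0) == pytest.approx(1.0, abs=1e-12)


def test_cumulative_prob_half_at_threshold():
    p = params(alpha=1.291, kp=-1.396, kt=-0.374)
    theta = p.kappa_partial / p.alpha
    assert cumulative_prob(p.alpha, p.kappa_partial, theta) == pytest.approx(0.5)


def test_cumulative_prob_rejects_bad_inputs():
    with pytest.raises(ValidationError):
        cumulative_prob(-1.0, 0.0, 0.0)
    with pytest.raises(ValidationError):
        cumulative_prob(1.0, 0.0, float("nan"))


def test_category_probs_hand_example():
    # alpha=1, kappas=(-1, 1), theta=0: p1 = expit(1) - expit(-1)
    p = category_probs(params(), 0.0)
    assert p == pytest.approx([0.2689414213699951, 0.4621171572600098, 0.2689414213699951])
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


def test_invalid_item_parameters():
    with pytest.raises(ValidationError):
        params(alpha=0.0)
    with pytest.raises(ValidationError):
        params(kp=1.0, kt=1.0)
    with pytest.raises(ValidationError):
        params(kp=2.0, kt=1.0)


@given(item_param_strategy, st.floats(min_value=-20, max_value=20))
def test_category_probs_normalized_and_valid(p, theta):
    probs = category_probs(p, theta)
    assert probs.shape == (3,)
    assert np.all(probs >= -1e-15)
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)


moderate_param_strategy = st.tuples(
    st.floats(min_value=0.05, max_value=6.0),
    st.floats(min_value=-4.0, max_value=4.0),
    st.floats(min_value=0.05, max_value=5.0),
).map(lambda t: params(alpha=t[0], kp=t[1], kt=t[1] + t[2]))


@given(moderate_param_strategy, st.floats(min_value=-3, max_value=3))
def test_monotone_dominance_and_ordering(p, theta):
    """P(Y>=1) >= P(Y>=2), both strictly increasing in theta.

    Parameters are kept in the regime where the logistic has not
    saturated to 1.0 in double precision, so strictness is meaningful.
    """
    eps = 0.37
    p1_lo = cumulative_prob(p.alpha, p.kappa_partial, theta)
    p2_lo = cumulative_prob(p.alpha, p.kappa_total, theta)
    assert p1_lo >= p2_lo
    p1_hi = cumulative_prob(p.alpha, p.kappa_partial, theta + eps)
    p2_hi = cumulative_prob(p.alpha, p.kappa_total, theta + eps)
    assert p1_hi > p1_lo
    assert p2_hi > p2_lo
    ey_lo = float(category_probs(p, theta) @ np.arange(3))
    ey_hi = float(category_probs(p, theta + eps) @ np.arange(3))
    assert ey_hi > ey_lo


@given(
    st.floats(min_value=0.1, max_value=5.0),
    st.floats(min_value=0.1, max_value=4.0),
)
def test_symmetric_thresholds_give_symmetric_tails(alpha, a):
    probs = category_probs(params(alpha=alpha, kp=-a, kt=a), 0.0)
    assert probs[0] == pytest.approx(probs[2], abs=1e-12)


def test_response_loglik_contracts():
    p = params()
    assert response_loglik(p, 0.0, None) == 0.0
    expected = math.log(expit(1.0) - expit(-1.0))
    assert response_loglik(p, 0.0, 1) == pytest.approx(expected)
    assert expected == pytest.approx(-0.7719368, abs=1e-6)
    with pytest.raises(ValidationError):
        response_loglik(p, 0.0, 3)
    with pytest.raises(ValidationError):
        response_loglik(p, 0.0, -1)


def test_response_loglik_underflow_guard():
    ll = response_loglik(params(alpha=5.0), -50.0, 2)
    assert math.isfinite(ll)
    assert ll >= LOG_FLOOR


def _softplus(x: float) -> float:
    return x + math.log1p(math.exp(-x)) if x > 0 else math.log1p(math.exp(x))


def _brute_force_loglik(item_map, thetas, dataset):
    """Independent double-loop oracle using raw logistic arithmetic.

    log(1 − logistic(x)) is evaluated as −softplus(x) so the oracle stays
    accurate where the logistic saturates in double precision.
    """
    total = 0.0
    for r in dataset.responses:
        if r.category is None:
            continue
        p = item_map[r.item]
        th = thetas[(r.subject_id, r.visit_time)]
        x1 = p.alpha * th - p.kappa_partial
        x2 = p.alpha * th - p.kappa_total
        if r.category == 0:
            ll = -_softplus(x1)
        elif r.category == 2:
            ll = -_softplus(-x2)
        else:
            c1 = 1.0 / (1.0 + math.exp(-x1))
            c2 = 1.0 / (1.0 + math.exp(-x2))
            ll = math.log(c1 - c2) if c1 > c2 else LOG_FLOOR
        total += max(ll, LOG_FLOOR)
    return total


def _random_small_panel(rng):
    n = rng.integers(2, 6)
    subjects = [
        make_subject(f"S{i}", death=12.0, visits=(0.0, float(rng.uniform(1, 8))))
        for i in range(n)
    ]
    cats = {}
    for s in subjects:
        for t in s.visits:
            cats[(s.subject_id, t)] = [
                None if rng.random() < 0.2 else int(rng.integers(0, 3)) for _ in range(6)
            ]
    panel = make_panel(subjects, cats)
    item_map = {}
    for it in KATZ_ITEMS:
        kp = float(rng.uniform(-3, 1))
        item_map[it] = params(
            alpha=float(rng.uniform(0.3, 4.0)),
            kp=kp,
            kt=kp + float(rng.uniform(0.1, 4.0)),
            item=it,
        )
    thetas = {
        (s.subject_id, t): float(rng.normal(0, 2)) for s in subjects for t in s.visits
    }
    return item_map, thetas, panel


def test_panel_loglik_matches_brute_force():
    rng = np.random.default_rng(42)
    for _ in range(25):
        item_map, thetas, panel = _random_small_panel(rng)
        assert panel_loglik(item_map, thetas, panel) == pytest.approx(
            _brute_force_loglik(item_map, thetas, panel), abs=1e-9
        )


def test_panel_loglik_edge_cases():
    s = make_subject("S1", visits=(0.0,))
    one = make_panel([s], {("S1", 0.0): [1, None, None, None, None, None]})
    item_map = {it: params(item=it) for it in KATZ_ITEMS}
    thetas = {("S1", 0.0): 0.3}
    assert panel_loglik(item_map, thetas, one) == pytest.approx(
        response_loglik(item_map[KATZ_ITEMS[0]], 0.3, 1)
    )
    all_missing = make_panel([s], {("S1", 0.0): [None] * 6})
    assert panel_loglik(item_map, thetas, all_missing) == 0.0
    with pytest.raises(ValidationError, match="theta"):
        panel_loglik(item_map, {}, one)


def test_item_parameters_json_roundtrip(tmp_path):
    item_map = {it: params(alpha=1.5, kp=-0.5, kt=2.0, item=it) for it in KATZ_ITEMS}
    path = tmp_path / "items.json"
    item_parameters_to_json(item_map, path)
    back = item_parameters_from_json(path)
    assert back == item_map
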