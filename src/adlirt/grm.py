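"""Samejima graded-response model for three-category Katz items.

Each item *i* has a discrimination ``alpha_i > 0`` and two strictly
ordered thresholds ``kappa_partial < kappa_total`` on the latent
disability scale.  The model is built from cumulative logistic curves

    P(Y >= k | theta) = logistic(alpha * theta - kappa_k),   k in {1, 2}

with the boundary identities P(Y >= 0) = 1 and P(Y >= 3) = 0, so the
category probabilities are successive differences.  Larger theta means
more severe disability; a smaller kappa marks an ability lost earlier.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.special import expit, log_expit

from .data_model import KATZ_ITEMS, KatzItem, PanelDataset, ValidationError

__all__ = [
    "LOG_FLOOR",
    "ItemParameters",
    "cumulative_prob",
    "category_probs",
    "response_loglik",
    "panel_loglik",
    "item_parameters_to_json",
    "item_parameters_from_json",
]

#: Floor on log-probabilities (log of the smallest positive normal
#: double), keeping MCMC arithmetic finite under extreme parameters.
LOG_FLOOR = -745.0


@dataclass(frozen=True)
class ItemParameters:
    """GRM parameters of one Katz item.

    Raises :class:`ValidationError` unless ``alpha > 0`` and
    ``kappa_partial < kappa_total`` (strict) — an unordered pair would
    make the middle-category probability negative.
    """

    item: KatzItem
    alpha: float
    kappa_partial: float
    kappa_total: float

    def __post_init__(self) -> None:
        vals = (self.alpha, self.kappa_partial, self.kappa_total)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"non-finite item parameters: {vals}")
        if self.alpha <= 0:
            raise ValidationError(f"alpha must be > 0, got {self.alpha}")
        if not self.kappa_partial < self.kappa_total:
            raise ValidationError(
                f"thresholds must satisfy kappa_partial < kappa_total, got "
                f"({self.kappa_partial}, {self.kappa_total})"
            )


ArrayLike = Union[float, np.ndarray]


def cumulative_prob(alpha: float, kappa: float, theta: ArrayLike) -> ArrayLike:
    """P(Y >= k | theta) = logistic(alpha * theta - kappa).

    Strictly increasing in theta and equal to 1/2 exactly where
    ``alpha * theta == kappa``.  Accepts scalar or array theta.
    """
    if not (math.isfinite(alpha) and math.isfinite(kappa)):
        raise ValidationError("alpha and kappa must be finite")
    if alpha <= 0:
        raise ValidationError(f"alpha must be > 0, got {alpha}")
    theta_arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta_arr)):
        raise ValidationError("theta must be finite")
    out = expit(alpha * theta_arr - kappa)
    return float(out) if np.isscalar(theta) or theta_arr.ndim == 0 else out


def category_probs(params: ItemParameters, theta: ArrayLike) -> np.ndarray:
    """Probabilities (p0, p1, p2) of the three ordered categories.

    Returned along the last axis; sums to 1 to machine precision.
    """
    p_ge1 = cumulative_prob(params.alpha, params.kappa_partial, theta)
    p_ge2 = cumulative_prob(params.alpha, params.kappa_total, theta)
    p0 = 1.0 - np.asarray(p_ge1)
    p1 = np.asarray(p_ge1) - np.asarray(p_ge2)
    p2 = np.asarray(p_ge2)
    return np.stack([p0, p1, p2], axis=-1)


def response_loglik(
    params: ItemParameters, theta: float, category: Optional[int]
) -> float:
    """Log-probability of one observed category; missing contributes 0.

    Computed on the log scale (``log_expit``) so extreme theta values
    underflow gracefully to the :data:`LOG_FLOOR` rather than ``-inf``.
    """
    if category is None:
        return 0.0
    if category not in (0, 1, 2):
        raise ValidationError(f"category must be 0/1/2 or missing, got {category!r}")
    x1 = params.alpha * theta - params.kappa_partial
    x2 = params.alpha * theta - params.kappa_total
    if category == 0:
        ll = float(log_expit(-x1))
    elif category == 2:
        ll = float(log_expit(x2))
    else:
        p1 = float(expit(x1)) - float(expit(x2))
        ll = math.log(p1) if p1 > 0 else LOG_FLOOR
    return max(ll, LOG_FLOOR)


def _as_item_map(
    item_params: Union[Mapping[KatzItem, ItemParameters], Sequence[ItemParameters]],
) -> Mapping[KatzItem, ItemParameters]:
    if isinstance(item_params, Mapping):
        return item_params
    return {p.item: p for p in item_params}


def panel_loglik(
    item_params: Union[Mapping[KatzItem, ItemParameters], Sequence[ItemParameters]],
    thetas: Mapping[tuple[str, float], float],
    dataset: PanelDataset,
) -> float:
    """Total log-likelihood of a panel given per-(subject, visit) theta.

    Sums :func:`response_loglik` over all non-missing responses; raises
    if a non-missing response has no matching theta.
    """
    params = _as_item_map(item_params)
    total = 0.0
    for r in dataset.responses:
        if r.category is None:
            continue
        key = (r.subject_id, r.visit_time)
        if key not in thetas:
            raise ValidationError(f"no theta provided for (subject, visit) {key}")
        total += response_loglik(params[r.item], thetas[key], r.category)
    return total


def item_parameters_to_json(
    item_params: Union[Mapping[KatzItem, ItemParameters], Sequence[ItemParameters]],
    path: Optional[str | Path] = None,
) -> str:
    """Serialize item parameters; optionally write to ``path``."""
    params = _as_item_map(item_params)
    payload = [
        {
            "item": item.value,
            "alpha": params[item].alpha,
            "kappa_partial": params[item].kappa_partial,
            "kappa_total": params[item].kappa_total,
        }
        for item in KATZ_ITEMS
        if item in params
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def item_parameters_from_json(source: str | Path) -> dict[KatzItem, ItemParameters]:
    """Read item parameters from a JSON string or file, validating invariants."""
    text = (
        Path(source).read_text()
        if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists())
        else str(source)
    )
    payload = json.loads(text)
    out: dict[KatzItem, ItemParameters] = {}
    for entry in payload:
        item = KatzItem(entry["item"])
        out[item] = ItemParameters(
            item=item,
            alpha=float(entry["alpha"]),
            kappa_partial=float(entry["kappa_partial"]),
            kappa_total=float(entry["kappa_total"]),
        )
    return out
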