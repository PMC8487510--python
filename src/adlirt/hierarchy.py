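"""From fitted item parameters to the substantive ADL outputs.

* the ordered loss hierarchy: all 12 (item, level) thresholds sorted by
  difficulty kappa — smaller kappa means the ability is lost earlier on
  the disability continuum;
* partial→total threshold gaps per item (how much further along the
  continuum total loss lies beyond partial loss);
* discrimination bands and an applicability check (every item should
  discriminate with alpha > 0.3 for the scale to be usable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

from .data_model import ITEM_INDEX, KATZ_ITEMS, KatzItem, ValidationError
from .grm import ItemParameters

__all__ = [
    "ThresholdEntry",
    "entries_from_item_parameters",
    "rank_thresholds",
    "threshold_gap",
    "classify_discrimination",
    "applicability_check",
    "DISCRIMINATION_SCHEMES",
]

_LEVELS = ("partial", "total")


@dataclass(frozen=True)
class ThresholdEntry:
    """One difficulty threshold with its posterior uncertainty."""

    item: KatzItem
    level: str  # "partial" or "total"
    kappa: float
    se: float = math.nan
    q2_5: float = math.nan
    q97_5: float = math.nan

    def __post_init__(self) -> None:
        if self.level not in _LEVELS:
            raise ValidationError(f"level must be one of {_LEVELS}, got {self.level!r}")

    @property
    def label(self) -> str:
        return f"{self.item.value}_{self.level}"


def entries_from_item_parameters(
    items: Union[Mapping[KatzItem, ItemParameters], Sequence[ItemParameters]],
) -> list[ThresholdEntry]:
    """Expand six fitted items into the 12 threshold entries."""
    params = items if isinstance(items, Mapping) else {p.item: p for p in items}
    out = []
    for it in KATZ_ITEMS:
        p = params[it]
        out.append(ThresholdEntry(item=it, level="partial", kappa=p.kappa_partial))
        out.append(ThresholdEntry(item=it, level="total", kappa=p.kappa_total))
    return out


def _check_complete(entries: Iterable[ThresholdEntry]) -> dict[tuple[KatzItem, str], ThresholdEntry]:
    by_key: dict[tuple[KatzItem, str], ThresholdEntry] = {}
    for e in entries:
        key = (e.item, e.level)
        if key in by_key:
            raise ValidationError(f"duplicate threshold entry for {e.label}")
        by_key[key] = e
    for it in KATZ_ITEMS:
        for level in _LEVELS:
            if (it, level) not in by_key:
                raise ValidationError(f"missing threshold entry for {it.value}_{level}")
    return by_key


def rank_thresholds(entries: Sequence[ThresholdEntry]) -> list[ThresholdEntry]:
    """The ADL loss hierarchy: all 12 thresholds in ascending kappa.

    Ties break by the canonical item order, then partial before total,
    so the output is deterministic.  Requires exactly one entry per
    (item, level).
    """
    _check_complete(entries)
    return sorted(
        entries,
        key=lambda e: (e.kappa, ITEM_INDEX[e.item], _LEVELS.index(e.level)),
    )


def threshold_gap(entries: Sequence[ThresholdEntry], item: KatzItem) -> float:
    """kappa_total − kappa_partial for one item (posterior means).

    The distance along the disability continuum between losing an
    ability partially and losing it totally.
    """
    by_key = {}
    for e in entries:
        by_key[(e.item, e.level)] = e
    for level in _LEVELS:
        if (item, level) not in by_key:
            raise ValidationError(f"missing {level} threshold for item {item.value}")
    return by_key[(item, "total")].kappa - by_key[(item, "partial")].kappa


#: Discrimination band edges, half-open on the left: a value maps to the
#: band whose interval [lo, hi) contains it.
DISCRIMINATION_SCHEMES: dict[str, tuple[tuple[float, str], ...]] = {
    "baker_logistic": (
        (0.0, "none"),
        (0.01, "very_low"),
        (0.35, "low"),
        (0.65, "moderate"),
        (1.35, "high"),
        (1.70, "very_high"),
    ),
}


def classify_discrimination(alpha: float, scheme: str = "baker_logistic") -> str:
    """Map a discrimination value to a qualitative band.

    The default bands follow the common logistic-metric discrimination
    table (none < 0.01 ≤ very_low < 0.35 ≤ low < 0.65 ≤ moderate < 1.35
    ≤ high < 1.70 ≤ very_high); other schemes can be registered in
    :data:`DISCRIMINATION_SCHEMES`.
    """
    if scheme not in DISCRIMINATION_SCHEMES:
        raise ValidationError(
            f"unknown discrimination scheme {scheme!r}; "
            f"known: {sorted(DISCRIMINATION_SCHEMES)}"
        )
    if alpha < 0:
        raise ValidationError(f"alpha must be >= 0, got {alpha}")
    bands = DISCRIMINATION_SCHEMES[scheme]
    label = bands[0][1]
    for lo, name in bands:
        if alpha >= lo:
            label = name
    return label


def applicability_check(
    items: Union[Mapping[KatzItem, ItemParameters], Sequence[ItemParameters]],
    threshold: float = 0.3,
) -> dict[str, object]:
    """Flag items whose discrimination fails alpha > threshold (strict).

    A scale is applicable to the population only if every item
    discriminates; the overall verdict passes iff no item is flagged.
    """
    params = items if isinstance(items, Mapping) else {p.item: p for p in items}
    per_item = {
        it.value: bool(params[it].alpha > threshold) for it in KATZ_ITEMS if it in params
    }
    return {
        "threshold": threshold,
        "per_item": per_item,
        "overall": all(per_item.values()),
    }
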