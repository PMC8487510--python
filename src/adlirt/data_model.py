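"""Canonical containers and tabular I/O for Katz ADL panel data.

A panel holds one record per (subject, visit, item) with an ordinal
category — 0 no limitation, 1 partial limitation, 2 totally limited —
or a missing value, plus per-subject covariates and the time of death
measured from the subject's first interview.  Everything downstream
(simulation, Bayesian fitting, hierarchy and trajectory analysis)
consumes these types.

Missing responses are represented internally as ``None`` (never a
numeric sentinel); in delimited files they appear as an empty field or
``NA``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "KatzItem",
    "KATZ_ITEMS",
    "ITEM_INDEX",
    "COVARIATE_NAMES",
    "SchemaError",
    "ValidationError",
    "ReferentialError",
    "ResponseRecord",
    "SubjectCovariates",
    "Subject",
    "PanelDataset",
    "load_panel",
    "write_panel",
    "apply_inclusion_filter",
    "standardize_covariates",
    "covariate_matrix",
    "baseline_table",
    "write_exclusion_report",
]


class SchemaError(ValueError):
    """A required column is absent or a file cannot be interpreted."""


class ValidationError(ValueError):
    """A value violates the panel invariants (range, uniqueness, ...)."""


class ReferentialError(ValidationError):
    """A response refers to a subject that does not exist."""


class KatzItem(str, Enum):
    """The six Katz basic activities of daily living.

    The declaration order is the canonical item order used for stable
    serialization and deterministic tie-breaking throughout the package.
    """

    BATHING = "bathing"
    DRESSING = "dressing"
    TOILETING = "toileting"
    TRANSFERRING = "transferring"
    CONTINENCE = "continence"
    FEEDING = "feeding"


KATZ_ITEMS: tuple[KatzItem, ...] = tuple(KatzItem)
ITEM_INDEX: dict[KatzItem, int] = {item: i for i, item in enumerate(KATZ_ITEMS)}

#: Order of covariates in the slope-regression design vector Z.
COVARIATE_NAMES: tuple[str, ...] = (
    "sex",
    "age_std",
    "residence",
    "education_std",
    "marital",
)

_CATEGORIES = (0, 1, 2)


@dataclass(frozen=True)
class ResponseRecord:
    """One Katz item response at one visit.

    ``category`` is 0/1/2 or ``None`` for missing; ``visit_time`` is in
    years since the subject's first interview.
    """

    subject_id: str
    visit_time: float
    item: KatzItem
    category: Optional[int]

    def __post_init__(self) -> None:
        if not (isinstance(self.visit_time, (int, float)) and math.isfinite(self.visit_time)):
            raise ValidationError(f"visit_time must be finite, got {self.visit_time!r}")
        if self.visit_time < 0:
            raise ValidationError(f"visit_time must be >= 0, got {self.visit_time}")
        if self.category is not None and self.category not in _CATEGORIES:
            raise ValidationError(
                f"category must be one of {_CATEGORIES} or missing, got {self.category!r}"
            )
        if not isinstance(self.item, KatzItem):
            raise ValidationError(f"item must be a KatzItem, got {self.item!r}")


@dataclass
class SubjectCovariates:
    """Baseline subject characteristics.

    Binary coding: sex 0 = male, 1 = female; residence 0 = urban,
    1 = rural; marital 0 = with spouse, 1 = without spouse.  ``None``
    marks an incomplete covariate (such subjects are dropped by the
    inclusion filter).  ``age_std`` / ``education_std`` are populated by
    :func:`standardize_covariates` (sample mean 0, sample SD 1).
    """

    sex: Optional[int]
    residence: Optional[int]
    marital: Optional[int]
    age_baseline: Optional[float]
    education: Optional[float]
    age_std: Optional[float] = None
    education_std: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("sex", "residence", "marital"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValidationError(f"{name} must be 0, 1 or missing, got {v!r}")

    def is_complete(self) -> bool:
        return not any(
            getattr(self, name) is None
            for name in ("sex", "residence", "marital", "age_baseline", "education")
        )


@dataclass
class Subject:
    """A study subject: covariates, death time and visit schedule.

    ``death_time`` is years since first interview (``None`` if unknown;
    such subjects are excluded from analysis).  ``visits`` lists the
    visit times at which Katz responses were collected.
    """

    subject_id: str
    covariates: SubjectCovariates
    death_time: Optional[float]
    visits: list[float] = field(default_factory=list)


@dataclass
class PanelDataset:
    """A validated collection of subjects and their item responses."""

    subjects: list[Subject]
    responses: list[ResponseRecord]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_responses(self) -> int:
        return len(self.responses)

    def subject_map(self) -> dict[str, Subject]:
        return {s.subject_id: s for s in self.subjects}

    def validate(self) -> "PanelDataset":
        """Check referential integrity and uniqueness; return self."""
        smap = self.subject_map()
        if len(smap) != len(self.subjects):
            raise ValidationError("duplicate subject_id in subjects")
        visit_sets = {sid: set(s.visits) for sid, s in smap.items()}
        seen: set[tuple[str, float, KatzItem]] = set()
        for r in self.responses:
            if r.subject_id not in smap:
                raise ReferentialError(
                    f"response refers to unknown subject {r.subject_id!r}"
                )
            if r.visit_time not in visit_sets[r.subject_id]:
                raise ValidationError(
                    f"visit_time {r.visit_time} of subject {r.subject_id!r} "
                    "is not in that subject's visit list"
                )
            key = (r.subject_id, r.visit_time, r.item)
            if key in seen:
                raise ValidationError(f"duplicate response for {key}")
            seen.add(key)
        for s in self.subjects:
            if s.death_time is not None:
                for t in s.visits:
                    if t >= s.death_time:
                        raise ValidationError(
                            f"subject {s.subject_id!r} has visit at {t} on or after "
                            f"death_time {s.death_time}"
                        )
        return self

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Export as (responses, subjects) data frames in file dialect."""
        resp = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.responses],
                "visit_time": [r.visit_time for r in self.responses],
                "item": [r.item.value for r in self.responses],
                "category": [r.category for r in self.responses],
            }
        )
        subj = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "sex": [s.covariates.sex for s in self.subjects],
                "residence": [s.covariates.residence for s in self.subjects],
                "marital": [s.covariates.marital for s in self.subjects],
                "age_baseline": [s.covariates.age_baseline for s in self.subjects],
                "education": [s.covariates.education for s in self.subjects],
                "death_time": [s.death_time for s in self.subjects],
            }
        )
        return resp, subj


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


_RESPONSE_COLUMNS = ("subject_id", "visit_time", "item", "category")
_SUBJECT_COLUMNS = (
    "subject_id",
    "sex",
    "residence",
    "marital",
    "age_baseline",
    "education",
    "death_time",
)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} file is missing required column {col!r}")


def _opt_int(v) -> Optional[int]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    f = float(v)
    if f != int(f):
        raise ValidationError(f"expected an integer code, got {v!r}")
    return int(f)


def _opt_float(v) -> Optional[float]:
    if v is None or pd.isna(v):
        return None
    return float(v)


def load_panel(responses_path: str | Path, subjects_path: str | Path) -> PanelDataset:
    """Read a panel from delimited files and validate it.

    Expected columns: responses ``subject_id, visit_time, item,
    category`` and subjects ``subject_id, sex, residence, marital,
    age_baseline, education, death_time``.  The delimiter is inferred
    from the extension (``.tsv``/``.tab`` tab, otherwise comma); missing
    values are empty fields or ``NA``.

    Out-of-range categories are rejected (never coerced).  Subjects with
    unknown death time, or without a single non-missing Katz response,
    are dropped with a logged warning — the analysis covers decedents
    with at least one measurement.
    """
    responses_path = Path(responses_path)
    subjects_path = Path(subjects_path)
    na = ["", "NA"]
    resp_df = pd.read_csv(
        responses_path, sep=_sep_for(responses_path), na_values=na, keep_default_na=False
    )
    subj_df = pd.read_csv(
        subjects_path, sep=_sep_for(subjects_path), na_values=na, keep_default_na=False
    )
    _require_columns(resp_df, _RESPONSE_COLUMNS, "responses")
    _require_columns(subj_df, _SUBJECT_COLUMNS, "subjects")

    item_by_name = {item.value: item for item in KATZ_ITEMS}

    subjects: list[Subject] = []
    dropped_no_death: list[str] = []
    for row in subj_df.itertuples(index=False):
        sid = str(row.subject_id)
        death = _opt_float(row.death_time)
        cov = SubjectCovariates(
            sex=_opt_int(row.sex),
            residence=_opt_int(row.residence),
            marital=_opt_int(row.marital),
            age_baseline=_opt_float(row.age_baseline),
            education=_opt_float(row.education),
        )
        if death is None:
            dropped_no_death.append(sid)
            continue
        subjects.append(Subject(subject_id=sid, covariates=cov, death_time=death))
    if dropped_no_death:
        logger.warning(
            "dropped %d subject(s) with unknown death_time: %s",
            len(dropped_no_death),
            ", ".join(dropped_no_death[:10]),
        )

    smap = {s.subject_id: s for s in subjects}
    dropped_ids = set(dropped_no_death)
    responses: list[ResponseRecord] = []
    for row in resp_df.itertuples(index=False):
        sid = str(row.subject_id)
        if sid in dropped_ids:
            continue
        if sid not in smap:
            raise ReferentialError(f"response refers to unknown subject {sid!r}")
        item_name = str(row.item)
        if item_name not in item_by_name:
            raise ValidationError(f"unknown Katz item {item_name!r}")
        cat = _opt_int(row.category)
        if cat is not None and cat not in _CATEGORIES:
            raise ValidationError(
                f"category {cat!r} out of range for subject {sid!r}; expected 0/1/2 or missing"
            )
        responses.append(
            ResponseRecord(
                subject_id=sid,
                visit_time=float(row.visit_time),
                item=item_by_name[item_name],
                category=cat,
            )
        )

    # Derive visit lists and apply the "at least one Katz measurement" rule.
    observed: dict[str, set[float]] = {sid: set() for sid in smap}
    has_measurement: set[str] = set()
    for r in responses:
        observed[r.subject_id].add(r.visit_time)
        if r.category is not None:
            has_measurement.add(r.subject_id)
    kept: list[Subject] = []
    dropped_all_missing: list[str] = []
    for s in subjects:
        s.visits = sorted(observed[s.subject_id])
        if s.subject_id in has_measurement:
            kept.append(s)
        else:
            dropped_all_missing.append(s.subject_id)
    if dropped_all_missing:
        logger.warning(
            "dropped %d subject(s) with no non-missing Katz response: %s",
            len(dropped_all_missing),
            ", ".join(dropped_all_missing[:10]),
        )
    kept_ids = {s.subject_id for s in kept}
    responses = [r for r in responses if r.subject_id in kept_ids]

    return PanelDataset(subjects=kept, responses=responses).validate()


def write_panel(
    dataset: PanelDataset, responses_path: str | Path, subjects_path: str | Path
) -> None:
    """Write a panel in the dialect read by :func:`load_panel`."""
    responses_path = Path(responses_path)
    subjects_path = Path(subjects_path)
    resp, subj = dataset.to_frames()
    resp["category"] = resp["category"].astype("Int64")
    resp.to_csv(responses_path, sep=_sep_for(responses_path), index=False, na_rep="")
    subj.to_csv(subjects_path, sep=_sep_for(subjects_path), index=False, na_rep="")


#: Exclusion reasons in precedence order: each excluded subject is
#: counted under the first reason that applies.
EXCLUSION_REASONS = (
    "age_at_or_below_minimum",
    "unknown_death_time",
    "no_katz_measurement",
    "incomplete_covariates",
)


def apply_inclusion_filter(
    dataset: PanelDataset, min_age: float = 60.0
) -> tuple[PanelDataset, dict[str, int]]:
    """Keep analysis-eligible subjects and report exclusions by reason.

    A subject is retained when baseline age is strictly greater than
    ``min_age``, death time is known, at least one non-missing Katz
    response exists, and all covariates are complete.  The report maps
    each reason to the number of subjects excluded for it (first
    applicable reason wins).  Idempotent.
    """
    report = {reason: 0 for reason in EXCLUSION_REASONS}
    measured: set[str] = {
        r.subject_id for r in dataset.responses if r.category is not None
    }
    kept: list[Subject] = []
    for s in dataset.subjects:
        age = s.covariates.age_baseline
        if age is None or not age > min_age:
            report["age_at_or_below_minimum"] += 1
        elif s.death_time is None:
            report["unknown_death_time"] += 1
        elif s.subject_id not in measured:
            report["no_katz_measurement"] += 1
        elif not s.covariates.is_complete():
            report["incomplete_covariates"] += 1
        else:
            kept.append(s)
    kept_ids = {s.subject_id for s in kept}
    responses = [r for r in dataset.responses if r.subject_id in kept_ids]
    return PanelDataset(subjects=kept, responses=responses), report


def standardize_covariates(dataset: PanelDataset) -> PanelDataset:
    """Populate ``age_std`` / ``education_std`` (zero mean, unit sample SD).

    Uses the sample standard deviation (n − 1 denominator).  Raises
    :class:`ValidationError` if fewer than two subjects have a value or
    a continuous covariate has zero variance.
    """
    for attr, std_attr in (("age_baseline", "age_std"), ("education", "education_std")):
        values = np.array(
            [getattr(s.covariates, attr) for s in dataset.subjects if getattr(s.covariates, attr) is not None],
            dtype=float,
        )
        if values.size < 2:
            raise ValidationError(f"need >=2 subjects with {attr} to standardize")
        mean = values.mean()
        sd = values.std(ddof=1)
        if sd == 0:
            raise ValidationError(f"zero variance in {attr}: cannot standardize")
        for s in dataset.subjects:
            v = getattr(s.covariates, attr)
            setattr(s.covariates, std_attr, None if v is None else (v - mean) / sd)
    return dataset


def covariate_matrix(dataset: PanelDataset) -> np.ndarray:
    """Design matrix Z (n_subjects × 5) in :data:`COVARIATE_NAMES` order.

    Requires complete, standardized covariates.
    """
    rows = []
    for s in dataset.subjects:
        c = s.covariates
        if not c.is_complete():
            raise ValidationError(f"subject {s.subject_id!r} has incomplete covariates")
        if c.age_std is None or c.education_std is None:
            raise ValidationError(
                "covariates are not standardized; call standardize_covariates first"
            )
        rows.append([c.sex, c.age_std, c.residence, c.education_std, c.marital])
    return np.asarray(rows, dtype=float)


def baseline_table(dataset: PanelDataset) -> dict[str, float]:
    """Baseline composition: counts, percentages (1 dp) and mean (SD)."""
    n = dataset.n_subjects
    cov = [s.covariates for s in dataset.subjects]
    n_female = sum(1 for c in cov if c.sex == 1)
    n_rural = sum(1 for c in cov if c.residence == 1)
    n_no_spouse = sum(1 for c in cov if c.marital == 1)
    ages = np.array([c.age_baseline for c in cov if c.age_baseline is not None], float)
    edu = np.array([c.education for c in cov if c.education is not None], float)

    def pct(k: int) -> float:
        return round(100.0 * k / n, 1) if n else float("nan")

    return {
        "n": n,
        "n_female": n_female,
        "n_male": n - n_female,
        "pct_female": pct(n_female),
        "pct_male": pct(n - n_female),
        "n_rural": n_rural,
        "n_urban": n - n_rural,
        "pct_rural": pct(n_rural),
        "pct_urban": pct(n - n_rural),
        "n_no_spouse": n_no_spouse,
        "n_spouse": n - n_no_spouse,
        "pct_no_spouse": pct(n_no_spouse),
        "pct_spouse": pct(n - n_no_spouse),
        "age_mean": round(float(ages.mean()), 1) if ages.size else float("nan"),
        "age_sd": round(float(ages.std(ddof=1)), 1) if ages.size > 1 else float("nan"),
        "education_mean": round(float(edu.mean()), 1) if edu.size else float("nan"),
        "education_sd": round(float(edu.std(ddof=1)), 1) if edu.size > 1 else float("nan"),
    }


def write_exclusion_report(report: Mapping[str, int], path: str | Path) -> None:
    """Write the exclusion report as ``{reason: count}`` JSON."""
    Path(path).write_text(json.dumps(dict(report), indent=2) + "\n")
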