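import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adlirt.data_model import (
    KATZ_ITEMS,
    PanelDataset,
    ResponseRecord,
    Subject,
    SubjectCovariates,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_subject(
    sid: str,
    sex: int = 0,
    residence: int = 0,
    marital: int = 1,
    age: float = 90.0,
    education: float = 2.0,
    death: float = 10.0,
    visits=(0.0, 3.0),
) -> Subject:
    return Subject(
        subject_id=sid,
        covariates=SubjectCovariates(
            sex=sex,
            residence=residence,
            marital=marital,
            age_baseline=age,
            education=education,
        ),
        death_time=death,
        visits=list(visits),
    )


def make_panel(subjects, categories) -> PanelDataset:
    """Build a panel: ``categories[(sid, t)]`` is a 6-vector (or None)."""
    responses = []
    for s in subjects:
        for t in s.visits:
            cats = categories.get((s.subject_id, t))
            for j, item in enumerate(KATZ_ITEMS):
                responses.append(
                    ResponseRecord(
                        subject_id=s.subject_id,
                        visit_time=t,
                        item=item,
                        category=None if cats is None else cats[j],
                    )
                )
    return PanelDataset(subjects=list(subjects), responses=responses).validate()


@pytest.fixture
def two_subject_panel() -> PanelDataset:
    subjects = [
        make_subject("S1", age=85.0, education=0.0, death=8.0, visits=(0.0, 2.5)),
        make_subject("S2", sex=1, age=95.0, education=4.0, death=6.0, visits=(0.0, 3.0)),
    ]
    cats = {
        ("S1", 0.0): [0, 0, 0, 0, 0, 0],
        ("S1", 2.5): [1, 0, 1, 0, 0, 1],
        ("S2", 0.0): [1, 1, 0, 0, 0, 0],
        ("S2", 3.0): [2, 2, 1, 1, 1, 2],
    }
    return make_panel(subjects, cats)
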