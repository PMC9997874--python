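"""Shared fixtures: hand-buildable encounter records and small cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dizzycta.cohort import EncounterRecord, Finding, Outcome
from dizzycta.encoding import Domain, FeatureDescriptor, FeatureMatrix


def make_record(eid: str, *, timestamp: float = 0.0, age: float = 60.0,
                sex: str = "female", race: set[str] | None = None,
                pmh: set[str] | None = None,
                ros: dict[str, Finding] | None = None,
                pe: dict[str, Finding] | None = None,
                numerics: dict[str, float] | None = None,
                nihss: int | None = None, stroke_code: bool = False,
                outcome: Outcome = Outcome.NO_ACUTE) -> EncounterRecord:
    """Terse builder for hand-checkable fixtures."""
    return EncounterRecord(
        encounter_id=eid, timestamp=timestamp, age=age, sex=sex,
        race_ethnicity=frozenset(race or set()),
        pmh_codes=frozenset(pmh or set()),
        ros=dict(ros or {}), pe=dict(pe or {}),
        numerics=dict(numerics or {}), nihss=nihss,
        stroke_code=stroke_code, outcome=outcome)


def random_records(rng: np.random.Generator, n: int,
                   pmh_pool: list[str] | None = None,
                   ros_pool: list[str] | None = None,
                   pe_pool: list[str] | None = None,
                   positive_rate: float = 0.2) -> list[EncounterRecord]:
    """Unstructured random fixture cohort for oracle-equivalence tests."""
    pmh_pool = pmh_pool if pmh_pool is not None else [f"code {i}" for i in range(12)]
    ros_pool = ros_pool if ros_pool is not None else ["Dizziness", "Headache", "Nausea"]
    pe_pool = pe_pool if pe_pool is not None else ["Nystagmus", "Ataxia on exam"]
    records = []
    for i in range(n):
        pmh = {c for c in pmh_pool if rng.random() < 0.15}
        ros = {item: (Finding.POSITIVE if rng.random() < 0.5 else Finding.NEGATIVE)
               for item in ros_pool if rng.random() < 0.6}
        pe = {item: (Finding.POSITIVE if rng.random() < 0.5 else Finding.NEGATIVE)
              for item in pe_pool if rng.random() < 0.6}
        numerics = {"systolic_bp": float(rng.normal(135, 15))} if rng.random() < 0.8 else {}
        positive = rng.random() < positive_rate
        records.append(make_record(
            f"R{i:04d}", timestamp=float(i), age=float(rng.uniform(20, 95)),
            sex="male" if rng.random() < 0.4 else "female",
            race={"White or Caucasian"} if rng.random() < 0.7 else {"Asian"},
            pmh=pmh, ros=ros, pe=pe, numerics=numerics,
            nihss=int(rng.integers(0, 10)) if rng.random() < 0.5 else None,
            stroke_code=bool(rng.random() < 0.2),
            outcome=Outcome.LVO if positive else Outcome.NO_ACUTE))
    return records


def binary_matrix(cells: dict[str, list], target: list[bool],
                  domain: Domain = Domain.PMH) -> FeatureMatrix:
    """FeatureMatrix straight from per-column TRUE/FALSE/None cell lists."""
    n = len(target)
    index = pd.Index([f"M{i:03d}" for i in range(n)], name="encounter_id")
    data, schema = {}, {}
    for name, col in cells.items():
        desc = FeatureDescriptor(name, domain, name)
        data[desc.key] = pd.Series([pd.NA if v is None else v for v in col],
                                   index=index, dtype="boolean")
        schema[desc.key] = desc
    return FeatureMatrix(pd.DataFrame(data, index=index), schema,
                         pd.Series(target, index=index))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def random_cohort(rng) -> list[EncounterRecord]:
    return random_records(rng, 50)
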