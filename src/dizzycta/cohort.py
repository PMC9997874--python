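"""Synthetic ED-dizziness cohorts.

Generates encounter-level records emulating an emergency-department EHR
extract for adult patients imaged by CT angiography (CTA) for dizziness:
demographics, past-medical-history (PMH) diagnosis codes, review-of-systems
(ROS) and physical-exam (PE) findings with tri-state documentation
(pertinent positive / pertinent negative / undocumented), numeric vitals,
NIHSS, a stroke-code flag, and an acute-vascular-pathology outcome label.

The default generation parameters ship in ``data/cohort_defaults.json`` and
reproduce the published study population's statistical structure: 3.3%
outcome prevalence (66% of positives being large vessel occlusions) and
class-conditional PMH prevalences such as vertebral-artery dissection at
0.1% in negatives vs 17% in positives.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a cohort specification violates its invariants."""


class Outcome(str, Enum):
    """CTA outcome category; anything other than NO_ACUTE is a positive."""

    NO_ACUTE = "no_acute"
    LVO = "lvo"
    OTHER_ACUTE = "other_acute"

    @property
    def is_positive(self) -> bool:
        return self is not Outcome.NO_ACUTE


class Finding(str, Enum):
    """Documented ROS/PE finding state; undocumented items carry no entry."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass
class EncounterRecord:
    """One ED encounter (one CTA-imaged dizziness visit)."""

    encounter_id: str
    timestamp: float
    age: float
    sex: str
    race_ethnicity: frozenset[str]
    pmh_codes: frozenset[str]
    ros: dict[str, Finding]
    pe: dict[str, Finding]
    numerics: dict[str, float]
    nihss: int | None
    stroke_code: bool
    outcome: Outcome

    def __post_init__(self) -> None:
        if self.nihss is not None and not (0 <= int(self.nihss) <= 42):
            raise ConfigurationError(f"nihss out of [0, 42]: {self.nihss}")

    @property
    def is_positive(self) -> bool:
        return self.outcome.is_positive


@dataclass(frozen=True)
class BinaryFeatureSpec:
    """Class-conditional generator for one binary PMH/ROS/PE item.

    For PMH, ``prev_neg``/``prev_pos`` are the probabilities the diagnosis
    code is on the problem list (codes are never "documented absent").
    For ROS/PE the item is documented with probability ``documentation_rate``
    and, when documented, is a pertinent positive with the class-conditional
    prevalence (else a pertinent negative).
    """

    name: str
    domain: str  # "PMH" | "ROS" | "PE"
    prev_neg: float
    prev_pos: float
    documentation_rate: float = 1.0
    established: bool = False

    def validate(self) -> None:
        if self.domain not in ("PMH", "ROS", "PE"):
            raise ConfigurationError(f"bad domain {self.domain!r} for {self.name!r}")
        for p in (self.prev_neg, self.prev_pos, self.documentation_rate):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"probability out of [0,1] for {self.name!r}: {p}")


@dataclass(frozen=True)
class NumericFeatureSpec:
    """Gaussian numeric measurement with class-dependent location."""

    name: str
    mean_neg: float
    mean_pos: float
    sd: float
    documentation_rate: float = 1.0
    low: float = -math.inf
    high: float = math.inf
    integer: bool = False

    def validate(self) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"negative sd for {self.name!r}")
        if not (0.0 <= self.documentation_rate <= 1.0):
            raise ConfigurationError(f"documentation_rate out of [0,1] for {self.name!r}")


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic cohort.

    ``planted_mode`` controls the outcome-injection guarantee that makes
    covering-recovery experiments meaningful:

    * ``"any"`` — a positive lacking every planted risk feature gets one
      (sampled proportionally to its positive-class prevalence) with
      probability ``penetrance``;
    * ``"partition"`` — each positive is assigned exactly one planted
      feature, uniformly at random, regardless of the independent draws
      (useful when each planted feature must carry its own positives).
    """

    n_encounters: int = 1429
    positive_rate: float = 0.033
    lvo_fraction_of_positives: float = 0.66
    features: list[BinaryFeatureSpec] = field(default_factory=list)
    numerics: list[NumericFeatureSpec] = field(default_factory=list)
    n_rare_pmh: int = 60
    n_rare_ros: int = 20
    n_rare_pe: int = 20
    rare_prevalence_max: float = 0.01
    planted: list[str] = field(default_factory=list)
    penetrance: float = 1.0
    planted_mode: str = "any"
    male_rate_neg: float = 0.392
    male_rate_pos: float = 0.489
    hispanic_rate_neg: float = 0.134
    hispanic_rate_pos: float = 0.085
    race_categories: list[str] = field(
        default_factory=lambda: ["White or Caucasian", "Black or African American", "Asian", "Other"]
    )
    race_probs_neg: list[float] = field(default_factory=lambda: [0.684, 0.188, 0.022, 0.106])
    race_probs_pos: list[float] = field(default_factory=lambda: [0.681, 0.234, 0.0, 0.085])
    stroke_code_rate: float = 0.08
    nihss_documentation_rate: float = 0.3
    nihss_mean_neg: float = 1.0
    nihss_mean_pos: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_encounters <= 0:
            raise ConfigurationError("n_encounters must be positive")
        for name in ("positive_rate", "lvo_fraction_of_positives", "penetrance",
                     "rare_prevalence_max", "male_rate_neg", "male_rate_pos",
                     "hispanic_rate_neg", "hispanic_rate_pos", "stroke_code_rate",
                     "nihss_documentation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} out of [0,1]: {v}")
        for n in (self.n_rare_pmh, self.n_rare_ros, self.n_rare_pe):
            if n < 0:
                raise ConfigurationError("rare-feature counts must be non-negative")
        if self.planted_mode not in ("any", "partition"):
            raise ConfigurationError(f"unknown planted_mode {self.planted_mode!r}")
        for pr in (self.race_probs_neg, self.race_probs_pos):
            if len(pr) != len(self.race_categories) or abs(sum(pr) - 1.0) > 1e-6:
                raise ConfigurationError("race category probabilities must match categories and sum to 1")
        known = {f.name for f in self.features}
        for p in self.planted:
            if p not in known:
                raise ConfigurationError(f"planted feature {p!r} not in feature catalog")
        for f in self.features:
            f.validate()
        for f in self.numerics:
            f.validate()


def _load_defaults() -> dict:
    with resources.files("dizzycta.data").joinpath("cohort_defaults.json").open() as fh:
        return json.load(fh)


def default_spec(**overrides) -> CohortSpec:
    """Cohort spec with the packaged study-population defaults."""
    raw = _load_defaults()
    features = [BinaryFeatureSpec(**f) for f in raw["features"]]
    numerics = [NumericFeatureSpec(**f) for f in raw["numerics"]]
    planted = [f.name for f in features if f.established and f.domain == "PMH"]
    spec = CohortSpec(features=features, numerics=numerics, planted=planted)
    return replace(spec, **overrides) if overrides else spec


def spec_from_yaml(path: str | Path) -> CohortSpec:
    """Read a CohortSpec from a YAML key-value file (missing keys → defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    features = [BinaryFeatureSpec(**f) for f in raw.pop("features", [])]
    numerics = [NumericFeatureSpec(**f) for f in raw.pop("numerics", [])]
    if not features and not numerics:
        spec = default_spec()
        return replace(spec, **raw)
    return CohortSpec(features=features, numerics=numerics, **raw)


def _draw_binary(rng: np.random.Generator, positive: np.ndarray, p_neg: float, p_pos: float) -> np.ndarray:
    p = np.where(positive, p_pos, p_neg)
    return rng.random(positive.size) < p


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> list[EncounterRecord]:
    """Generate a reproducible synthetic cohort.

    Timestamps are strictly increasing (fractional hours from an arbitrary
    origin); outcomes are drawn at ``positive_rate``; every catalog feature
    is drawn independently given the outcome class; long-tail nuisance
    features exercise the documentation-frequency filter; planted risk
    features are injected into positives per ``planted_mode``/``penetrance``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_encounters

    timestamps = np.cumsum(rng.uniform(0.1, 2.0, size=n))
    positive = rng.random(n) < spec.positive_rate
    lvo = positive & (rng.random(n) < spec.lvo_fraction_of_positives)

    male = _draw_binary(rng, positive, spec.male_rate_neg, spec.male_rate_pos)
    hispanic = _draw_binary(rng, positive, spec.hispanic_rate_neg, spec.hispanic_rate_pos)
    race_idx = np.empty(n, dtype=int)
    k = len(spec.race_categories)
    neg_mask = ~positive
    race_idx[neg_mask] = rng.choice(k, size=int(neg_mask.sum()), p=spec.race_probs_neg)
    race_idx[positive] = rng.choice(k, size=int(positive.sum()), p=spec.race_probs_pos)

    # catalog + long-tail nuisance features (nuisance prevalences are part of
    # the seeded draw, equal across classes)
    catalog = list(spec.features)
    for dom, count in (("PMH", spec.n_rare_pmh), ("ROS", spec.n_rare_ros), ("PE", spec.n_rare_pe)):
        for i in range(count):
            p = float(rng.uniform(0.0005, spec.rare_prevalence_max))
            doc = 1.0 if dom == "PMH" else float(rng.uniform(0.01, 0.2))
            catalog.append(BinaryFeatureSpec(
                name=f"Rare {dom.lower()} item {i + 1:03d}", domain=dom,
                prev_neg=p, prev_pos=p, documentation_rate=doc))

    pmh_present: dict[str, np.ndarray] = {}
    ros_doc: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    pe_doc: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for f in catalog:
        if f.domain == "PMH":
            pmh_present[f.name] = _draw_binary(rng, positive, f.prev_neg, f.prev_pos)
        else:
            documented = rng.random(n) < f.documentation_rate
            pos_finding = _draw_binary(rng, positive, f.prev_neg, f.prev_pos)
            (ros_doc if f.domain == "ROS" else pe_doc)[f.name] = (documented, pos_finding)

    # outcome injection: guarantee positives a recoverable risk signal
    planted = [f for f in spec.features if f.name in set(spec.planted)]
    if planted:
        pos_indices = np.flatnonzero(positive)
        if spec.planted_mode == "partition":
            assignment = rng.integers(0, len(planted), size=pos_indices.size)
            for j, f in enumerate(planted):
                idx = pos_indices[assignment == j]
                _set_feature(f, idx, pmh_present, ros_doc, pe_doc)
        else:
            weights = np.array([max(f.prev_pos, 1e-9) for f in planted])
            weights = weights / weights.sum()
            for i in pos_indices:
                if _has_any(planted, i, pmh_present, ros_doc, pe_doc):
                    continue
                if rng.random() < spec.penetrance:
                    f = planted[int(rng.choice(len(planted), p=weights))]
                    _set_feature(f, np.array([i]), pmh_present, ros_doc, pe_doc)

    numeric_values: dict[str, np.ndarray] = {}
    numeric_doc: dict[str, np.ndarray] = {}
    for f in spec.numerics:
        mean = np.where(positive, f.mean_pos, f.mean_neg)
        vals = rng.normal(mean, f.sd)
        vals = np.clip(vals, f.low, f.high)
        if f.integer:
            vals = np.round(vals)
        numeric_values[f.name] = vals
        numeric_doc[f.name] = rng.random(n) < f.documentation_rate

    stroke_code = rng.random(n) < spec.stroke_code_rate
    nihss_documented = stroke_code | (rng.random(n) < spec.nihss_documentation_rate)
    nihss_vals = np.clip(
        rng.poisson(np.where(positive, spec.nihss_mean_pos, spec.nihss_mean_neg)), 0, 42)

    records: list[EncounterRecord] = []
    width = max(5, len(str(n)))
    for i in range(n):
        pmh = frozenset(name for name, arr in pmh_present.items() if arr[i])
        ros = {name: (Finding.POSITIVE if posf[i] else Finding.NEGATIVE)
               for name, (doc, posf) in ros_doc.items() if doc[i]}
        pe = {name: (Finding.POSITIVE if posf[i] else Finding.NEGATIVE)
              for name, (doc, posf) in pe_doc.items() if doc[i]}
        nums = {name: float(numeric_values[name][i])
                for name in numeric_values if numeric_doc[name][i]}
        outcome = Outcome.NO_ACUTE
        if positive[i]:
            outcome = Outcome.LVO if lvo[i] else Outcome.OTHER_ACUTE
        age = nums.get("age", float(numeric_values.get("age", np.full(n, 60.0))[i]))
        race = {spec.race_categories[race_idx[i]]}
        if hispanic[i]:
            race.add("Hispanic or Latino")
        records.append(EncounterRecord(
            encounter_id=f"E{i + 1:0{width}d}",
            timestamp=float(timestamps[i]),
            age=age,
            sex="male" if male[i] else "female",
            race_ethnicity=frozenset(race),
            pmh_codes=pmh,
            ros=ros,
            pe=pe,
            numerics=nums,
            nihss=int(nihss_vals[i]) if nihss_documented[i] else None,
            stroke_code=bool(stroke_code[i]),
            outcome=outcome,
        ))
    return records


def _set_feature(f: BinaryFeatureSpec, idx: np.ndarray,
                 pmh: dict, ros: dict, pe: dict) -> None:
    if f.domain == "PMH":
        pmh[f.name][idx] = True
    else:
        doc, posf = (ros if f.domain == "ROS" else pe)[f.name]
        doc[idx] = True
        posf[idx] = True


def _has_any(planted: Sequence[BinaryFeatureSpec], i: int,
             pmh: dict, ros: dict, pe: dict) -> bool:
    for f in planted:
        if f.domain == "PMH":
            if pmh[f.name][i]:
                return True
        else:
            doc, posf = (ros if f.domain == "ROS" else pe)[f.name]
            if doc[i] and posf[i]:
                return True
    return False


def temporal_split(cohort: Sequence[EncounterRecord], train_fraction: float = 0.75
                   ) -> tuple[list[EncounterRecord], list[EncounterRecord]]:
    """Split a cohort into the temporally first/last portions.

    The boundary uses the ceiling convention — the training set is the first
    ``ceil(n * train_fraction)`` encounters by timestamp — which yields the
    1072/357 split of a 1429-encounter cohort at 75%.
    """
    if not cohort:
        raise ValueError("cannot split an empty cohort")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    ordered = sorted(cohort, key=lambda r: r.timestamp)
    n_train = math.ceil(len(ordered) * train_fraction - 1e-12)
    return ordered[:n_train], ordered[n_train:]


def make_stroke_code_cohort(cohort: Iterable[EncounterRecord], nihss_max: int = 7,
                            dizziness_item: str = "Dizziness") -> list[EncounterRecord]:
    """Stroke-code sub-cohort: code activated, documented NIHSS ≤ cutoff,
    and a positive review of systems for dizziness."""
    if not (0 <= nihss_max <= 42):
        raise ValueError("nihss_max must lie in [0, 42]")
    return [r for r in cohort
            if r.stroke_code
            and r.nihss is not None and r.nihss <= nihss_max
            and r.ros.get(dizziness_item) is Finding.POSITIVE]


# ---------------------------------------------------------------------------
# CSV round trip: encounters.csv (one row per encounter) + findings.csv
# (long format; undocumented items have no row)

_ENCOUNTER_FIELDS = ["encounter_id", "timestamp", "age", "sex", "race_ethnicity",
                     "nihss", "stroke_code", "outcome"]


def write_cohort(cohort: Sequence[EncounterRecord], outdir: str | Path) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enc_path = outdir / "encounters.csv"
    fin_path = outdir / "findings.csv"
    with open(enc_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_ENCOUNTER_FIELDS)
        for r in cohort:
            w.writerow([r.encounter_id, repr(r.timestamp), repr(r.age), r.sex,
                        ";".join(sorted(r.race_ethnicity)),
                        "" if r.nihss is None else r.nihss,
                        int(r.stroke_code), r.outcome.value])
    with open(fin_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["encounter_id", "domain", "item", "value"])
        for r in cohort:
            for code in sorted(r.pmh_codes):
                w.writerow([r.encounter_id, "PMH", code, 1])
            for dom, items in (("ROS", r.ros), ("PE", r.pe)):
                for item in sorted(items):
                    w.writerow([r.encounter_id, dom, item,
                                1 if items[item] is Finding.POSITIVE else 0])
            for name in sorted(r.numerics):
                w.writerow([r.encounter_id, "NUMERIC", name, repr(r.numerics[name])])
    return enc_path, fin_path


def read_cohort(indir: str | Path) -> list[EncounterRecord]:
    indir = Path(indir)
    findings: dict[str, dict] = {}
    with open(indir / "findings.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            d = findings.setdefault(row["encounter_id"], {"pmh": set(), "ros": {}, "pe": {}, "num": {}})
            dom, item, val = row["domain"], row["item"], row["value"]
            if dom == "PMH":
                d["pmh"].add(item)
            elif dom in ("ROS", "PE"):
                d["ros" if dom == "ROS" else "pe"][item] = (
                    Finding.POSITIVE if val == "1" else Finding.NEGATIVE)
            elif dom == "NUMERIC":
                d["num"][item] = float(val)
    records = []
    with open(indir / "encounters.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            d = findings.get(row["encounter_id"], {"pmh": set(), "ros": {}, "pe": {}, "num": {}})
            records.append(EncounterRecord(
                encounter_id=row["encounter_id"],
                timestamp=float(row["timestamp"]),
                age=float(row["age"]),
                sex=row["sex"],
                race_ethnicity=frozenset(x for x in row["race_ethnicity"].split(";") if x),
                pmh_codes=frozenset(d["pmh"]),
                ros=d["ros"],
                pe=d["pe"],
                numerics=d["num"],
                nihss=None if row["nihss"] == "" else int(row["nihss"]),
                stroke_code=bool(int(row["stroke_code"])),
                outcome=Outcome(row["outcome"]),
            ))
    return records
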