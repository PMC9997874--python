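"""Representation and application of a rule-out decision rule.

A rule is an ordered set of clinical-category groups, each holding member
features. An encounter is *excluded* — no acute vascular pathology expected
on CTA — iff it has none of the rule's features. Feature matching is exact
string matching on canonicalized names (trimmed, case-folded, dashes and
whitespace normalized): the published rule identifies features by verbatim
diagnosis-code descriptions, so no ontology mapping is attempted.

The published 23-feature rule ships as packaged data
(``data/published_rule.json``) and loads via :func:`load_published_rule`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .cohort import EncounterRecord, Finding

_DASHES = re.compile(r"[‐-―−]")
_WS = re.compile(r"\s+")


def canonical_name(name: str) -> str:
    """Canonical form used for all rule-feature matching."""
    s = _DASHES.sub("-", name)
    s = _WS.sub(" ", s).strip().casefold()
    return s


@dataclass(frozen=True)
class RuleFeature:
    """One rule member. Binary members match by presence (PMH code on the
    problem list, or a pertinent-positive ROS/PE finding); numeric members
    carry a threshold and trigger when the documented value lies on the
    risk side of it."""

    name: str
    domain: str = "PMH"  # PMH | ROS | PE | NUMERIC | DEMOGRAPHIC
    threshold: float | None = None
    direction: str | None = None  # "gt" | "le" (numeric only)

    def __post_init__(self):
        if self.domain == "NUMERIC" and (self.threshold is None or self.direction not in ("gt", "le")):
            raise ValueError(f"numeric rule feature {self.name!r} needs threshold and direction")


@dataclass(frozen=True)
class RuleCategory:
    label: str
    features: tuple[RuleFeature, ...]


@dataclass
class DecisionRule:
    """Ordered clinical categories partitioning the rule's feature set."""

    categories: tuple[RuleCategory, ...]
    name: str = "decision-rule"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        feats = [f for c in self.categories for f in c.features]
        if not feats:
            raise ValueError("a decision rule must contain at least one feature")
        canon = [(canonical_name(f.name), f.domain) for f in feats]
        if len(set(canon)) != len(canon):
            raise ValueError("rule features must partition across categories (duplicate member)")

    @property
    def all_features(self) -> tuple[RuleFeature, ...]:
        return tuple(f for c in self.categories for f in c.features)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "categories": [
                {"label": c.label,
                 "features": [
                     {k: v for k, v in
                      (("name", f.name), ("domain", f.domain),
                       ("threshold", f.threshold), ("direction", f.direction))
                      if v is not None}
                     for f in c.features]}
                for c in self.categories],
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, raw: dict) -> "DecisionRule":
        cats = tuple(
            RuleCategory(c["label"], tuple(RuleFeature(**f) for f in c["features"]))
            for c in raw["categories"])
        meta = dict(raw.get("metadata", {}))
        for k in ("description", "inclusion_criteria"):
            if k in raw:
                meta[k] = raw[k]
        return cls(categories=cats, name=raw.get("name", "decision-rule"), metadata=meta)

    @classmethod
    def from_json(cls, path: str | Path) -> "DecisionRule":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_published_rule() -> DecisionRule:
    """The published 23-feature, 3-category rule-out rule."""
    with resources.files("dizzycta.data").joinpath("published_rule.json").open() as fh:
        return DecisionRule.from_dict(json.load(fh))


@dataclass(frozen=True)
class Prediction:
    excluded: bool
    triggering_features: frozenset[str]

    def __post_init__(self):
        if self.excluded != (not self.triggering_features):
            raise ValueError("excluded must hold iff no feature triggers")


def apply_rule(rule: DecisionRule, record: EncounterRecord) -> Prediction:
    """Apply a rule to one encounter.

    Triggering features are those present in the record; undocumented ROS/PE
    items and undocumented numerics never trigger, so missing documentation
    always works in favor of exclusion (a deployment caveat of the scheme).
    """
    pmh = {canonical_name(c) for c in record.pmh_codes}
    ros_pos = {canonical_name(i) for i, v in record.ros.items() if v is Finding.POSITIVE}
    pe_pos = {canonical_name(i) for i, v in record.pe.items() if v is Finding.POSITIVE}
    demo = {canonical_name(f) for f in record.race_ethnicity}
    if record.sex == "male":
        demo.add("male")

    triggered = set()
    for f in rule.all_features:
        cname = canonical_name(f.name)
        hit = False
        if f.domain == "PMH":
            hit = cname in pmh
        elif f.domain == "ROS":
            hit = cname in ros_pos
        elif f.domain == "PE":
            hit = cname in pe_pos
        elif f.domain == "DEMOGRAPHIC":
            hit = cname in demo
        elif f.domain == "NUMERIC":
            val = record.numerics.get(f.name)
            if f.name == "age":
                val = record.age
            elif f.name == "nihss":
                val = record.nihss
            if val is not None:
                hit = (val > f.threshold) if f.direction == "gt" else (val <= f.threshold)
        if hit:
            triggered.add(f.name)
    return Prediction(excluded=not triggered, triggering_features=frozenset(triggered))


@dataclass(frozen=True)
class CohortSummary:
    n: int
    n_excluded: int
    n_positive: int
    n_positive_excluded: int


def apply_rule_cohort(rule: DecisionRule, cohort: Sequence[EncounterRecord]
                      ) -> tuple[list[Prediction], CohortSummary]:
    """Apply a rule across a cohort; returns per-encounter predictions and
    the summary counts (n, excluded, positives, positives among excluded)."""
    if not cohort:
        raise ValueError("cannot apply a rule to an empty cohort")
    preds = [apply_rule(rule, r) for r in cohort]
    n_exc = sum(p.excluded for p in preds)
    n_pos = sum(r.is_positive for r in cohort)
    n_pos_exc = sum(p.excluded and r.is_positive for p, r in zip(preds, cohort))
    return preds, CohortSummary(len(cohort), n_exc, n_pos, n_pos_exc)


class RuleClassifier:
    """Estimator-style wrapper applying a fixed decision rule.

    ``predict`` returns 1 where the rule does NOT exclude the encounter
    (test positive: imaging warranted) and 0 where it excludes.
    """

    def __init__(self, rule: DecisionRule | None = None):
        self.rule = rule

    def fit(self, X: Sequence[EncounterRecord] | None = None, y=None) -> "RuleClassifier":
        if self.rule is None:
            raise ValueError("RuleClassifier requires a rule")
        self.rule_ = self.rule
        self.classes_ = [0, 1]
        return self

    def predict(self, X: Sequence[EncounterRecord]):
        import numpy as np

        rule = getattr(self, "rule_", self.rule)
        if rule is None:
            raise RuntimeError("RuleClassifier has no rule")
        return np.array([0 if apply_rule(rule, r).excluded else 1 for r in X])

    def get_params(self, deep: bool = True) -> dict:
        return {"rule": self.rule}

    def set_params(self, **params) -> "RuleClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self
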