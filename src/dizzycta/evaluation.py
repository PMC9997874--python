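"""Diagnostic performance of a rule-out instrument.

Orientation convention throughout: *test positive* means the rule does NOT
exclude the encounter (imaging warranted); *condition positive* means acute
vascular pathology was present on CTA. A rule-out instrument lives or dies
by sensitivity and NPV under this orientation — a false negative is a
missed vascular lesion.

All proportions carry 95% Wilson score intervals. The Wilson interval is
used (rather than the Wald interval) because the metrics of interest sit at
or near 0% and 100%, where the Wald interval degenerates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import EncounterRecord
from .decision_rule import DecisionRule, Prediction, apply_rule

#: exact 97.5th-percentile standard normal quantile
Z_95 = 1.959963984540054


class UndefinedProportionError(ValueError):
    """A proportion over an empty denominator was requested."""


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with its Wilson score interval."""

    x: int
    n: int
    estimate: float
    lower: float
    upper: float
    z: float = Z_95

    @property
    def defined(self) -> bool:
        return self.n > 0

    @classmethod
    def undefined(cls, x: int = 0, n: int = 0, z: float = Z_95) -> "ProportionCI":
        return cls(x=x, n=n, estimate=math.nan, lower=math.nan, upper=math.nan, z=z)

    def round2(self) -> tuple[float, float]:
        return (round(self.lower, 2), round(self.upper, 2))

    def __str__(self) -> str:
        if not self.defined:
            return "undefined"
        return f"{format_percent(self.estimate)}% (95% CI: {self.lower:.2f}–{self.upper:.2f})"


def wilson_ci(x: int, n: int, z: float = Z_95) -> ProportionCI:
    """Wilson score interval for ``x`` successes in ``n`` trials.

    center = (p̂ + z²/2n) / (1 + z²/n);
    half-width = z·sqrt(p̂(1−p̂)/n + z²/4n²) / (1 + z²/n);
    bounds clipped to [0, 1]. Closed-form consequences asserted in tests:
    x = n ⇒ lower = n/(n+z²) and x = 0 ⇒ upper = z²/(n+z²).
    """
    if n < 1:
        raise UndefinedProportionError("wilson_ci requires n >= 1")
    if not (0 <= x <= n):
        raise ValueError(f"x must lie in [0, n]; got x={x}, n={n}")
    return wilson_ci_from_estimate(x / n, n, z=z, x=x)


def wilson_ci_from_estimate(p: float, n: int, z: float = Z_95,
                            x: int | None = None) -> ProportionCI:
    """Wilson interval computed from a (possibly pre-rounded) proportion.

    Primarily used to document reproduction of published intervals that
    were evidently computed from rounded point estimates; the exact-count
    entry point is :func:`wilson_ci`.
    """
    if n < 1:
        raise UndefinedProportionError("wilson interval requires n >= 1")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"proportion out of [0, 1]: {p}")
    z2 = z * z
    denom = 1.0 + z2 / n
    center = (p + z2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z2 / (4 * n * n)) / denom
    # clamp to [0, 1] and to the estimate itself (guards the lower <= p <=
    # upper ordering against floating-point residue at p = 0 or 1)
    lower = min(max(0.0, center - half), p)
    upper = max(min(1.0, center + half), p)
    return ProportionCI(x=int(round(p * n)) if x is None else x, n=n,
                        estimate=p, lower=lower, upper=upper, z=z)


def format_percent(p: float) -> int:
    """Integer percent, rounding half away from zero (so 8.5% → 9%)."""
    if math.isnan(p):
        raise ValueError("cannot render an undefined proportion")
    return int(Decimal(repr(p * 100)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """2×2 counts under the rule-out orientation (test positive = not
    excluded; condition positive = acute vascular pathology)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_excluded(self) -> int:
        return self.tn + self.fn


def confusion(predictions: Sequence[Prediction] | Sequence[bool],
              labels: Sequence[bool],
              ids: Sequence[str] | None = None,
              label_ids: Sequence[str] | None = None) -> ConfusionTable:
    """Tabulate predictions against outcome labels.

    ``predictions`` may be :class:`Prediction` objects or plain booleans
    meaning *excluded*. Optional id sequences are checked for alignment.
    """
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    if ids is not None and label_ids is not None and list(ids) != list(label_ids):
        raise ValueError("prediction and label ids are misaligned")
    tp = fp = tn = fn = 0
    for pred, pos in zip(predictions, labels):
        excluded = pred.excluded if isinstance(pred, Prediction) else bool(pred)
        if excluded:
            if pos:
                fn += 1
            else:
                tn += 1
        else:
            if pos:
                tp += 1
            else:
                fp += 1
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class DiagnosticReport:
    """Confusion counts plus the five headline proportions with Wilson CIs.

    ``predicted_negative`` is the proportion of encounters the rule
    excludes — the potentially avoidable CTA fraction.
    """

    confusion: ConfusionTable
    sensitivity: ProportionCI
    specificity: ProportionCI
    ppv: ProportionCI
    npv: ProportionCI
    predicted_negative: ProportionCI

    def to_dict(self) -> dict:
        def ci(p: ProportionCI) -> dict:
            if not p.defined:
                return {"x": p.x, "n": p.n, "defined": False}
            return {"x": p.x, "n": p.n, "estimate": p.estimate,
                    "lower": p.lower, "upper": p.upper, "defined": True}

        c = self.confusion
        return {"confusion": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
                "sensitivity": ci(self.sensitivity),
                "specificity": ci(self.specificity),
                "ppv": ci(self.ppv), "npv": ci(self.npv),
                "predicted_negative": ci(self.predicted_negative)}


def _safe_ci(x: int, n: int, z: float) -> ProportionCI:
    if n == 0:
        return ProportionCI.undefined(x=x, n=0, z=z)
    return wilson_ci(x, n, z=z)


def diagnostic_report(table: ConfusionTable, z: float = Z_95) -> DiagnosticReport:
    """All five metrics from a confusion table; a metric whose margin is
    empty (e.g. sensitivity with zero condition positives) is marked
    undefined while the others are still computed."""
    if table.n == 0:
        raise UndefinedProportionError("empty confusion table")
    return DiagnosticReport(
        confusion=table,
        sensitivity=_safe_ci(table.tp, table.tp + table.fn, z),
        specificity=_safe_ci(table.tn, table.tn + table.fp, z),
        ppv=_safe_ci(table.tp, table.tp + table.fp, z),
        npv=_safe_ci(table.tn, table.tn + table.fn, z),
        predicted_negative=_safe_ci(table.n_excluded, table.n, z),
    )


def report_from_counts(n: int, n_excluded: int, tp: int, fn: int, z: float = Z_95
                       ) -> DiagnosticReport:
    """Convenience: build the report from cohort-level counts (total,
    excluded, and the positives split by exclusion status)."""
    tn = n_excluded - fn
    fp = n - n_excluded - tp
    return diagnostic_report(ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn), z=z)


# ---------------------------------------------------------------------------
# NIHSS comparator sweep

_CONVENTIONS = ("exclude_if_le", "exclude_if_eq0_only", "exclude_if_gt")


def nihss_sweep(cohort: Sequence[EncounterRecord],
                cutoffs: Iterable[int] = range(0, 9),
                convention: str = "exclude_if_le") -> dict[int, DiagnosticReport]:
    """Diagnostic reports for NIHSS cut-offs as a comparator rule.

    Encounters without a documented NIHSS are dropped (the comparator can
    only be evaluated on the documentation subset). ``convention`` states
    explicitly which side of the cut-off is treated as excluded:

    * ``exclude_if_le`` — excluded iff NIHSS ≤ cutoff;
    * ``exclude_if_eq0_only`` — excluded iff NIHSS = 0 (cutoff ignored);
    * ``exclude_if_gt`` — excluded iff NIHSS > cutoff.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    documented = [r for r in cohort if r.nihss is not None]
    if not documented:
        raise ValueError("no encounter has a documented NIHSS")
    labels = [r.is_positive for r in documented]
    out: dict[int, DiagnosticReport] = {}
    for c in cutoffs:
        if convention == "exclude_if_le":
            excl = [r.nihss <= c for r in documented]
        elif convention == "exclude_if_eq0_only":
            excl = [r.nihss == 0 for r in documented]
        else:
            excl = [r.nihss > c for r in documented]
        out[int(c)] = diagnostic_report(confusion(excl, labels))
    return out


def evaluate_rule(rule: DecisionRule, cohort: Sequence[EncounterRecord],
                  z: float = Z_95) -> DiagnosticReport:
    """Apply a rule to a cohort and report its diagnostic performance."""
    preds = [apply_rule(rule, r) for r in cohort]
    labels = [r.is_positive for r in cohort]
    return diagnostic_report(confusion(preds, labels), z=z)


def sweep_table(reports: Mapping[int, DiagnosticReport],
                rule_report: DiagnosticReport | None = None) -> str:
    """Plain-text table (metric × cutoff, plus an optional rule row)."""

    def fmt(p: ProportionCI) -> str:
        if not p.defined:
            return "undefined"
        return f"{p.estimate:.2f} ({p.lower:.2f}–{p.upper:.2f})"

    header = f"{'Test':<22}{'Sensitivity':<20}{'Specificity':<20}{'PPV':<20}{'NPV':<20}{'PN':<20}"
    lines = [header, "-" * len(header)]
    for cutoff in sorted(reports, reverse=True):
        r = reports[cutoff]
        lines.append(f"{'NIHSS <= ' + str(cutoff):<22}{fmt(r.sensitivity):<20}"
                     f"{fmt(r.specificity):<20}{fmt(r.ppv):<20}{fmt(r.npv):<20}"
                     f"{fmt(r.predicted_negative):<20}")
    if rule_report is not None:
        r = rule_report
        lines.append(f"{'Decision rule':<22}{fmt(r.sensitivity):<20}"
                     f"{fmt(r.specificity):<20}{fmt(r.ppv):<20}{fmt(r.npv):<20}"
                     f"{fmt(r.predicted_negative):<20}")
    return "\n".join(lines)
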