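"""End-to-end orchestration: simulate → encode → select → derive → apply →
evaluate, with a single configuration, deterministic seeding, and a run
manifest.

Two entry points matter:

* :func:`run_derivation` executes the full three-cohort workflow on a
  synthetic cohort (temporal 75/25 split for derivation/validation plus the
  stroke-code sensitivity-analysis sub-cohort) and writes every artifact.
* :func:`run_published_check` recomputes every published performance metric
  from the published confusion counts (packaged as data, not simulated) and
  compares against the published renderings — the reproduction harness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .cohort import (CohortSpec, default_spec, generate_cohort,
                     make_stroke_code_cohort, spec_from_yaml, temporal_split,
                     write_cohort)
from .decision_rule import DecisionRule, apply_rule_cohort
from .encoding import encode
from .evaluation import (DiagnosticReport, evaluate_rule, format_percent,
                         nihss_sweep, report_from_counts, sweep_table,
                         wilson_ci, wilson_ci_from_estimate)
from .feature_selection import (FrequencyCaps, frequency_filter, scores_to_frame,
                                select_top_k)
from .rule_induction import SequentialCoveringClassifier

logger = logging.getLogger("dizzycta")


def load_established_risk_factors() -> list[str]:
    """Packaged default list of established vascular risk factors (editable
    by pointing RunConfig.established_path at a replacement JSON)."""
    with resources.files("dizzycta.data").joinpath("established_risk_factors.json").open() as fh:
        return json.load(fh)["established_risk_factors"]


def load_published_counts() -> dict:
    with resources.files("dizzycta.data").joinpath("published_counts.json").open() as fh:
        return json.load(fh)


@dataclass
class RunConfig:
    """Configuration for a full derivation run."""

    cohort_spec_path: str | None = None
    train_fraction: float = 0.75
    pmh_cap: int = 200
    ros_cap: int = 100
    pe_cap: int = 100
    chi2_top_k: int = 100
    n_trees: int = 100
    gini_rank_max: int = 5
    seed: int = 0
    established_path: str | None = None
    grouping_map_path: str | None = None
    nihss_max: int = 7
    nihss_convention: str = "exclude_if_le"
    output_dir: str = "dizzycta_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def cohort_spec(self) -> CohortSpec:
        if self.cohort_spec_path:
            return spec_from_yaml(self.cohort_spec_path)
        return default_spec(seed=self.seed)

    def established(self) -> list[str]:
        if self.established_path:
            with open(self.established_path) as fh:
                return json.load(fh)["established_risk_factors"]
        return load_established_risk_factors()

    def grouping_map(self) -> dict | None:
        if self.grouping_map_path:
            with open(self.grouping_map_path) as fh:
                return json.load(fh)
        return None


def _report_json(report: DiagnosticReport) -> dict:
    return report.to_dict()


def run_derivation(config: RunConfig) -> dict[str, Any]:
    """Execute the full derivation chain and write all artifacts.

    Returns a dict with the derived rule, the three diagnostic reports, the
    derivation state, and the output manifest. Fully deterministic under a
    fixed config (asserted in tests via byte-identical rule JSON).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.cohort_spec()

    logger.info("stage=simulate n=%d seed=%d", spec.n_encounters, config.seed)
    cohort = generate_cohort(spec, seed=config.seed)
    write_cohort(cohort, outdir / "cohort")

    train, valid = temporal_split(cohort, config.train_fraction)
    stroke = make_stroke_code_cohort(cohort, nihss_max=config.nihss_max)

    logger.info("stage=encode train=%d valid=%d stroke_code=%d",
                len(train), len(valid), len(stroke))
    matrix = encode(train)

    logger.info("stage=select columns=%d", len(matrix.columns))
    caps = FrequencyCaps(config.pmh_cap, config.ros_cap, config.pe_cap)
    reduced = frequency_filter(matrix, caps)
    selected_matrix, scores = select_top_k(reduced, config.chi2_top_k)
    scores_to_frame(scores).to_csv(outdir / "feature_scores.csv", index=False)

    logger.info("stage=derive features=%d", len(selected_matrix.columns))
    inducer = SequentialCoveringClassifier(
        established=config.established(), n_trees=config.n_trees,
        gini_rank_max=config.gini_rank_max, random_state=config.seed,
        grouping_map=config.grouping_map())
    chi2_ranks = {s.feature.key: s.chi2_rank for s in scores}
    inducer.fit(selected_matrix, chi2_ranks=chi2_ranks)
    rule = inducer.rule_
    rule.metadata.setdefault("provenance", {})["package_version"] = __version__
    rule_path = outdir / "derived_rule.json"
    rule.to_json(rule_path)

    logger.info("stage=apply+evaluate")
    reports = {
        "derivation": evaluate_rule(rule, train),
        "validation": evaluate_rule(rule, valid),
    }
    if stroke:
        reports["stroke_code"] = evaluate_rule(rule, stroke)
    sweep = None
    if any(r.nihss is not None for r in valid):
        sweep = nihss_sweep(valid, convention=config.nihss_convention)

    results = {
        "seed": config.seed,
        "config": asdict(config),
        "rule_features": [f.name for f in rule.all_features],
        "iteration_log": inducer.state_.log,
        "reports": {k: _report_json(v) for k, v in reports.items()},
        "nihss_sweep": {str(c): _report_json(r) for c, r in (sweep or {}).items()},
    }
    with open(outdir / "reports.json", "w") as fh:
        json.dump(results, fh, indent=1)

    manifest = sorted(str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
                      if p.name != "manifest.json")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"outputs": manifest, "seed": config.seed}, fh, indent=1)

    return {"rule": rule, "state": inducer.state_, "reports": reports,
            "nihss_sweep": sweep, "manifest": manifest, "outdir": outdir,
            "cohorts": {"train": train, "validation": valid, "stroke_code": stroke}}


# ---------------------------------------------------------------------------
# Published-metric reproduction


@dataclass
class MetricCheck:
    cohort: str
    metric: str
    published_pct: int | None
    computed_pct: int | None
    published_ci: tuple[float, float] | None
    computed_ci: tuple[float, float] | None
    matches: bool
    anomalous: bool = False
    note: str = ""


@dataclass
class PublishedCheckReport:
    checks: list[MetricCheck] = field(default_factory=list)

    @property
    def mismatches(self) -> list[MetricCheck]:
        return [c for c in self.checks if not c.matches and not c.anomalous]

    @property
    def anomalies(self) -> list[MetricCheck]:
        return [c for c in self.checks if c.anomalous]

    @property
    def ok(self) -> bool:
        return not self.mismatches


def run_published_check() -> PublishedCheckReport:
    """Recompute every published metric from the published confusion counts.

    Non-anomalous entries must reproduce exactly at the published rounding
    (integer percent, 2-decimal interval bounds). Entries flagged anomalous
    in the packaged counts are published values that only reproduce via
    Wilson applied to the rounded point estimate (or whose published point
    estimate is itself misrounded); for those the check records both
    computations instead of failing.
    """
    counts = load_published_counts()
    out = PublishedCheckReport()
    for cohort_name, entry in counts.items():
        report = report_from_counts(entry["n"], entry["n_excluded"],
                                    tp=entry["tp"], fn=entry["fn"])
        for metric, expected in entry["published"].items():
            ci_obj = getattr(report, metric)
            comp_pct = format_percent(ci_obj.estimate) if ci_obj.defined else None
            comp_ci = ci_obj.round2() if ci_obj.defined else None
            pub_pct = expected.get("pct")
            pub_ci = tuple(expected["ci"]) if "ci" in expected else None
            matches = (pub_pct is None or pub_pct == comp_pct) and \
                      (pub_ci is None or pub_ci == comp_ci)
            anomalous = bool(expected.get("anomalous"))
            if anomalous and not matches:
                # document the computational path that produced the published
                # rendering: Wilson applied to the rounded estimate
                alt = wilson_ci_from_estimate(pub_pct / 100, ci_obj.n)
                matches = pub_ci is None or alt.round2() == pub_ci
            out.checks.append(MetricCheck(
                cohort=cohort_name, metric=metric,
                published_pct=pub_pct, computed_pct=comp_pct,
                published_ci=pub_ci, computed_ci=comp_ci,
                matches=matches, anomalous=anomalous,
                note=expected.get("note", "")))
    return out
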