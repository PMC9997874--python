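# Methods

This note records the scientific model behind the package, the parameter
choices that matter, what the synthetic data do and do not emulate, and the
numerical conventions. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The problem and the estimand

The package targets a *rule-out* instrument: a set of clinical features
such that an adult ED dizziness encounter carrying **none** of them has
near-zero probability of acute vascular pathology (LVO, other occlusion,
dissection, hemorrhagic vascular lesion) on CTA head and neck. The
operative metrics are sensitivity and NPV under the orientation
*test-positive = rule does not exclude*; specificity and the
predicted-negative proportion measure how many CTAs the rule could avoid.
"Positive" everywhere means any acute vascular pathology (LVO is tracked
as a subset but not treated separately by the rule).

## Synthetic cohort generator

The generator emulates an EHR extract at the level of its *statistical
structure*, not its clinical causality:

- **Scale and prevalence.** Defaults: 1429 encounters, outcome prevalence
  3.3% (~47 positives), 66% of positives LVO, 75/25 temporal split by
  strictly increasing timestamps giving 1072/357. The split boundary uses
  the ceiling convention `⌈n·f⌉`, which is the only reading that produces
  1072 from 1429 at 75%.
- **Class-conditional features.** Each catalog feature is drawn
  independently given the outcome class from the published
  class-conditional prevalences of the study population's characteristics
  table (e.g. vertebral-artery dissection 1/1382 vs 8/47; long-term
  anticoagulant use 81/1382 vs 9/47). Conditional independence given class
  is an explicit simplification — real comorbidities co-occur.
- **ROS/PE documentation.** Marginal documentation rates of ROS/PE items
  are **not published**; the packaged defaults (0.5–0.95 per item, with
  conditional pertinent-positive probabilities mildly enriched in
  positives) are assumptions, configurable per item. An item is documented
  with its documentation rate and, when documented, is a pertinent
  positive with the class-conditional prevalence.
- **Long-tail nuisance features.** 60 PMH / 20 ROS / 20 PE rare items at
  prevalence ≤ 1% (equal across classes) exercise the
  documentation-frequency filter the way a 1500-code problem-list
  vocabulary would.
- **NIHSS.** Documented for all stroke-code encounters and a configurable
  30% of the rest (real documentation was incomplete); values are Poisson
  with class-dependent mean (1 in negatives, 3 in positives), truncated to
  [0, 42]. The distribution is not asserted against any published table —
  it exists to exercise the comparator sweep.
- **Outcome injection.** Positives are guaranteed a recoverable signal:
  any positive lacking all planted risk features receives one (sampled by
  positive-class prevalence) with penetrance 1 by default. In `partition`
  mode each positive is assigned exactly one planted feature, which is the
  regime in which covering-recovery experiments are meaningful. Without
  this guarantee a positive with an empty feature vector is uncoverable
  and the covering loop stalls — as it would on real data if a case had no
  documented history at all.

What passing tests on these cohorts show: the *procedure* terminates,
recovers planted signal, and reproduces the published evaluation
arithmetic. What they cannot show: that the procedure recovers the
published 23-feature list, which depends on the real, undeposited EHR
data.

## Encoding

PMH absence is FALSE (codes only appear when assigned); ROS/PE absence is
MISSING in both the pertinent-positive and pertinent-negative column of an
item. This asymmetry is the central encoding decision. For consumers that
cannot handle missingness (χ², CART, forest) one imputation convention is
applied at a single boundary (`FeatureMatrix.imputed`): binary MISSING →
FALSE, numeric MISSING → column median. Documentation counting emits both
plausible conventions (documented rows vs positive rows) because it is not
knowable which one a given "most commonly documented" ranking used.

## Feature selection

Frequency caps (200 PMH / 100 ROS / 100 PE source items, all numerics and
demographics kept; lexicographic tie-break) followed by a single merged χ²
ranking to the top 100. The χ² test uses no continuity correction and no
multiplicity adjustment — it is a ranking device, not an inference.
Numeric features are quartile-binned for the test (quartiles are
conventional and deterministic; the binning scheme is shared with the
monotonicity gate).

## Rule induction

- **CART**: Gini splits, no depth cap, minimum split size 2 — leaves are
  pure or unsplittable. Determinism comes from a fixed `random_state`;
  equal-impurity ties resolve by the library's seeded ordering rather than
  a documented column-order rule, so structural tests compare achieved
  impurity decrease against an exhaustive-search oracle instead of split
  identity.
- **Forest**: 100 trees, bootstrap resampling, `max_features=None` (every
  tree sees every feature at every split — ensemble variation comes from
  bagging only). Importance is mean impurity decrease, normalized per tree
  to sum to 1 (the library convention); rank ties break by (χ² rank, name).
- **Phase 1** adds established risk factors with Gini rank ≤ 5,
  re-evaluated after every refit. A rank-≤5 established feature that would
  cover no new positive is skipped with a log entry (adding it would
  violate the strict-decrease invariant that guarantees termination).
- **Phase 2** adds the highest-importance admissible feature on the path
  to the largest all-negative leaf (ties toward the leftmost leaf). A
  binary feature is admissible only when the negative leaf lies on its
  absence branch — the rule's semantics are "no history of X", so presence
  must predict risk. Pertinent-negative columns are never admissible rule
  members. A continuous feature is admissible only if its quartile-binned
  positive rate is monotone, and enters with the threshold of its path
  split.
- **Refit scope.** "Cases not excluded by the evolving decision rule" is
  read as: refit on cases possessing *none* of the selected features (the
  candidate rule-out stratum), since the loop's goal is driving that
  stratum's positive count to zero. The complementary reading is available
  as `refit_scope="flagged"` for comparison but cannot terminate in the
  stated sense.
- **Fallback.** When neither phase yields a covering candidate — which
  legitimately happens when the negative-leaf path consists solely of
  continuous splits (e.g. age) — the loop falls back to the
  highest-importance admissible binary feature that covers a new positive,
  logged per iteration as a fallback step. `allow_fallback=False` restores
  a strict stall error instead.
- Termination: every accepted feature covers ≥ 1 previously uncovered
  positive, so the loop runs at most (number of positives) iterations and
  ends with zero uncovered positives — training sensitivity is exactly
  100% by construction, asserted on every run.

## Evaluation

Wilson score intervals use the exact 97.5% normal quantile (1.959963985…);
at 2-decimal rounding the results are indistinguishable from z = 1.96 for
all count pairs exercised here. Percent renderings round half away from
zero. Degenerate margins (e.g. sensitivity with zero positives) are marked
undefined rather than raising, so the rest of a report stays usable.

Three published renderings are reproduction anomalies, verified by
computation (`run_published_check` flags them; tests document them):

1. derivation specificity: 603/1031 = 58.5% renders 58%, published 59%;
2. the derivation specificity interval (0.56–0.62) matches Wilson applied
   to p = 0.59 (the misrounded estimate), not to the raw counts (0.55–0.61);
3. the validation specificity interval lower bound 0.48 matches Wilson
   applied to p = 0.53, not the raw counts (0.47); the validation PPV
   point estimate 4% vs 6/172 = 3.5% → 3% is the same class of artifact.

These are recorded as source-side rounding artifacts; the package computes
intervals from raw counts and exposes `wilson_ci_from_estimate` to
demonstrate the provenance of the published values.

The NIHSS comparator sweep requires an explicit exclusion convention
(`exclude_if_le`, `exclude_if_eq0_only`, `exclude_if_gt`) because the
published comparator table is not consistent with a single convention, and
drops encounters without a documented NIHSS (the published documentation
denominators are unavailable and are not reverse-engineered).

## Problem sizes

Property-based checks run at the scales the derivation is claimed for:
covering termination on ten study-scale cohorts (training n = 1072),
planted-feature recovery on ten cohorts of n = 5000, oracle equivalences on
instances of n ≤ 500. These sizes make the full suite complete in a few
minutes on one core while keeping the binomial bands of the prevalence
checks narrow enough to be informative.

## Known limitations

- Feature independence given class; no ICD hierarchy, no visit structure,
  no free text. Name matching of rule features is canonicalized exact
  string matching — deploying against a real EHR would require code-level
  mapping.
- The "unexplained" qualifier of the published rule's speech/ataxia/visual
  items is not computable from structured data; the packaged rule applies
  the explicit member features only.
- Undocumented items never trigger rule features, so missing documentation
  always favors exclusion; this mirrors the encoding's semantics and is a
  real deployment caveat of any documentation-based rule.
- Synthetic validation-phase sensitivity is not guaranteed (and is an
  honest measure of covering overfit under independence); only the
  training-phase guarantee is structural.
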