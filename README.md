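# dizzycta

Derivation and evaluation of a **rule-out clinical decision rule** for CT
angiography (CTA) of the head and neck in emergency-department patients
presenting with dizziness.

Dizziness is a common, non-specific ED complaint. A small fraction of these
patients (~3%) harbor acute vascular pathology — large vessel occlusion
(LVO), dissection, smaller occlusions, or hemorrhagic vascular lesions —
detectable on CTA, but the large majority of CTAs are negative. A decision
rule that identifies encounters with *near-zero* risk could defer imaging
in favor of more sensitive modalities (MRI, HINTS exam). This package
implements, end to end and on synthetic EHR-style cohorts, the pipeline
that derives and evaluates such a rule:

1. **Synthetic cohort generation** — encounter records (demographics, PMH
   diagnosis codes, ROS/PE findings with pertinent-positive /
   pertinent-negative / undocumented tri-state documentation, vitals,
   NIHSS, stroke-code flag, CTA outcome label) with the published study
   population's statistical structure: 1429 encounters, 3.3% outcome
   prevalence, 66% of positives LVO, and class-conditional PMH prevalences
   such as vertebral-artery dissection at 0.1% in negatives vs 17% in
   positives.
2. **Null-aware encoding** — one-hot PMH (absence of a code is informative
   absence, FALSE), dual binary columns per ROS/PE item (both missing when
   undocumented), continuous numerics.
3. **Candidate filtering** — documentation-frequency caps (top 200 PMH /
   100 ROS / 100 PE items), then χ² ranking to the top 100 features.
4. **Sequential-covering rule induction** — fully grown CART trees and a
   100-tree bagged forest (all features available at every split) rank
   features by Gini importance; established vascular risk factors with Gini
   rank ≤ 5 are added first, then the highest-importance features on the
   decision path to the largest all-negative leaf; continuous candidates
   must pass a monotonicity gate; after each addition the models are refit
   on the cases not yet covered, until **no positive case remains
   uncovered** (training sensitivity 100% by construction).
5. **Evaluation** — sensitivity, specificity, PPV, NPV and the
   predicted-negative (potentially avoidable CTA) proportion, each with a
   95% **Wilson score interval**, on the temporally held-out validation
   cohort and a stroke-code (NIHSS ≤ 7, dizziness-positive) sub-cohort,
   against NIHSS cut-off comparators.

The published 23-feature rule (no PMH of cerebrovascular event; no PMH of
specific vascular risk factors; no long-term anticoagulant/antiplatelet
use) ships as packaged data and can be applied to any cohort. For a
proportion `x/n`, the Wilson interval used throughout is

    center = (p̂ + z²/2n) / (1 + z²/n),
    half-width = z·√(p̂(1−p̂)/n + z²/4n²) / (1 + z²/n),  z = 1.95996…

## Worked example

A full synthetic derivation at study scale (single command, ~5 s):

```text
$ dizzycta derive --seed 7 --out demo_run
derived rule with 13 features in 13 categories -> demo_run
  derivation: sensitivity 100% (95% CI: 0.90–1.00), predicted negative 41% (95% CI: 0.38–0.44)
  validation: sensitivity 83% (95% CI: 0.55–0.95), predicted negative 43% (95% CI: 0.38–0.48)
  stroke_code: sensitivity 100% (95% CI: 0.57–1.00), predicted negative 34% (95% CI: 0.26–0.43)
```

The derivation-phase sensitivity is 100% *by construction* — the covering
loop only terminates when every positive training case carries at least one
rule feature. Validation sensitivity on synthetic data need not be 100%:
synthetic features are drawn independently given class, so features that
covered rare training positives (including some noise features, exactly as
overfitting would in real data) may miss validation positives. The
predicted-negative proportion (~40–55%) is the fraction of CTAs the rule
would have avoided. Artifacts written: the cohort CSVs, `feature_scores.csv`
(χ² ranking), `derived_rule.json` (with per-iteration provenance log), and
`reports.json`.

Applying the *published* rule and reproducing its published metrics from
the published confusion counts:

```text
$ dizzycta check-published
derivation   sensitivity          published=100% (0.91, 1.0) computed=100% (0.91, 1.0) [ok]
derivation   specificity          published=59% (0.56, 0.62) computed=58% (0.55, 0.61) [ANOMALY]
...
all non-anomalous published metrics reproduced
```

The three `ANOMALY` rows are documented source-side rounding artifacts
(intervals computed from rounded point estimates, and one misrounded point
estimate); see `docs/methods.md`.

## Layout

- `src/dizzycta/cohort.py` — synthetic cohort generator, temporal split, stroke-code sub-cohort, CSV I/O
- `src/dizzycta/encoding.py` — null-aware feature matrix (`EncounterEncoder`)
- `src/dizzycta/feature_selection.py` — frequency caps and χ² ranking (`FrequencyFilter`, `Chi2TopK`)
- `src/dizzycta/rule_induction.py` — CART/forest machinery and the covering loop (`SequentialCoveringClassifier`)
- `src/dizzycta/decision_rule.py` — rule representation/application (`RuleClassifier`, packaged published rule)
- `src/dizzycta/evaluation.py` — Wilson intervals, confusion tables, diagnostic reports, NIHSS sweep
- `src/dizzycta/pipeline.py`, `cli.py` — orchestration and the `dizzycta` command
- `docs/methods.md` — model assumptions, parameter choices, limitations
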