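"""Sequential-covering derivation of a rule-out decision rule.

The derivation loop mirrors the published procedure:

1. On the currently uncovered cases (those possessing none of the selected
   features), fit a fully grown CART tree and a 100-tree random forest in
   which every tree sees every candidate feature at every split (bagging
   only, no per-split feature subsampling), yielding a Gini
   (impurity-decrease) importance ranking.
2. Phase 1: if any *established* vascular risk factor ranks in the Gini
   top 5 and would cover at least one uncovered positive, add the
   best-ranked such feature to the rule.
3. Phase 2: otherwise add the highest-Gini admissible feature lying on the
   decision path to the largest all-negative leaf of the CART tree.
   Continuous features must pass a quartile-bin monotonicity gate and
   enter with the threshold of their path split; binary features are
   admissible only in the presence direction (the final rule is phrased as
   "no history of …", so a feature whose *absence* predicts risk cannot be
   a member).
4. Remove the newly covered cases and repeat until no positive case remains
   uncovered — at which point the rule's training sensitivity is 100% by
   construction.

Every added feature must cover at least one previously uncovered positive;
the uncovered-positive count therefore strictly decreases and the loop
terminates in at most (number of positives) iterations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .decision_rule import DecisionRule, RuleCategory, RuleFeature, canonical_name
from .encoding import Domain, FeatureDescriptor, FeatureMatrix
from .feature_selection import quartile_bins


class StallError(RuntimeError):
    """Covering cannot proceed: no admissible candidate covers a new positive."""

    def __init__(self, message: str, log: list | None = None):
        super().__init__(message)
        self.log = log or []


class NoNegativeLeafError(RuntimeError):
    """The CART tree has no leaf free of positive cases."""


# admissible binary rule-member domains (presence-type)
_PRESENCE_DOMAINS = {Domain.PMH, Domain.ROS_POS, Domain.PE_POS, Domain.DEMOGRAPHIC}
_RULE_DOMAIN = {Domain.PMH: "PMH", Domain.ROS_POS: "ROS", Domain.PE_POS: "PE",
                Domain.DEMOGRAPHIC: "DEMOGRAPHIC", Domain.NUMERIC: "NUMERIC"}


# ---------------------------------------------------------------------------
# CART


@dataclass
class LeafInfo:
    node_id: int
    n_cases: int
    n_positive: int


@dataclass
class PathStep:
    key: str
    goes_right: bool  # branch taken toward the leaf: right = "value > threshold"
    threshold: float


class TreeModel:
    """A fully grown CART tree over an (imputed) feature matrix subset.

    Grown with Gini splits, no depth cap and minimum split size 2, so every
    leaf is pure or unsplittable; leaf case counts always sum to the
    training-subset size.
    """

    def __init__(self, clf: DecisionTreeClassifier, keys: list[str],
                 X: np.ndarray, y: np.ndarray):
        self.clf = clf
        self.keys = keys
        self._X = X
        self._leaf_assign = clf.apply(X)
        self._y = y

    def leaves(self) -> list[LeafInfo]:
        tree = self.clf.tree_
        out = []
        for node in range(tree.node_count):
            if tree.children_left[node] == -1:
                mask = self._leaf_assign == node
                out.append(LeafInfo(node, int(mask.sum()), int(self._y[mask].sum())))
        return out

    def training_error(self) -> int:
        """Misclassified training cases (0 unless duplicate feature vectors
        carry conflicting labels, which make pure leaves unattainable)."""
        return int((self.clf.predict(self._X) != self._y).sum())

    def path_to(self, leaf_id: int) -> list[PathStep]:
        tree = self.clf.tree_
        # parent map via one pass
        parent = {}
        for node in range(tree.node_count):
            for child, right in ((tree.children_left[node], False),
                                 (tree.children_right[node], True)):
                if child != -1:
                    parent[child] = (node, right)
        steps: list[PathStep] = []
        node = leaf_id
        while node in parent:
            up, went_right = parent[node]
            steps.append(PathStep(self.keys[tree.feature[up]], went_right,
                                  float(tree.threshold[up])))
            node = up
        steps.reverse()
        return steps


def fit_cart(matrix: FeatureMatrix, seed: int = 0) -> TreeModel:
    """Fit a fully grown CART tree on a (possibly single-class) subset."""
    X, keys = matrix.imputed()
    y = matrix.target.to_numpy(dtype=bool)
    clf = DecisionTreeClassifier(criterion="gini", max_depth=None,
                                 min_samples_split=2, random_state=seed)
    clf.fit(X, y)
    return TreeModel(clf, keys, X, y)


def largest_negative_leaf_path(tree: TreeModel) -> list[PathStep]:
    """Root-to-leaf path of the largest leaf containing zero positives
    (ties broken toward the leftmost = smallest node id)."""
    neg = [l for l in tree.leaves() if l.n_positive == 0 and l.n_cases > 0]
    if not neg:
        raise NoNegativeLeafError("tree has no all-negative leaf")
    best = min(neg, key=lambda l: (-l.n_cases, l.node_id))
    return tree.path_to(best.node_id)


# ---------------------------------------------------------------------------
# Forest importance


@dataclass
class ForestImportance:
    """Mean Gini importance over a bagged forest of fully grown trees.

    Importances follow sklearn's convention: per-tree impurity decreases are
    normalized to sum to 1 and averaged over trees. Ranks are 1-based,
    tie-broken by (chi-squared rank asc, name asc).
    """

    importances: dict[str, float]
    ranks: dict[str, int]
    order: list[str]

    def rank(self, key: str) -> int:
        return self.ranks[key]


def forest_gini(matrix: FeatureMatrix, n_trees: int = 100, seed: int = 0,
                chi2_ranks: dict[str, int] | None = None) -> ForestImportance:
    """Rank features by mean impurity decrease across ``n_trees`` fully
    grown bootstrap trees, every tree offered all features at every split."""
    X, keys = matrix.imputed()
    y = matrix.target.to_numpy(dtype=bool)
    if np.unique(y).size < 2 or not keys:
        imp = {k: 0.0 for k in keys}
    else:
        rf = RandomForestClassifier(
            n_estimators=n_trees, criterion="gini", max_depth=None,
            min_samples_split=2, max_features=None, bootstrap=True,
            random_state=seed, n_jobs=1)
        rf.fit(X, y)
        imp = dict(zip(keys, (float(v) for v in rf.feature_importances_)))
    c2 = chi2_ranks or {}
    schema = matrix.schema
    order = sorted(keys, key=lambda k: (-imp[k], c2.get(k, 10 ** 9), schema[k].name))
    ranks = {k: i for i, k in enumerate(order, start=1)}
    return ForestImportance(imp, ranks, order)


# ---------------------------------------------------------------------------
# Monotonicity gate for continuous candidates


def monotone_ok(values: np.ndarray, target: np.ndarray) -> bool:
    """True iff the positive rate across the feature's quartile bins is
    non-decreasing or non-increasing (documented values only)."""
    values = np.asarray(values, dtype=float)
    target = np.asarray(target, dtype=bool)
    mask = ~np.isnan(values)
    v, t = values[mask], target[mask]
    if np.unique(v).size < 2:
        return False
    bins = quartile_bins(v)
    if bins is None:
        return False
    rates = [t[bins == b].mean() for b in np.unique(bins)]
    inc = all(a <= b for a, b in zip(rates, rates[1:]))
    dec = all(a >= b for a, b in zip(rates, rates[1:]))
    return inc or dec


# ---------------------------------------------------------------------------
# Sequential covering


@dataclass(frozen=True)
class CoveringConfig:
    n_trees: int = 100
    gini_rank_max: int = 5
    seed: int = 0
    max_iterations: int = 500
    allow_fallback: bool = True
    refit_scope: str = "uncovered"  # or "flagged" (comparison reading)

    def validate(self) -> None:
        if self.refit_scope not in ("uncovered", "flagged"):
            raise ValueError(f"unknown refit_scope {self.refit_scope!r}")
        if self.n_trees < 1 or self.gini_rank_max < 1:
            raise ValueError("n_trees and gini_rank_max must be positive")


@dataclass
class SelectedFeature:
    descriptor: FeatureDescriptor
    phase: str  # "ESTABLISHED" | "DISCOVERED"
    iteration: int
    covered_new: int
    gini_importance: float
    gini_rank: int
    threshold: float | None = None
    direction: str | None = None  # numeric members: "gt" | "le"
    via_fallback: bool = False

    def as_rule_feature(self) -> RuleFeature:
        return RuleFeature(name=self.descriptor.source_item
                           if self.descriptor.domain is not Domain.NUMERIC
                           else self.descriptor.name,
                           domain=_RULE_DOMAIN[self.descriptor.domain],
                           threshold=self.threshold, direction=self.direction)


@dataclass
class RuleDerivationState:
    selected_features: list[SelectedFeature]
    log: list[dict]
    uncovered_ids: list[str]
    config: CoveringConfig
    n_training: int
    n_positives: int

    @property
    def excluded_fraction(self) -> float:
        return len(self.uncovered_ids) / self.n_training


def _coverage(matrix: FeatureMatrix, sel: SelectedFeature) -> np.ndarray:
    """Boolean vector: which rows possess the selected feature."""
    col = matrix.data[sel.descriptor.key]
    if sel.descriptor.domain is Domain.NUMERIC:
        vals = col.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            hit = (vals > sel.threshold) if sel.direction == "gt" else (vals <= sel.threshold)
        return hit & ~np.isnan(vals)
    return col.fillna(False).to_numpy(dtype=bool)


def _uncovered_mask(matrix: FeatureMatrix, selected: Sequence[SelectedFeature]) -> np.ndarray:
    mask = np.ones(matrix.n_rows, dtype=bool)
    for sel in selected:
        mask &= ~_coverage(matrix, sel)
    return mask


def _admissible_binary(desc: FeatureDescriptor) -> bool:
    return desc.domain in _PRESENCE_DOMAINS


def sequential_cover(matrix: FeatureMatrix, established: Iterable[str],
                     config: CoveringConfig = CoveringConfig(),
                     chi2_ranks: dict[str, int] | None = None) -> RuleDerivationState:
    """Run the two-phase sequential-covering loop on a training matrix.

    ``established`` holds feature names (or source items) designated a
    priori as vascular risk factors. Returns the full derivation state with
    a per-iteration log; raises :class:`StallError` when no admissible
    candidate can cover a remaining positive.
    """
    config.validate()
    y = matrix.target.to_numpy(dtype=bool)
    if not y.any():
        raise ValueError("training matrix has no positive case")
    est_canon = {canonical_name(e) for e in established}

    selected: list[SelectedFeature] = []
    log: list[dict] = []
    uncovered = np.ones(matrix.n_rows, dtype=bool)
    n_pos_prev = int(y.sum())
    iteration = 0

    while (y & uncovered).any():
        iteration += 1
        if iteration > config.max_iterations:
            raise StallError("covering exceeded max_iterations", log)
        if config.refit_scope == "flagged" and selected:
            fit_mask = ~uncovered
            if not fit_mask.any():
                fit_mask = np.ones_like(uncovered)
        else:
            fit_mask = uncovered
        sub = matrix.select_rows_mask(fit_mask)
        cover_sub = matrix.select_rows_mask(uncovered)
        sub_y = cover_sub.target.to_numpy(dtype=bool)

        imp = forest_gini(sub, config.n_trees, seed=config.seed + iteration,
                          chi2_ranks=chi2_ranks)

        def covered_count(sel: SelectedFeature) -> int:
            return int((_coverage(cover_sub, sel) & sub_y).sum())

        def make_sel(key: str, phase: str, threshold=None, direction=None,
                     fallback=False) -> SelectedFeature:
            return SelectedFeature(
                descriptor=matrix.schema[key], phase=phase, iteration=iteration,
                covered_new=0, gini_importance=imp.importances.get(key, 0.0),
                gini_rank=imp.ranks.get(key, 0), threshold=threshold,
                direction=direction, via_fallback=fallback)

        selected_keys = {s.descriptor.key for s in selected}
        candidate: SelectedFeature | None = None
        notes: list[str] = []

        # -- phase 1: established risk factors in the Gini top ranks -------
        est_keys = [k for k in imp.order
                    if k not in selected_keys
                    and imp.ranks[k] <= config.gini_rank_max
                    and _admissible_binary(matrix.schema[k])
                    and (canonical_name(matrix.schema[k].source_item) in est_canon
                         or canonical_name(matrix.schema[k].name) in est_canon)]
        for k in est_keys:  # best rank first (imp.order is rank order)
            cand = make_sel(k, "ESTABLISHED")
            if covered_count(cand) > 0:
                candidate = cand
                break
            notes.append(f"established candidate covers no new positive: {k}")

        # -- phase 2: highest-Gini feature on the path to the largest
        #    all-negative leaf ---------------------------------------------
        if candidate is None:
            try:
                tree = fit_cart(sub, seed=config.seed + iteration)
                path = largest_negative_leaf_path(tree)
            except NoNegativeLeafError:
                path = []
                notes.append("no all-negative leaf in CART tree")
            path_cands: list[SelectedFeature] = []
            seen: set[str] = set()
            for step in path:
                key = step.key
                if key in selected_keys or key in seen:
                    continue
                seen.add(key)
                desc = matrix.schema[key]
                if desc.is_binary:
                    if not _admissible_binary(desc):
                        continue
                    # the negative leaf must lie on the absence side: the
                    # branch toward the leaf goes left (value <= 0.5)
                    if step.goes_right:
                        notes.append(f"path feature inadmissible (presence predicts negative): {key}")
                        continue
                    path_cands.append(make_sel(key, "DISCOVERED"))
                else:
                    vals = cover_sub.data[key].to_numpy(dtype=float)
                    if not monotone_ok(vals, sub_y):
                        notes.append(f"continuous path feature fails monotonicity: {key}")
                        continue
                    direction = "le" if step.goes_right else "gt"
                    path_cands.append(make_sel(key, "DISCOVERED",
                                               threshold=step.threshold,
                                               direction=direction))
            path_cands = [c for c in path_cands if covered_count(c) > 0]
            if path_cands:
                candidate = min(path_cands, key=lambda c: c.gini_rank)

        # -- fallback: highest-Gini admissible covering feature ------------
        if candidate is None and config.allow_fallback:
            for k in imp.order:
                if k in selected_keys or not _admissible_binary(matrix.schema[k]):
                    continue
                cand = make_sel(k, "DISCOVERED", fallback=True)
                if covered_count(cand) > 0:
                    candidate = cand
                    notes.append(f"fallback step selected {k}")
                    break

        if candidate is None:
            raise StallError(
                f"iteration {iteration}: no admissible candidate covers a new positive",
                log)

        candidate.covered_new = covered_count(candidate)
        selected.append(candidate)
        uncovered = _uncovered_mask(matrix, selected)
        n_pos_now = int((y & uncovered).sum())
        if n_pos_now >= n_pos_prev:
            raise StallError(
                f"iteration {iteration}: uncovered positives did not decrease", log)
        log.append({
            "iteration": iteration,
            "feature": candidate.descriptor.key,
            "phase": candidate.phase,
            "via_fallback": candidate.via_fallback,
            "gini_importance": candidate.gini_importance,
            "gini_rank": candidate.gini_rank,
            "covered_new_positives": candidate.covered_new,
            "uncovered_positives_remaining": n_pos_now,
            "uncovered_cases_remaining": int(uncovered.sum()),
            "notes": notes,
        })
        n_pos_prev = n_pos_now

    ids = [str(i) for i in matrix.data.index[uncovered]]
    return RuleDerivationState(selected, log, ids, config,
                               matrix.n_rows, int(y.sum()))


# ---------------------------------------------------------------------------
# Clinical grouping


def _invert_grouping(grouping_map: dict) -> dict[str, str]:
    """Accept either {feature: category} or {"categories": {cat: [features]}}
    / {cat: [features]} forms; return canonical feature → category."""
    if "categories" in grouping_map and isinstance(grouping_map["categories"], dict):
        grouping_map = grouping_map["categories"]
    inverted: dict[str, str] = {}
    if all(isinstance(v, (list, tuple)) for v in grouping_map.values()):
        for cat, names in grouping_map.items():
            for name in names:
                c = canonical_name(name)
                if c in inverted and inverted[c] != cat:
                    raise ValueError(f"feature {name!r} mapped to two categories")
                inverted[c] = cat
    else:
        for name, cat in grouping_map.items():
            c = canonical_name(name)
            if c in inverted and inverted[c] != cat:
                raise ValueError(f"feature {name!r} mapped to two categories")
            inverted[c] = str(cat)
    return inverted


def group_features(selected: Sequence[SelectedFeature] | Sequence[RuleFeature],
                   grouping_map: dict | None = None,
                   name: str = "derived-rule",
                   metadata: dict | None = None) -> DecisionRule:
    """Group selected features into clinically coherent categories.

    Unmapped features become their own singleton category. Category order
    follows first appearance in the selection order.
    """
    inverted = _invert_grouping(grouping_map or {})
    rule_feats = [s.as_rule_feature() if isinstance(s, SelectedFeature) else s
                  for s in selected]
    cats: dict[str, list[RuleFeature]] = {}
    for f in rule_feats:
        label = inverted.get(canonical_name(f.name), f.name)
        cats.setdefault(label, []).append(f)
    return DecisionRule(
        categories=tuple(RuleCategory(label, tuple(feats))
                         for label, feats in cats.items()),
        name=name, metadata=metadata or {})


def _config_hash(config: CoveringConfig) -> str:
    raw = json.dumps(config.__dict__, sort_keys=True).encode()
    return hashlib.sha256(raw).hexdigest()[:12]


class SequentialCoveringClassifier:
    """Scikit-learn-style estimator for the covering derivation.

    ``fit(X, y)`` takes a :class:`FeatureMatrix` (``y`` defaults to the
    matrix's own target) and derives a decision rule; ``predict`` returns 1
    where the rule does NOT exclude a row (test positive: imaging
    warranted). Fitted attributes: ``rule_``, ``state_``,
    ``selected_features_``.
    """

    def __init__(self, established: Sequence[str] = (), n_trees: int = 100,
                 gini_rank_max: int = 5, random_state: int = 0,
                 allow_fallback: bool = True, refit_scope: str = "uncovered",
                 grouping_map: dict | None = None):
        self.established = established
        self.n_trees = n_trees
        self.gini_rank_max = gini_rank_max
        self.random_state = random_state
        self.allow_fallback = allow_fallback
        self.refit_scope = refit_scope
        self.grouping_map = grouping_map

    def _config(self) -> CoveringConfig:
        return CoveringConfig(n_trees=self.n_trees,
                              gini_rank_max=self.gini_rank_max,
                              seed=self.random_state,
                              allow_fallback=self.allow_fallback,
                              refit_scope=self.refit_scope)

    def fit(self, X: FeatureMatrix, y=None,
            chi2_ranks: dict[str, int] | None = None) -> "SequentialCoveringClassifier":
        if y is not None:
            X = FeatureMatrix(X.data, X.schema,
                              pd.Series(np.asarray(y, dtype=bool), index=X.data.index))
        config = self._config()
        self.state_ = sequential_cover(X, self.established, config, chi2_ranks)
        self.selected_features_ = self.state_.selected_features
        self.rule_ = group_features(
            self.selected_features_, self.grouping_map,
            metadata={
                "provenance": {
                    "phases": {s.descriptor.key: s.phase for s in self.selected_features_},
                    "iteration_log": self.state_.log,
                    "seed": self.random_state,
                    "config_hash": _config_hash(config),
                }})
        self.classes_ = [0, 1]
        return self

    def predict(self, X: FeatureMatrix) -> np.ndarray:
        if not hasattr(self, "state_"):
            raise RuntimeError("SequentialCoveringClassifier is not fitted")
        return (~_uncovered_mask(X, self.selected_features_)).astype(int)

    def get_params(self, deep: bool = True) -> dict:
        return {"established": self.established, "n_trees": self.n_trees,
                "gini_rank_max": self.gini_rank_max,
                "random_state": self.random_state,
                "allow_fallback": self.allow_fallback,
                "refit_scope": self.refit_scope,
                "grouping_map": self.grouping_map}

    def set_params(self, **params) -> "SequentialCoveringClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self
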