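"""Two-stage candidate feature filtering.

Stage 1 caps the candidate pool by documentation frequency per source
domain (by default the 200 most-documented PMH codes, 100 ROS items, 100 PE
items, plus all numeric and demographic columns). Stage 2 ranks the
survivors by a chi-squared test of association with the outcome and keeps
the 100 highest-ranked features as a single merged list. The chi-squared
statistic is used purely for ranking: no continuity correction and no
multiple-testing adjustment are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import Domain, FeatureDescriptor, FeatureMatrix, documentation_counts


@dataclass(frozen=True)
class FrequencyCaps:
    pmh: int = 200
    ros: int = 100
    pe: int = 100

    def validate(self) -> None:
        if min(self.pmh, self.ros, self.pe) <= 0:
            raise ValueError("frequency caps must be positive")


@dataclass
class FeatureScore:
    """Scoring record for one feature column."""

    feature: FeatureDescriptor
    doc_count: int
    chi2_stat: float
    chi2_p: float
    chi2_rank: int = 0
    gini_importance: float | None = None
    gini_rank: int | None = None


def frequency_filter(matrix: FeatureMatrix, caps: FrequencyCaps = FrequencyCaps()
                     ) -> FeatureMatrix:
    """Keep only the most-documented features per domain.

    PMH columns rank by code-present count; ROS/PE rank at the *source item*
    level by documented count (keeping both the pertinent-positive and
    pertinent-negative variants of each kept item); numeric and demographic
    columns always survive. Ties break lexicographically by name.
    """
    caps.validate()
    counts = documentation_counts(matrix)

    def top_items(domain_values: list[str], cap: int, by_item: bool) -> set[str]:
        sub = counts[counts["domain"].isin(domain_values)]
        if by_item:
            # both variants of a pair share the same documented count; rank
            # the source items
            items = {}
            for key in sub.index:
                desc = matrix.schema[key]
                items.setdefault(desc.source_item, int(sub.loc[key, "doc_count"]))
            ranked = sorted(items, key=lambda it: (-items[it], it))[:cap]
            keep_items = set(ranked)
            return {key for key in sub.index
                    if matrix.schema[key].source_item in keep_items}
        ranked = sorted(sub.index, key=lambda k: (-int(sub.loc[k, "doc_count"]),
                                                  matrix.schema[k].name))
        return set(ranked[:cap])

    keep = top_items(["PMH"], caps.pmh, by_item=False)
    keep |= top_items(["ROS_POS", "ROS_NEG"], caps.ros, by_item=True)
    keep |= top_items(["PE_POS", "PE_NEG"], caps.pe, by_item=True)
    keep |= {k for k, d in matrix.schema.items()
             if d.domain in (Domain.NUMERIC, Domain.DEMOGRAPHIC)}
    return matrix.select_columns([k for k in matrix.columns if k in keep])


def _chi2_binary(cell: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Chi-squared on the 2×2 (feature TRUE/FALSE × outcome) table."""
    table = np.array([[np.sum(cell & y), np.sum(cell & ~y)],
                      [np.sum(~cell & y), np.sum(~cell & ~y)]], dtype=float)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def quartile_bins(values: np.ndarray) -> np.ndarray | None:
    """Quartile bin assignment over documented values (NaN rows excluded by
    caller); returns None when fewer than 2 distinct bins exist."""
    edges = np.unique(np.quantile(values, [0.25, 0.5, 0.75]))
    bins = np.searchsorted(edges, values, side="left")
    if np.unique(bins).size < 2:
        return None
    return bins


def _chi2_numeric(values: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Quartile-binned chi-squared for a continuous feature; undocumented
    rows are dropped from the test."""
    mask = ~np.isnan(values)
    if mask.sum() == 0:
        return 0.0, 1.0
    v, t = values[mask], y[mask]
    bins = quartile_bins(v)
    if bins is None or np.unique(t).size < 2:
        return 0.0, 1.0
    table = pd.crosstab(bins, t).to_numpy(dtype=float)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def score_features(matrix: FeatureMatrix) -> list[FeatureScore]:
    """Chi-squared score for every feature, ranked (statistic desc, name asc).

    Binary cells treat missing as FALSE (the consumer-boundary convention);
    degenerate single-valued features score 0 and rank last.
    """
    y = matrix.target.to_numpy(dtype=bool)
    counts = documentation_counts(matrix)
    scores: list[FeatureScore] = []
    for key, desc in matrix.schema.items():
        if desc.is_binary:
            cell = matrix.data[key].fillna(False).to_numpy(dtype=bool)
            stat, p = _chi2_binary(cell, y)
        else:
            stat, p = _chi2_numeric(matrix.data[key].to_numpy(dtype=float), y)
        scores.append(FeatureScore(desc, int(counts.loc[key, "doc_count"]), stat, p))
    scores.sort(key=lambda s: (-s.chi2_stat, s.feature.name))
    for i, s in enumerate(scores, start=1):
        s.chi2_rank = i
    return scores


def chi2_rank(matrix: FeatureMatrix, top_k: int = 100) -> list[FeatureScore]:
    """The ``top_k`` features most associated with the outcome."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    return score_features(matrix)[:top_k]


def select_top_k(matrix: FeatureMatrix, top_k: int = 100
                 ) -> tuple[FeatureMatrix, list[FeatureScore]]:
    """Reduce a matrix to its chi-squared top-``top_k`` columns."""
    scores = chi2_rank(matrix, top_k)
    keep = {s.feature.key for s in scores}
    return matrix.select_columns([k for k in matrix.columns if k in keep]), scores


def scores_to_frame(scores: list[FeatureScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"name": s.feature.name, "domain": s.feature.domain.value,
          "doc_count": s.doc_count, "chi2_stat": s.chi2_stat, "chi2_p": s.chi2_p,
          "chi2_rank": s.chi2_rank, "gini_importance": s.gini_importance,
          "gini_rank": s.gini_rank}
         for s in scores])


class FrequencyFilter:
    """Transformer wrapper over :func:`frequency_filter`."""

    def __init__(self, pmh_cap: int = 200, ros_cap: int = 100, pe_cap: int = 100):
        self.pmh_cap, self.ros_cap, self.pe_cap = pmh_cap, ros_cap, pe_cap

    def fit(self, X: FeatureMatrix, y=None) -> "FrequencyFilter":
        caps = FrequencyCaps(self.pmh_cap, self.ros_cap, self.pe_cap)
        self.kept_keys_ = frequency_filter(X, caps).columns
        return self

    def transform(self, X: FeatureMatrix) -> FeatureMatrix:
        return X.select_columns(self.kept_keys_)

    def fit_transform(self, X: FeatureMatrix, y=None) -> FeatureMatrix:
        return self.fit(X).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {"pmh_cap": self.pmh_cap, "ros_cap": self.ros_cap, "pe_cap": self.pe_cap}

    def set_params(self, **params) -> "FrequencyFilter":
        for k, v in params.items():
            setattr(self, k, v)
        return self


class Chi2TopK:
    """Transformer wrapper over :func:`select_top_k`."""

    def __init__(self, k: int = 100):
        self.k = k

    def fit(self, X: FeatureMatrix, y=None) -> "Chi2TopK":
        _, self.scores_ = select_top_k(X, self.k)
        self.kept_keys_ = [s.feature.key for s in self.scores_]
        return self

    def transform(self, X: FeatureMatrix) -> FeatureMatrix:
        return X.select_columns(self.kept_keys_)

    def fit_transform(self, X: FeatureMatrix, y=None) -> FeatureMatrix:
        return self.fit(X).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k}

    def set_params(self, **params) -> "Chi2TopK":
        for k, v in params.items():
            setattr(self, k, v)
        return self
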