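"""Null-aware feature encoding of encounter records.

The encoding scheme distinguishes three documentation states for ROS and PE
items — pertinent positive, pertinent negative, undocumented — by giving
each source item two nullable boolean columns (``_POS`` and ``_NEG``
variants) whose cells are both missing when the item was never documented.
PMH diagnosis codes are one-hot with *informative absence*: a code not on
the problem list is FALSE, never missing, because codes only appear when
assigned. Numeric measurements pass through as floats with NaN for
undocumented values; demographics become plain binary columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import EncounterRecord, Finding


class Domain(str, Enum):
    PMH = "PMH"
    ROS_POS = "ROS_POS"
    ROS_NEG = "ROS_NEG"
    PE_POS = "PE_POS"
    PE_NEG = "PE_NEG"
    NUMERIC = "NUMERIC"
    DEMOGRAPHIC = "DEMOGRAPHIC"


_DOMAIN_ORDER = {d: i for i, d in enumerate(Domain)}
_BINARY_DOMAINS = {Domain.PMH, Domain.ROS_POS, Domain.ROS_NEG,
                   Domain.PE_POS, Domain.PE_NEG, Domain.DEMOGRAPHIC}
# domains that may carry missing cells (undocumented ROS/PE items)
_NULLABLE_DOMAINS = {Domain.ROS_POS, Domain.ROS_NEG, Domain.PE_POS, Domain.PE_NEG}


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one feature column: display name, domain, source item."""

    name: str
    domain: Domain
    source_item: str

    @property
    def key(self) -> str:
        return f"{self.domain.value}:{self.name}"

    @property
    def is_binary(self) -> bool:
        return self.domain in _BINARY_DOMAINS


class FeatureMatrix:
    """Encounters × features table with tri-state binary cells.

    Binary columns use pandas' nullable ``boolean`` dtype (pd.NA = missing);
    numeric columns are float64 with NaN. ``target`` is the per-row
    positive-outcome indicator aligned with the row index.
    """

    def __init__(self, data: pd.DataFrame, schema: dict[str, FeatureDescriptor],
                 target: pd.Series):
        if list(data.columns) != list(schema):
            raise ValueError("data columns and schema keys disagree")
        if not data.index.equals(target.index):
            raise ValueError("target index misaligned with data rows")
        self.data = data
        self.schema = schema
        self.target = target.astype(bool)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def descriptors(self, domains: Iterable[Domain] | None = None) -> list[FeatureDescriptor]:
        if domains is None:
            return list(self.schema.values())
        wanted = set(domains)
        return [d for d in self.schema.values() if d.domain in wanted]

    def binary_keys(self) -> list[str]:
        return [k for k, d in self.schema.items() if d.is_binary]

    def numeric_keys(self) -> list[str]:
        return [k for k, d in self.schema.items() if d.domain is Domain.NUMERIC]

    # -- subsetting --------------------------------------------------------
    def select_columns(self, keys: Sequence[str]) -> "FeatureMatrix":
        keys = [k for k in self.schema if k in set(keys)]  # preserve order
        return FeatureMatrix(self.data[keys], {k: self.schema[k] for k in keys},
                             self.target)

    def select_rows(self, ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[list(ids)], dict(self.schema),
                             self.target.loc[list(ids)])

    def select_rows_mask(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[mask], dict(self.schema),
                             self.target.loc[mask])

    # -- consumer-boundary imputation --------------------------------------
    def imputed(self) -> tuple[np.ndarray, list[str]]:
        """Dense float matrix for algorithms that cannot consume missingness.

        Single documented convention: MISSING → FALSE for binary columns
        (documentation absence treated as feature absence) and MISSING →
        column median for numeric columns (all-missing column → 0).
        """
        cols = []
        for key, desc in self.schema.items():
            col = self.data[key]
            if desc.is_binary:
                cols.append(col.fillna(False).to_numpy(dtype=float))
            else:
                vals = col.to_numpy(dtype=float)
                med = np.nanmedian(vals) if np.isfinite(vals).any() else 0.0
                cols.append(np.where(np.isnan(vals), med, vals))
        X = np.column_stack(cols) if cols else np.empty((self.n_rows, 0))
        return X, self.columns

    # -- serialization -----------------------------------------------------
    def to_csv(self, path: str | Path, schema_path: str | Path | None = None) -> None:
        """Wide CSV (missing cells rendered empty) plus a sidecar JSON schema."""
        path = Path(path)
        out = self.data.copy()
        for key, desc in self.schema.items():
            if desc.is_binary:
                out[key] = self.data[key].map({True: 1, False: 0}, na_action="ignore")
        out.insert(0, "target", self.target.astype(int))
        out.to_csv(path, index_label="encounter_id")
        schema_path = Path(schema_path) if schema_path else path.with_suffix(".schema.json")
        with open(schema_path, "w") as fh:
            json.dump([{"key": k, "name": d.name, "domain": d.domain.value,
                        "source_item": d.source_item} for k, d in self.schema.items()],
                      fh, indent=1)


def _ordered(descs: Iterable[FeatureDescriptor]) -> list[FeatureDescriptor]:
    return sorted(descs, key=lambda d: (_DOMAIN_ORDER[d.domain], d.name))


def encode(cohort: Sequence[EncounterRecord],
           vocabulary: Sequence[FeatureDescriptor] | None = None) -> FeatureMatrix:
    """Encode a cohort into a FeatureMatrix.

    Every distinct PMH code observed becomes one binary column; every ROS/PE
    item becomes a ``_POS``/``_NEG`` column pair; numerics (including age and
    NIHSS) pass through; sex and race/ethnicity flags become DEMOGRAPHIC
    binaries. Column order is deterministic (domain, then name). A fitted
    ``vocabulary`` may be supplied to encode new records into an existing
    column space (unseen items are then ignored).
    """
    if not cohort:
        raise ValueError("cannot encode an empty cohort")
    ids = [r.encounter_id for r in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate encounter ids")

    descs = _ordered(build_vocabulary(cohort)) if vocabulary is None else list(vocabulary)
    index = pd.Index(ids, name="encounter_id")
    columns: dict[str, pd.Series] = {}
    for desc in descs:
        columns[desc.key] = _encode_column(cohort, desc, index)
    data = pd.DataFrame(columns, index=index)
    target = pd.Series([r.is_positive for r in cohort], index=index, name="target")
    return FeatureMatrix(data, {d.key: d for d in descs}, target)


def build_vocabulary(cohort: Sequence[EncounterRecord]) -> list[FeatureDescriptor]:
    """All feature descriptors observable in a cohort, deterministically ordered."""
    pmh, ros, pe, nums, demo = set(), set(), set(), set(), set()
    for r in cohort:
        pmh |= r.pmh_codes
        ros |= set(r.ros)
        pe |= set(r.pe)
        nums |= set(r.numerics)
        demo |= r.race_ethnicity
    descs = [FeatureDescriptor(c, Domain.PMH, c) for c in pmh]
    for item in ros:
        descs.append(FeatureDescriptor(f"{item} (pertinent positive)", Domain.ROS_POS, item))
        descs.append(FeatureDescriptor(f"{item} (pertinent negative)", Domain.ROS_NEG, item))
    for item in pe:
        descs.append(FeatureDescriptor(f"{item} (pertinent positive)", Domain.PE_POS, item))
        descs.append(FeatureDescriptor(f"{item} (pertinent negative)", Domain.PE_NEG, item))
    nums |= {"age"}
    if any(r.nihss is not None for r in cohort):
        nums |= {"nihss"}
    descs += [FeatureDescriptor(n, Domain.NUMERIC, n) for n in nums]
    descs.append(FeatureDescriptor("Male", Domain.DEMOGRAPHIC, "sex"))
    descs += [FeatureDescriptor(flag, Domain.DEMOGRAPHIC, flag) for flag in demo]
    return _ordered(descs)


def _encode_column(cohort: Sequence[EncounterRecord], desc: FeatureDescriptor,
                   index: pd.Index) -> pd.Series:
    dom = desc.domain
    if dom is Domain.PMH:
        vals = [desc.source_item in r.pmh_codes for r in cohort]
        return pd.Series(vals, index=index, dtype="boolean")
    if dom in _NULLABLE_DOMAINS:
        finding = Finding.POSITIVE if dom in (Domain.ROS_POS, Domain.PE_POS) else Finding.NEGATIVE
        source = (lambda r: r.ros) if dom in (Domain.ROS_POS, Domain.ROS_NEG) else (lambda r: r.pe)
        vals = [pd.NA if desc.source_item not in source(r)
                else source(r)[desc.source_item] is finding for r in cohort]
        return pd.Series(vals, index=index, dtype="boolean")
    if dom is Domain.NUMERIC:
        if desc.source_item == "age":
            vals = [float(r.age) for r in cohort]
        elif desc.source_item == "nihss":
            vals = [np.nan if r.nihss is None else float(r.nihss) for r in cohort]
        else:
            vals = [r.numerics.get(desc.source_item, np.nan) for r in cohort]
        return pd.Series(vals, index=index, dtype=float)
    if dom is Domain.DEMOGRAPHIC:
        if desc.source_item == "sex":
            vals = [r.sex == "male" for r in cohort]
        else:
            vals = [desc.source_item in r.race_ethnicity for r in cohort]
        return pd.Series(vals, index=index, dtype="boolean")
    raise ValueError(f"unhandled domain {dom}")


def decode(matrix: FeatureMatrix) -> dict[str, dict]:
    """Recover each encounter's documented content from the matrix.

    Returns ``{encounter_id: {"pmh": set, "ros": {item: Finding}, "pe": ...,
    "numerics": {name: value}}}``; inverse of :func:`encode` for documented
    content (the round trip is exercised as an encoding-contract test).
    """
    out: dict[str, dict] = {
        eid: {"pmh": set(), "ros": {}, "pe": {}, "numerics": {}} for eid in matrix.data.index}
    for key, desc in matrix.schema.items():
        col = matrix.data[key]
        if desc.domain is Domain.PMH:
            for eid in col.index[col.fillna(False).to_numpy(dtype=bool)]:
                out[eid]["pmh"].add(desc.source_item)
        elif desc.domain in (Domain.ROS_POS, Domain.PE_POS):
            slot = "ros" if desc.domain is Domain.ROS_POS else "pe"
            for eid, v in col.items():
                if v is not pd.NA and not pd.isna(v):
                    out[eid][slot][desc.source_item] = Finding.POSITIVE if v else Finding.NEGATIVE
        elif desc.domain is Domain.NUMERIC and desc.source_item not in ("age", "nihss"):
            for eid, v in col.items():
                if not pd.isna(v):
                    out[eid]["numerics"][desc.source_item] = float(v)
    return out


def documentation_counts(matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-feature documentation tallies.

    Two conventions are emitted side by side (it is not always knowable
    which one a given EHR report used when ranking "most documented"):

    * ``doc_count`` — PMH: rows where the code is present; ROS/PE variants:
      rows where the item was documented at all (positively or negatively);
      numeric: rows with a value; demographic: all rows.
    * ``positive_count`` — binary columns: rows where the cell is TRUE.
    """
    rows = []
    for key, desc in matrix.schema.items():
        col = matrix.data[key]
        if desc.domain is Domain.PMH:
            pos = int(col.fillna(False).sum())
            doc = pos
        elif desc.is_binary and desc.domain in _NULLABLE_DOMAINS:
            doc = int(col.notna().sum())
            pos = int(col.fillna(False).sum())
        elif desc.is_binary:  # demographics: always known
            doc = matrix.n_rows
            pos = int(col.fillna(False).sum())
        else:
            doc = int(col.notna().sum())
            pos = doc
        rows.append((key, desc.name, desc.domain.value, doc, pos))
    df = pd.DataFrame(rows, columns=["key", "name", "domain", "doc_count", "positive_count"])
    df = df.set_index("key")
    df.attrs["convention"] = ("doc_count: PMH=code-present rows, ROS/PE=documented rows, "
                              "NUMERIC=non-missing rows, DEMOGRAPHIC=all rows; "
                              "positive_count: TRUE cells")
    return df


class EncounterEncoder:
    """Transformer wrapper over :func:`encode` (scikit-learn style).

    ``fit`` captures the feature vocabulary of a cohort; ``transform``
    encodes (possibly different) records into that fixed column space.
    """

    def __init__(self) -> None:
        self.vocabulary_: list[FeatureDescriptor] | None = None

    def fit(self, records: Sequence[EncounterRecord], y=None) -> "EncounterEncoder":
        if not records:
            raise ValueError("cannot fit on an empty cohort")
        self.vocabulary_ = build_vocabulary(records)
        return self

    def transform(self, records: Sequence[EncounterRecord]) -> FeatureMatrix:
        if self.vocabulary_ is None:
            raise RuntimeError("EncounterEncoder is not fitted")
        return encode(records, vocabulary=self.vocabulary_)

    def fit_transform(self, records: Sequence[EncounterRecord], y=None) -> FeatureMatrix:
        return self.fit(records).transform(records)

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "EncounterEncoder":
        return self
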