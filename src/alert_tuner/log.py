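"""Alert-firing logs: outcome derivation, alert-level filtering, encoding.

An alert log has one row per firing of a Best Practice Advisory (BPA): the
BPA identifier, a timestamp, the free-text user action, and a mixed bag of
categorical/numeric features captured before the alert was displayed. This
module derives the binary outcome (accepted vs not accepted) from the
action label, drops alerts with too little signal, and encodes features
into a fully binary design matrix: categoricals are one-hot over the
training vocabulary, numerics are imputed, cut into 10 equal-width bins
learned on training data, and one-hot over bins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .rules import Predicate, Rule

logger = logging.getLogger(__name__)

__all__ = [
    "ACCEPTED",
    "NOT_ACCEPTED",
    "ResponseMapping",
    "map_response",
    "derive_outcomes",
    "filter_alerts",
    "impute_numeric",
    "bin_numeric",
    "FeatureSchema",
    "DesignMatrix",
    "build_design_matrix",
    "decode_column",
    "read_log",
    "write_log",
]

ACCEPTED = 0
NOT_ACCEPTED = 1

#: Action labels that count as the user *not* accepting the alert; every
#: other observed label counts as accepted.
DEFAULT_NOT_ACCEPTED_LABELS = frozenset(
    {
        "Acknowledge/override Warning",
        "Cancel Warning",
        "No Action Taken",
        "Accept BPA (No Action Taken)",
        "Cancel BPA",
    }
)

#: Labels known to mean acceptance (suppresses the unknown-label warning).
DEFAULT_ACCEPTED_LABELS = frozenset({"single order", "remove order set"})

RESERVED_COLUMNS = ("bpa_id", "fired_at", "action", "outcome")


@dataclass(frozen=True)
class ResponseMapping:
    """Maps free-text user actions onto the binary accepted/not-accepted outcome."""

    not_accepted_labels: frozenset = DEFAULT_NOT_ACCEPTED_LABELS
    accepted_labels: frozenset = DEFAULT_ACCEPTED_LABELS


def map_response(action_label: str, mapping: ResponseMapping = ResponseMapping()) -> int:
    """Classify one action label; unknown labels are accepted (with a warning)."""
    if not isinstance(action_label, str) or action_label == "":
        raise ValueError("action label must be a non-empty string")
    if action_label in mapping.not_accepted_labels:
        return NOT_ACCEPTED
    if action_label not in mapping.accepted_labels:
        logger.warning("unknown action label %r mapped to accepted", action_label)
    return ACCEPTED


def derive_outcomes(log: pd.DataFrame, mapping: ResponseMapping = ResponseMapping()) -> pd.DataFrame:
    """Attach an ``outcome`` column (1 = not accepted) derived from ``action``."""
    if "action" not in log.columns:
        raise KeyError("log requires an 'action' column")
    actions = log["action"].astype(str)
    unknown = sorted(
        set(actions.unique()) - set(mapping.not_accepted_labels) - set(mapping.accepted_labels)
    )
    if unknown:
        logger.warning(
            "%d unknown action label(s) mapped to accepted: %s", len(unknown), unknown[:10]
        )
    out = log.copy()
    out["outcome"] = actions.isin(mapping.not_accepted_labels).astype(np.int8)
    return out


def filter_alerts(log: pd.DataFrame, min_firings: int = 100, min_acceptances: int = 10) -> pd.DataFrame:
    """Drop BPAs with firing count <= ``min_firings`` or acceptances <= ``min_acceptances``.

    Requires derived outcomes. Row order of retained firings is preserved.
    """
    if "outcome" not in log.columns:
        raise KeyError("derive outcomes before filtering alerts")
    grp = log.groupby("bpa_id")["outcome"]
    firings = grp.size()
    acceptances = grp.apply(lambda s: int((s == ACCEPTED).sum()))
    keep = firings.index[(firings > min_firings) & (acceptances > min_acceptances)]
    out = log[log["bpa_id"].isin(keep)]
    if out.empty:
        logger.warning("alert-level filtering removed every firing")
    return out


def impute_numeric(values, strategy: str = "median", name: str = "feature"):
    """Fill missing entries with a training statistic; returns (filled, value).

    The statistic is computed on the supplied values (training data); apply
    the returned value at transform time for new rows.
    """
    arr = pd.to_numeric(pd.Series(values), errors="coerce")
    if arr.isna().all():
        raise ValueError(f"feature {name!r} has no observed values to impute from")
    if strategy == "mean":
        fill = float(arr.mean())
    elif strategy == "median":
        fill = float(arr.median())
    elif strategy == "most_frequent":
        fill = float(arr.mode(dropna=True).iloc[0])
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    return arr.fillna(fill).to_numpy(dtype=float), fill


def bin_numeric(values, n_bins: int = 10, edges=None):
    """Equal-width binning: value v maps to floor(n*(v-min)/(max-min)), clamped.

    The last bin is right-closed so the maximum lands in bin n-1. With
    ``edges`` given (transform mode), the learned span is reused and
    out-of-range values are clamped into the terminal bins. A constant
    column yields a single degenerate bin 0.
    """
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("binning requires imputed (non-missing) values")
    if edges is None:
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        lo, hi = float(arr.min()), float(arr.max())
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        edges = np.asarray(edges, dtype=float)
        lo, hi = float(edges[0]), float(edges[-1])
        n_bins = len(edges) - 1
    span = hi - lo
    if span == 0.0:
        return np.zeros(arr.shape, dtype=np.int64), edges
    idx = np.floor(n_bins * (arr - lo) / span).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1), edges


@dataclass
class NumericSpec:
    edges: np.ndarray
    impute_value: float


@dataclass
class CategoricalSpec:
    categories: list


@dataclass
class FeatureSchema:
    """Frozen encoding recipe learned from training data only.

    Numeric features carry 11 bin edges (10 equal-width bins) and an
    imputation value; categorical features carry their training vocabulary.
    """

    numeric: dict = field(default_factory=dict)
    categorical: dict = field(default_factory=dict)
    n_bins: int = 10
    impute_strategy: str = "median"

    @property
    def features(self) -> list:
        return sorted(list(self.numeric) + list(self.categorical))

    @classmethod
    def fit(
        cls,
        df: pd.DataFrame,
        feature_columns: Optional[Iterable[str]] = None,
        n_bins: int = 10,
        impute_strategy: str = "median",
        categorical_overrides: Iterable[str] = (),
    ) -> "FeatureSchema":
        if feature_columns is None:
            feature_columns = [c for c in df.columns if c not in RESERVED_COLUMNS]
        schema = cls(n_bins=n_bins, impute_strategy=impute_strategy)
        overrides = set(categorical_overrides)
        for name in feature_columns:
            if "=" in name:
                raise ValueError(f"feature name {name!r} may not contain '='")
            col = df[name]
            if name not in overrides and pd.api.types.is_numeric_dtype(col):
                filled, fill = impute_numeric(col, impute_strategy, name=name)
                _, edges = bin_numeric(filled, n_bins=n_bins)
                schema.numeric[name] = NumericSpec(edges=edges, impute_value=fill)
            else:
                cats = sorted(col.dropna().astype(str).unique().tolist())
                schema.categorical[name] = CategoricalSpec(categories=cats)
        return schema

    # --- predicates / columns -------------------------------------------------
    def predicate_for(self, feature: str, value) -> Predicate:
        """Predicate for a raw (feature, value) pair under this schema."""
        if feature in self.categorical:
            return Predicate(feature=feature, op="eq", value=str(value))
        if feature in self.numeric:
            spec = self.numeric[feature]
            idx, _ = bin_numeric([float(value)], edges=spec.edges)
            return self.bin_predicate(feature, int(idx[0]))
        raise KeyError(f"feature {feature!r} not in schema")

    def bin_predicate(self, feature: str, bin_index: int) -> Predicate:
        spec = self.numeric[feature]
        n = len(spec.edges) - 1
        if not 0 <= bin_index < n:
            raise ValueError(f"bin index {bin_index} out of range for {feature!r}")
        return Predicate(
            feature=feature,
            op="in_bin",
            bin_index=bin_index,
            lo=float(spec.edges[bin_index]),
            hi=float(spec.edges[bin_index + 1]),
            hi_closed=bin_index == n - 1,
        )

    def columns(self) -> tuple[list, list]:
        """All design-matrix column names and their aligned predicates."""
        names, preds = [], []
        for feat in sorted(self.categorical):
            for cat in self.categorical[feat].categories:
                p = Predicate(feature=feat, op="eq", value=cat)
                names.append(p.column)
                preds.append(p)
        for feat in sorted(self.numeric):
            for b in range(len(self.numeric[feat].edges) - 1):
                p = self.bin_predicate(feat, b)
                names.append(p.column)
                preds.append(p)
        return names, preds

    # --- serialization --------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "n_bins": self.n_bins,
            "impute_strategy": self.impute_strategy,
            "numeric": {
                k: {"edges": [float(e) for e in v.edges], "impute_value": v.impute_value}
                for k, v in self.numeric.items()
            },
            "categorical": {k: {"categories": v.categories} for k, v in self.categorical.items()},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "FeatureSchema":
        try:
            data = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                data = json.load(fh)
        schema = cls(n_bins=data["n_bins"], impute_strategy=data["impute_strategy"])
        for k, v in data["numeric"].items():
            schema.numeric[k] = NumericSpec(
                edges=np.asarray(v["edges"], dtype=float), impute_value=v["impute_value"]
            )
        for k, v in data["categorical"].items():
            schema.categorical[k] = CategoricalSpec(categories=list(v["categories"]))
        return schema


def decode_column(name: str, schema: FeatureSchema) -> Predicate:
    """Invert a design-matrix column name back to its predicate."""
    feature, _, value = name.partition("=")
    if feature in schema.categorical:
        return Predicate(feature=feature, op="eq", value=value)
    if feature in schema.numeric and value.startswith("bin"):
        return schema.bin_predicate(feature, int(value[3:]))
    raise KeyError(f"column {name!r} does not decode against the schema")


@dataclass
class DesignMatrix:
    """Fully binary encoded log: one column per (feature, category-or-bin)."""

    X: np.ndarray
    columns: list
    predicates: list
    y: Optional[np.ndarray] = None
    bpa_ids: Optional[np.ndarray] = None
    index: Optional[np.ndarray] = None

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    def mask_for_rule(self, rule: Rule) -> np.ndarray:
        """Rows covered by a rule (restricted to its BPA when scoped)."""
        mask = np.ones(self.n_rows, dtype=bool)
        if rule.bpa_id is not None and self.bpa_ids is not None:
            mask &= self.bpa_ids == rule.bpa_id
        for pred in rule.predicates:
            try:
                j = self.column_index(pred.column)
            except ValueError:
                return np.zeros(self.n_rows, dtype=bool)
            mask &= self.X[:, j] == 1
        return mask

    def subset(self, row_mask: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(
            X=self.X[row_mask],
            columns=self.columns,
            predicates=self.predicates,
            y=None if self.y is None else self.y[row_mask],
            bpa_ids=None if self.bpa_ids is None else self.bpa_ids[row_mask],
            index=None if self.index is None else self.index[row_mask],
        )


def build_design_matrix(log: pd.DataFrame, schema: FeatureSchema) -> DesignMatrix:
    """Encode a log through a fitted schema.

    Numerics: impute with the schema's training statistic, bin on the
    learned edges, one-hot over bins. Categoricals: one-hot over the
    training vocabulary; a category unseen at fit time yields an all-zero
    block for that feature. Feature columns in the log that the schema does
    not know are an error.
    """
    feature_cols = [c for c in log.columns if c not in RESERVED_COLUMNS]
    unknown = set(feature_cols) - set(schema.features)
    if unknown:
        raise KeyError(f"features absent from schema: {sorted(unknown)}")
    missing = set(schema.features) - set(feature_cols)
    if missing:
        raise KeyError(f"schema features missing from log: {sorted(missing)}")

    names, preds = schema.columns()
    X = np.zeros((len(log), len(names)), dtype=np.uint8)
    col_of = {n: j for j, n in enumerate(names)}

    for feat in sorted(schema.categorical):
        values = log[feat].astype("string")
        for cat in schema.categorical[feat].categories:
            X[:, col_of[f"{feat}={cat}"]] = (values == cat).fillna(False).to_numpy(dtype=np.uint8)
    for feat in sorted(schema.numeric):
        spec = schema.numeric[feat]
        vals = pd.to_numeric(log[feat], errors="coerce").to_numpy(dtype=float)
        vals = np.where(np.isnan(vals), spec.impute_value, vals)
        idx, _ = bin_numeric(vals, edges=spec.edges)
        for b in range(len(spec.edges) - 1):
            X[:, col_of[f"{feat}=bin{b}"]] = (idx == b).astype(np.uint8)

    y = log["outcome"].to_numpy(dtype=np.int8) if "outcome" in log.columns else None
    bpa = log["bpa_id"].astype(str).to_numpy() if "bpa_id" in log.columns else None
    return DesignMatrix(
        X=X, columns=names, predicates=preds, y=y, bpa_ids=bpa, index=log.index.to_numpy()
    )


def read_log(path) -> pd.DataFrame:
    """Read an alert log from CSV or Parquet (by file extension)."""
    path = str(path)
    if path.endswith(".parquet"):
        return pd.read_parquet(path)
    return pd.read_csv(path)


def write_log(log: pd.DataFrame, path) -> None:
    path = str(path)
    if path.endswith(".parquet"):
        log.to_parquet(path, index=False)
    else:
        log.to_csv(path, index=False)
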