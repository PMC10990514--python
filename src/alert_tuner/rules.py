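"""Rules: conjunctions of feature predicates scoped to one alert (BPA).

A rule is the unit every explainer emits and every downstream screen
consumes: "IF <predicates> THEN the user is unlikely to accept the alert".
Predicates come in two flavours matching the encoded design matrix:
equality on a categorical feature, or membership in one equal-width bin of
a numeric feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Predicate",
    "Rule",
    "RuleSet",
    "rule_mask",
    "merge_rules",
]


@dataclass(frozen=True)
class Predicate:
    """One atomic condition on a source feature.

    op == "eq": feature equals ``value`` (categorical).
    op == "in_bin": feature falls in bin ``bin_index`` with interval
    [lo, hi) — hi-closed for the last bin of a feature.
    """

    feature: str
    op: str  # "eq" | "in_bin"
    value: Optional[str] = None
    bin_index: Optional[int] = None
    lo: Optional[float] = None
    hi: Optional[float] = None
    hi_closed: bool = False

    def __post_init__(self) -> None:
        if self.op not in ("eq", "in_bin"):
            raise ValueError(f"unknown predicate op: {self.op!r}")
        if self.op == "eq" and self.value is None:
            raise ValueError("eq predicate requires a value")
        if self.op == "in_bin" and self.bin_index is None:
            raise ValueError("in_bin predicate requires a bin index")

    @property
    def column(self) -> str:
        """Design-matrix column name this predicate corresponds to."""
        if self.op == "eq":
            return f"{self.feature}={self.value}"
        return f"{self.feature}=bin{self.bin_index}"

    def sort_key(self) -> tuple:
        return (self.feature, self.op, str(self.value), -1 if self.bin_index is None else self.bin_index)

    def render(self) -> str:
        if self.op == "eq":
            return f"{self.feature} = {self.value}"
        lo = "-inf" if self.lo is None else f"{self.lo:g}"
        hi = "inf" if self.hi is None else f"{self.hi:g}"
        close = "]" if self.hi_closed else ")"
        return f"{self.feature} in [{lo}, {hi}{close}"

    def to_dict(self) -> dict:
        d = {"feature": self.feature, "op": self.op}
        if self.op == "eq":
            d["value"] = self.value
        else:
            d.update(bin_index=self.bin_index, lo=self.lo, hi=self.hi, hi_closed=self.hi_closed)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Predicate":
        return cls(**d)


@dataclass(frozen=True)
class Rule:
    """A non-empty conjunction of predicates, scoped to one BPA (or global).

    Predicates are kept in canonical order (sorted by feature name) so that
    syntactic deduplication is a set operation on canonical keys.
    """

    predicates: tuple[Predicate, ...]
    bpa_id: Optional[str] = None
    source: tuple[str, ...] = ()
    precision: Optional[float] = None
    coverage: Optional[float] = None
    #: boosting round weight (alpha) for rules emitted by the boosted rule set
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.predicates) == 0:
            raise ValueError("a rule requires at least one predicate")
        feats = [p.feature for p in self.predicates]
        if len(set(feats)) != len(feats):
            raise ValueError("at most one predicate per feature per rule")
        ordered = tuple(sorted(self.predicates, key=Predicate.sort_key))
        object.__setattr__(self, "predicates", ordered)
        for v, name in ((self.precision, "precision"), (self.coverage, "coverage")):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    def canonical_key(self) -> tuple:
        return (self.bpa_id, tuple(p.sort_key() + (str(p.value),) for p in self.predicates))

    def with_stats(self, precision: float, coverage: float) -> "Rule":
        return replace(self, precision=float(precision), coverage=float(coverage))

    def render(self) -> str:
        return " AND ".join(p.render() for p in self.predicates)

    def to_dict(self) -> dict:
        return {
            "bpa_id": self.bpa_id,
            "predicates": [p.to_dict() for p in self.predicates],
            "source": list(self.source),
            "precision": self.precision,
            "coverage": self.coverage,
            "weight": self.weight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        return cls(
            predicates=tuple(Predicate.from_dict(p) for p in d["predicates"]),
            bpa_id=d.get("bpa_id"),
            source=tuple(d.get("source", ())),
            precision=d.get("precision"),
            coverage=d.get("coverage"),
            weight=d.get("weight"),
        )


class RuleSet(Sequence):
    """An ordered collection of rules, deduplicated under canonical form.

    Adding a rule whose canonical form is already present merges the
    provenance sources instead of appending a duplicate.
    """

    def __init__(self, rules: Iterable[Rule] = ()) -> None:
        self._rules: list[Rule] = []
        self._index: dict[tuple, int] = {}
        for r in rules:
            self.add(r)

    def add(self, rule: Rule) -> None:
        key = rule.canonical_key()
        if key in self._index:
            i = self._index[key]
            old = self._rules[i]
            merged_sources = tuple(dict.fromkeys(old.source + rule.source))
            self._rules[i] = replace(old, source=merged_sources)
        else:
            self._index[key] = len(self._rules)
            self._rules.append(rule)

    def __len__(self) -> int:
        return len(self._rules)

    def __getitem__(self, i):
        return self._rules[i]

    def __iter__(self) -> Iterator[Rule]:
        return iter(self._rules)

    @property
    def rules(self) -> list[Rule]:
        return list(self._rules)

    def to_json(self, path=None) -> str:
        payload = json.dumps([r.to_dict() for r in self._rules], indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source: str) -> "RuleSet":
        try:
            data = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                data = json.load(fh)
        return cls(Rule.from_dict(d) for d in data)


def _predicate_mask(pred: Predicate, df: pd.DataFrame, schema) -> np.ndarray:
    """Boolean row mask of one predicate over a raw (unencoded) log."""
    if pred.feature not in df.columns:
        raise KeyError(f"feature {pred.feature!r} not present in the log")
    col = df[pred.feature]
    if pred.op == "eq":
        mask = col.astype("string") == pred.value
        return mask.fillna(False).to_numpy(dtype=bool)
    spec = schema.numeric[pred.feature]
    values = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    values = np.where(np.isnan(values), spec.impute_value, values)
    from .log import bin_numeric  # local import to avoid a cycle

    idx, _ = bin_numeric(values, edges=spec.edges)
    return idx == pred.bin_index


def rule_mask(rule: Rule, df: pd.DataFrame, schema) -> np.ndarray:
    """Rows of a raw log covered by ``rule``.

    If the rule is BPA-scoped and the log carries a ``bpa_id`` column, only
    rows of that BPA can be covered.
    """
    mask = np.ones(len(df), dtype=bool)
    if rule.bpa_id is not None and "bpa_id" in df.columns:
        mask &= (df["bpa_id"].astype(str) == str(rule.bpa_id)).to_numpy()
    for pred in rule.predicates:
        mask &= _predicate_mask(pred, df, schema)
    return mask


def merge_rules(*rulesets: Iterable[Rule], dm=None) -> RuleSet:
    """Union rule sets with syntactic and (optionally) semantic deduplication.

    Syntactic: identical canonical predicate sets within a scope collapse to
    one rule, provenance concatenated. Semantic (when a design matrix ``dm``
    is supplied): rules covering the *same* set of firings collapse to the
    shortest rule, ties broken by canonical order.
    """
    merged = RuleSet()
    for rs in rulesets:
        for r in rs:
            merged.add(r)
    if dm is None:
        return merged

    by_cover: dict[tuple, Rule] = {}
    order: list[tuple] = []
    for r in merged:
        cover = dm.mask_for_rule(r)
        key = (r.bpa_id, cover.tobytes())
        if key not in by_cover:
            by_cover[key] = r
            order.append(key)
        else:
            keep = by_cover[key]
            cand_sorted = sorted(
                [keep, r], key=lambda x: (len(x.predicates), x.canonical_key())
            )
            winner = cand_sorted[0]
            sources = tuple(dict.fromkeys(keep.source + r.source))
            by_cover[key] = replace(winner, source=sources)
    return RuleSet(by_cover[k] for k in order)
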