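"""Render selected rules as suggestions and quantify their predicted impact.

A selected rule becomes a human-readable exclusion suggestion
("Do not fire when: <feature> = <value> [AND ...]"). Applying the
suggestions to a log removes every firing covered by the union of a BPA's
suggestion rules; the impact report compares original and predicted firing
counts and acceptance rates per BPA, and a temporal holdout check re-matches
the suggestions against a later firing window to see whether the targeted
scenario still occurs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .log import ACCEPTED, FeatureSchema
from .metrics import RuleMetrics
from .rules import Rule, rule_mask

__all__ = [
    "Suggestion",
    "render_suggestion",
    "make_suggestions",
    "apply_suggestions",
    "impact_report",
    "temporal_holdout_check",
]


def render_suggestion(rule: Rule) -> str:
    """Template rendering: 'Do not fire when: <pred> AND <pred> ...'."""
    return "Do not fire when: " + rule.render()


@dataclass(frozen=True)
class Suggestion:
    bpa_id: str
    rule: Rule
    text: str
    metrics: Optional[RuleMetrics] = None

    def to_dict(self) -> dict:
        return {
            "bpa_id": self.bpa_id,
            "text": self.text,
            "rule": self.rule.to_dict(),
            "metrics": None if self.metrics is None else self.metrics.to_dict(),
        }


def make_suggestions(rules: Sequence[Rule], metrics: Optional[Sequence[RuleMetrics]] = None) -> list:
    out = []
    for i, rule in enumerate(rules):
        m = metrics[i] if metrics is not None else None
        out.append(Suggestion(bpa_id=rule.bpa_id, rule=rule, text=render_suggestion(rule), metrics=m))
    return out


def _union_mask(log: pd.DataFrame, suggestions: Sequence[Suggestion], schema: FeatureSchema) -> np.ndarray:
    mask = np.zeros(len(log), dtype=bool)
    for s in suggestions:
        mask |= rule_mask(s.rule, log, schema)
    return mask


def apply_suggestions(
    log: pd.DataFrame, suggestions: Sequence[Suggestion], schema: FeatureSchema
) -> pd.DataFrame:
    """Remove every firing covered by the union of its BPA's suggestion rules."""
    return log[~_union_mask(log, suggestions, schema)]


@dataclass
class ImpactReport:
    """Per-BPA before/after accounting plus unweighted dataset averages.

    ``relative_ar_change_printed`` recomputes the relative change from the
    two acceptance rates rounded to two decimals (report-table convention);
    ``relative_ar_change`` uses the raw rates.
    """

    per_bpa: pd.DataFrame
    average_decrease_pct: float
    average_relative_ar_change_pct: float

    def to_csv(self, path) -> None:
        self.per_bpa.to_csv(path, index=False)


def impact_report(
    log: pd.DataFrame, suggestions: Sequence[Suggestion], schema: FeatureSchema
) -> ImpactReport:
    """Original vs predicted firings and acceptance rates, per BPA.

    BPAs with no suggestions are included with zero eliminated firings.
    A BPA whose suggestions would remove every firing gets a null predicted
    acceptance rate. Dataset averages are unweighted means over the BPAs
    that carry at least one suggestion.
    """
    if "outcome" not in log.columns:
        raise KeyError("log requires derived outcomes")
    eliminated_mask = _union_mask(log, suggestions, schema)
    with_suggestions = {s.bpa_id for s in suggestions}

    rows = []
    for bpa, grp in log.groupby("bpa_id", sort=True):
        sub_elim = eliminated_mask[log["bpa_id"].to_numpy() == bpa]
        y = grp["outcome"].to_numpy()
        n_orig = len(grp)
        acc_orig = int((y == ACCEPTED).sum())
        n_elim = int(sub_elim.sum())
        n_pred = n_orig - n_elim
        acc_pred = acc_orig - int(((y == ACCEPTED) & sub_elim).sum())
        ar_orig = acc_orig / n_orig
        ar_pred = acc_pred / n_pred if n_pred > 0 else math.nan
        rel_raw = (ar_pred - ar_orig) / ar_orig if ar_orig > 0 and n_pred > 0 else math.nan
        r2o, r2p = round(ar_orig, 2), round(ar_pred, 2) if n_pred > 0 else math.nan
        rel_printed = (r2p - r2o) / r2o if n_pred > 0 and r2o > 0 else math.nan
        rows.append(
            {
                "bpa_id": bpa,
                "firings_original": n_orig,
                "ar_original": ar_orig,
                "firings_predicted": n_pred,
                "ar_predicted": ar_pred,
                "firings_eliminated": n_elim,
                "eliminated_pct": round(100.0 * n_elim / n_orig, 1),
                "relative_ar_change_pct": round(100.0 * rel_raw, 1) if not math.isnan(rel_raw) else math.nan,
                "relative_ar_change_printed_pct": round(100.0 * rel_printed, 1)
                if not math.isnan(rel_printed)
                else math.nan,
                "has_suggestions": bpa in with_suggestions,
            }
        )
    per_bpa = pd.DataFrame(rows)
    affected = per_bpa[per_bpa["has_suggestions"]]
    avg_dec = float(affected["eliminated_pct"].mean()) if len(affected) else 0.0
    avg_rel = float(affected["relative_ar_change_pct"].mean()) if len(affected) else 0.0
    return ImpactReport(
        per_bpa=per_bpa,
        average_decrease_pct=avg_dec,
        average_relative_ar_change_pct=avg_rel,
    )


def temporal_holdout_check(
    suggestions: Sequence[Suggestion], later_log: pd.DataFrame, schema: FeatureSchema
) -> pd.DataFrame:
    """Re-match suggestions against a later firing window.

    Per suggestion: ``bpa_retired`` when its BPA no longer fires at all,
    ``likely_implemented`` when the BPA fires but no firing matches the
    rule, else ``still_firing`` with the match count.
    """
    present = set(later_log["bpa_id"].astype(str).unique())
    rows = []
    for s in suggestions:
        if str(s.bpa_id) not in present:
            status, n = "bpa_retired", 0
        else:
            n = int(rule_mask(s.rule, later_log, schema).sum())
            status = "likely_implemented" if n == 0 else "still_firing"
        rows.append({"bpa_id": s.bpa_id, "suggestion": s.text, "matches": n, "status": status})
    return pd.DataFrame(rows)


def write_suggestions(suggestions: Sequence[Suggestion], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in suggestions], fh, indent=1, sort_keys=True)
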