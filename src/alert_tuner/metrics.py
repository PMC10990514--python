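"""Statistical screening of candidate rules on 2x2 contingency tables.

Each candidate rule is judged against its BPA's firing log through the
table

                covered (X)   uncovered (X-bar)
  not accepted       a              c
  accepted           b              d

and seven statistics: odds ratio ad/bc, a beta-binomial posterior
probability that the subgroup's acceptance rate is at most theta, the
decrease rate (a+b)/N (fraction of firings the suggestion removes),
confidence a/(a+b), interest (lift of non-acceptance), conviction, and a
Pearson chi-square p-value. A rule becomes a suggestion candidate only if
it clears every threshold simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .rules import Rule, RuleSet, rule_mask

__all__ = [
    "ContingencyTable",
    "RuleMetrics",
    "SelectionThresholds",
    "contingency",
    "compute_metrics",
    "prob_low_acceptance",
    "select_rules",
    "metrics_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # covered & not accepted
    b: int  # covered & accepted
    c: int  # uncovered & not accepted
    d: int  # uncovered & accepted

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {f.name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RuleMetrics:
    odds_ratio: float
    prob_low_acceptance: float
    theta: float
    decrease_rate: float
    confidence: float
    interest: float
    conviction: float
    chi2_p: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SelectionThresholds:
    """Pre-defined screens; a candidate must pass all of them (strictly)."""

    or_min: float = 1.25
    prob_low_min: float = 0.5
    low_acceptance_theta: float = 0.02
    decrease_max: float = 0.4
    confidence_min: float = 0.98
    interest_min: float = 1.0
    conviction_min: float = 1.2
    chi2_p_max: float = 0.01

    def passes(self, m: RuleMetrics) -> dict:
        return {
            "odds_ratio": m.odds_ratio > self.or_min,
            "prob_low_acceptance": m.prob_low_acceptance > self.prob_low_min,
            "decrease_rate": m.decrease_rate < self.decrease_max,
            "confidence": m.confidence > self.confidence_min,
            "interest": m.interest > self.interest_min,
            "conviction": m.conviction > self.conviction_min,
            "chi2_p": m.chi2_p < self.chi2_p_max,
        }


def contingency(rule: Rule, log: pd.DataFrame, schema) -> ContingencyTable:
    """Count the 2x2 cells of a rule over its BPA's firings.

    ``log`` must carry derived outcomes; rows are restricted to the rule's
    BPA before counting.
    """
    if "outcome" not in log.columns:
        raise KeyError("log requires derived outcomes")
    if rule.bpa_id is not None:
        log = log[log["bpa_id"].astype(str) == str(rule.bpa_id)]
    if len(log) == 0:
        raise ValueError(f"no firings for BPA {rule.bpa_id!r}")
    covered = rule_mask(rule, log, schema)
    y = log["outcome"].to_numpy()
    a = int(np.sum(covered & (y == 1)))
    b = int(np.sum(covered & (y == 0)))
    c = int(np.sum(~covered & (y == 1)))
    d = int(np.sum(~covered & (y == 0)))
    return ContingencyTable(a, b, c, d)


def prob_low_acceptance(a: int, b: int, theta: float) -> float:
    """Posterior P(acceptance rate <= theta) under a uniform Beta(1,1) prior.

    With a covered not-acceptances and b covered acceptances, the posterior
    of the acceptance rate is Beta(1+b, 1+a); the probability is the
    regularized incomplete beta function I_theta(1+b, 1+a).
    """
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must lie in (0, 1]")
    return float(stats.beta.cdf(theta, 1 + b, 1 + a))


def compute_metrics(
    t: ContingencyTable, theta: float = 0.02, yates_correction: bool = False
) -> RuleMetrics:
    """All seven screening statistics for one table.

    Zero-cell conventions: the odds ratio uses the Haldane-Anscombe +0.5
    adjustment on every cell when any cell is zero; confidence with b = 0 is
    exactly 1 and conviction is +inf; a degenerate table (an all-zero row or
    column) has chi-square p-value 1.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    if a + b == 0:
        raise ValueError("rule covers no firings (a + b = 0)")

    if min(a, b, c, d) == 0:
        odds_ratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds_ratio = (a * d) / (b * c)

    decrease_rate = (a + b) / n
    confidence = a / (a + b)
    interest = 0.0 if a == 0 else confidence / ((a + c) / n)
    conviction = math.inf if b == 0 else (a + b) * (b + d) / (n * b)

    table = np.array([[a, c], [b, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2_p = 1.0
    else:
        chi2_p = float(stats.chi2_contingency(table, correction=yates_correction).pvalue)

    return RuleMetrics(
        odds_ratio=float(odds_ratio),
        prob_low_acceptance=prob_low_acceptance(a, b, theta),
        theta=theta,
        decrease_rate=float(decrease_rate),
        confidence=float(confidence),
        interest=float(interest),
        conviction=float(conviction),
        chi2_p=chi2_p,
    )


def metrics_table(
    rules,
    log: pd.DataFrame,
    schema,
    thresholds: SelectionThresholds = SelectionThresholds(),
    yates_correction: bool = False,
) -> pd.DataFrame:
    """One row per rule: cells, the seven metrics, per-screen pass flags, selected flag."""
    rows = []
    for i, rule in enumerate(rules):
        t = contingency(rule, log, schema)
        if t.a + t.b == 0:
            continue
        m = compute_metrics(t, theta=thresholds.low_acceptance_theta, yates_correction=yates_correction)
        passes = thresholds.passes(m)
        row = {
            "rule_index": i,
            "bpa_id": rule.bpa_id,
            "rule": rule.render(),
            "source": "+".join(rule.source),
            "a": t.a,
            "b": t.b,
            "c": t.c,
            "d": t.d,
            **m.to_dict(),
        }
        row.update({f"pass_{k}": v for k, v in passes.items()})
        row["selected"] = all(passes.values())
        rows.append(row)
    return pd.DataFrame(rows)


def select_rules(
    rules,
    log: pd.DataFrame,
    schema,
    thresholds: SelectionThresholds = SelectionThresholds(),
    yates_correction: bool = False,
) -> RuleSet:
    """Keep the rules that pass the intersection of all seven screens."""
    selected = RuleSet()
    for rule in rules:
        t = contingency(rule, log, schema)
        if t.a + t.b == 0:
            continue
        m = compute_metrics(t, theta=thresholds.low_acceptance_theta, yates_correction=yates_correction)
        if all(thresholds.passes(m).values()):
            selected.add(rule)
    return selected
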