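"""Synthetic alert logs with planted low-acceptance subgroups.

Real alert-firing logs are protected health data, so every downstream stage
is exercised on simulated logs with known structure: each BPA fires many
times with a base acceptance rate drawn around the ~12% overall acceptance
typical of production alert systems, and selected BPAs carry *planted
rules* — feature-defined subgroups whose acceptance is far lower (the
ground-truth analogue of "hospice patients never accept the screening
alert"). Recovery of the planted rules is the headline evaluation.

Features are drawn independently per firing: categoricals uniform over
their vocabulary (re-weighted so a planted predicate's marginal equals its
target coverage), numerics from normal distributions with configurable
missingness. The generator algorithm is numpy's PCG64; the seed is
mandatory and a full config + seed reproduces the log byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .log import DEFAULT_NOT_ACCEPTED_LABELS, FeatureSchema
from .rules import Rule, rule_mask

__all__ = [
    "PlantedRule",
    "SimulationConfig",
    "simulate_alert_log",
    "recovery_score",
    "default_config",
]

_NOT_ACCEPTED_ACTIONS = sorted(DEFAULT_NOT_ACCEPTED_LABELS)
_ACCEPTED_ACTIONS = ["single order", "remove order set"]


@dataclass(frozen=True)
class PlantedRule:
    """Ground-truth subgroup: firings matching all predicates accept at
    ``subgroup_acceptance`` instead of the BPA's base rate.

    Predicates are (feature, value) for categoricals or (feature, (lo, hi))
    half-open intervals for numerics.
    """

    bpa_id: str
    predicates: tuple
    subgroup_acceptance: float
    target_coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.subgroup_acceptance <= 1.0:
            raise ValueError("subgroup_acceptance must lie in [0, 1]")
        if not 0.0 < self.target_coverage < 1.0:
            raise ValueError("target_coverage must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "bpa_id": self.bpa_id,
            "predicates": [list(p) for p in self.predicates],
            "subgroup_acceptance": self.subgroup_acceptance,
            "target_coverage": self.target_coverage,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedRule":
        preds = tuple(
            (f, tuple(v) if isinstance(v, (list, tuple)) else v) for f, v in d["predicates"]
        )
        return cls(d["bpa_id"], preds, d["subgroup_acceptance"], d["target_coverage"])


@dataclass
class SimulationConfig:
    """Study conditions for the simulated alert system.

    Defaults mirror the headline evaluation scenario: 5 BPAs firing 10 000
    times each, per-BPA base acceptance drawn from Beta(6, 44) (mean 0.12,
    matching the ~12% overall acceptance of production logs), 5 categorical
    features of cardinality 8 plus 3 numeric features with 5% missingness,
    and three planted single-predicate rules with coverages 0.05-0.15 and
    subgroup acceptance 0.01.
    """

    n_bpas: int = 5
    firings_per_bpa: tuple = (10_000, 10_000)  # inclusive range
    base_acceptance_beta: tuple = (6.0, 44.0)
    #: when set, every BPA uses this base acceptance instead of a Beta draw
    base_acceptance: Optional[float] = None
    n_categorical: int = 5
    categorical_cardinality: int = 8
    n_numeric: int = 3
    numeric_mean: float = 50.0
    numeric_sd: float = 15.0
    missingness: float = 0.05
    planted_rules: tuple = ()
    seed: Optional[int] = None
    generator: str = "numpy.PCG64"

    def feature_names(self) -> tuple[list, list]:
        cats = [f"cat_{i}" for i in range(self.n_categorical)]
        nums = [f"num_{i}" for i in range(self.n_numeric)]
        return cats, nums

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("simulation seed is mandatory")
        if not 0.0 <= self.missingness <= 1.0:
            raise ValueError("missingness must lie in [0, 1]")
        cats, nums = self.feature_names()
        known = set(cats) | set(nums)
        for pr in self.planted_rules:
            for feat, val in pr.predicates:
                if feat not in known:
                    raise KeyError(f"planted rule references unknown feature {feat!r}")
                if feat in cats and not isinstance(val, str):
                    raise ValueError(f"categorical planted predicate on {feat!r} needs a string value")
                if feat in nums and not (isinstance(val, tuple) and len(val) == 2):
                    raise ValueError(f"numeric planted predicate on {feat!r} needs an (lo, hi) interval")

    def to_dict(self) -> dict:
        d = {
            "n_bpas": self.n_bpas,
            "firings_per_bpa": list(self.firings_per_bpa),
            "base_acceptance_beta": list(self.base_acceptance_beta),
            "base_acceptance": self.base_acceptance,
            "n_categorical": self.n_categorical,
            "categorical_cardinality": self.categorical_cardinality,
            "n_numeric": self.n_numeric,
            "numeric_mean": self.numeric_mean,
            "numeric_sd": self.numeric_sd,
            "missingness": self.missingness,
            "planted_rules": [p.to_dict() for p in self.planted_rules],
            "seed": self.seed,
            "generator": self.generator,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["planted_rules"] = tuple(PlantedRule.from_dict(p) for p in d.get("planted_rules", ()))
        d["firings_per_bpa"] = tuple(d.get("firings_per_bpa", (10_000, 10_000)))
        d["base_acceptance_beta"] = tuple(d.get("base_acceptance_beta", (6.0, 44.0)))
        return cls(**d)


def default_config(seed: int) -> SimulationConfig:
    """The headline evaluation scenario with three planted rules."""
    planted = (
        PlantedRule("bpa_0", (("cat_0", "c0_v3"),), subgroup_acceptance=0.01, target_coverage=0.10),
        PlantedRule("bpa_1", (("cat_1", "c1_v5"),), subgroup_acceptance=0.01, target_coverage=0.05),
        PlantedRule("bpa_2", (("cat_2", "c2_v0"),), subgroup_acceptance=0.01, target_coverage=0.15),
    )
    return SimulationConfig(planted_rules=planted, seed=seed)


def _categorical_probs(config: SimulationConfig, bpa: str, feature: str) -> np.ndarray:
    """Vocabulary weights for one categorical feature within one BPA.

    Planted predicates on this feature pin their value's marginal to
    ``target_coverage ** (1/k)`` (k = predicates in the rule), so that under
    feature independence the rule's joint coverage equals its target.
    """
    card = config.categorical_cardinality
    probs = np.full(card, 1.0 / card)
    pinned = {}
    for pr in config.planted_rules:
        if pr.bpa_id != bpa:
            continue
        k = len(pr.predicates)
        for feat, val in pr.predicates:
            if feat == feature:
                pinned[val] = pr.target_coverage ** (1.0 / k)
    if not pinned:
        return probs
    fi = feature.split("_")[1]
    vocab = [f"c{fi}_v{j}" for j in range(card)]
    total_pinned = sum(pinned.values())
    if total_pinned >= 1.0:
        raise ValueError(f"pinned marginals on {feature!r} exceed 1")
    free = [v for v in vocab if v not in pinned]
    probs = np.empty(card)
    for j, v in enumerate(vocab):
        probs[j] = pinned.get(v, (1.0 - total_pinned) / len(free))
    return probs


def simulate_alert_log(config: SimulationConfig) -> tuple[pd.DataFrame, list]:
    """Draw an alert log and return (log, planted-rule ground truth).

    A firing covered by one or more planted rules draws its acceptance from
    the minimum covering subgroup_acceptance; otherwise from the BPA's base
    rate. Accepted firings get an accepting action label, others one of the
    standard overriding/dismissing labels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cats, nums = config.feature_names()

    frames = []
    t0 = pd.Timestamp("2019-01-01")
    horizon_s = int(pd.Timedelta(days=730).total_seconds())
    for b in range(config.n_bpas):
        bpa = f"bpa_{b}"
        lo, hi = config.firings_per_bpa
        n = int(rng.integers(lo, hi + 1))
        if config.base_acceptance is not None:
            base_acc = float(config.base_acceptance)
        else:
            base_acc = float(rng.beta(*config.base_acceptance_beta))
        rules_here = [pr for pr in config.planted_rules if pr.bpa_id == bpa]
        for pr in rules_here:
            if pr.subgroup_acceptance >= base_acc:
                raise ValueError(
                    f"planted subgroup acceptance {pr.subgroup_acceptance} is not below the "
                    f"base acceptance {base_acc:.3f} drawn for {bpa}"
                )

        data = {"bpa_id": np.full(n, bpa, dtype=object)}
        secs = np.sort(rng.integers(0, horizon_s, size=n))
        data["fired_at"] = [(t0 + pd.Timedelta(seconds=int(s))).isoformat() for s in secs]

        for feat in cats:
            fi = feat.split("_")[1]
            vocab = np.array([f"c{fi}_v{j}" for j in range(config.categorical_cardinality)], dtype=object)
            probs = _categorical_probs(config, bpa, feat)
            data[feat] = rng.choice(vocab, size=n, p=probs)
        for feat in nums:
            vals = rng.normal(config.numeric_mean, config.numeric_sd, size=n)
            interval = None
            for pr in rules_here:
                for f, v in pr.predicates:
                    if f == feat:
                        interval = (v, pr.target_coverage ** (1.0 / len(pr.predicates)))
            if interval is not None:
                (ilo, ihi), p_in = interval
                inside = rng.random(n) < p_in
                vals_in = rng.uniform(ilo, ihi, size=n)
                # resample draws that landed inside the planted interval
                out = vals.copy()
                bad = (out >= ilo) & (out < ihi)
                for _ in range(100):
                    if not bad.any():
                        break
                    out[bad] = rng.normal(config.numeric_mean, config.numeric_sd, size=int(bad.sum()))
                    bad = (out >= ilo) & (out < ihi)
                vals = np.where(inside, vals_in, out)
            if config.missingness > 0:
                miss = rng.random(n) < config.missingness
                vals = np.where(miss, np.nan, vals)
            data[feat] = vals

        df = pd.DataFrame(data)

        p_accept = np.full(n, base_acc)
        for pr in rules_here:
            covered = np.ones(n, dtype=bool)
            for feat, val in pr.predicates:
                if feat in cats:
                    covered &= (df[feat] == val).to_numpy()
                else:
                    v = df[feat].to_numpy(dtype=float)
                    covered &= ~np.isnan(v) & (v >= val[0]) & (v < val[1])
            p_accept = np.where(covered, np.minimum(p_accept, pr.subgroup_acceptance), p_accept)

        accepted = rng.random(n) < p_accept
        acc_actions = np.array(_ACCEPTED_ACTIONS, dtype=object)
        rej_actions = np.array(_NOT_ACCEPTED_ACTIONS, dtype=object)
        actions = np.where(
            accepted,
            acc_actions[rng.integers(0, len(acc_actions), size=n)],
            rej_actions[rng.integers(0, len(rej_actions), size=n)],
        )
        df["action"] = actions
        frames.append(df)

    log = pd.concat(frames, ignore_index=True)
    cols = ["bpa_id", "fired_at", "action"] + cats + nums
    return log[cols], list(config.planted_rules)


def _planted_mask(pr: PlantedRule, log: pd.DataFrame) -> np.ndarray:
    mask = (log["bpa_id"].astype(str) == pr.bpa_id).to_numpy()
    for feat, val in pr.predicates:
        col = log[feat]
        if isinstance(val, tuple):
            v = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            mask &= ~np.isnan(v) & (v >= val[0]) & (v < val[1])
        else:
            mask &= (col.astype("string") == val).fillna(False).to_numpy()
    return mask


def recovery_score(
    selected_rules: Sequence[Rule],
    truth: Sequence[PlantedRule],
    log: pd.DataFrame,
    schema: FeatureSchema,
    jaccard_threshold: float = 0.9,
) -> tuple[Optional[float], float]:
    """(precision, recall) of selected rules against the planted ground truth.

    A selected rule matches a planted rule when their covered firing sets
    overlap with Jaccard >= ``jaccard_threshold``. Precision is None when
    nothing was selected.
    """
    truth_masks = [_planted_mask(pr, log) for pr in truth]
    sel_masks = [rule_mask(r, log, schema) for r in selected_rules]

    def jaccard(m1, m2):
        inter = np.logical_and(m1, m2).sum()
        union = np.logical_or(m1, m2).sum()
        return 1.0 if union == 0 else inter / union

    matched_sel = np.zeros(len(sel_masks), dtype=bool)
    matched_truth = np.zeros(len(truth_masks), dtype=bool)
    for i, sm in enumerate(sel_masks):
        for j, tm in enumerate(truth_masks):
            if jaccard(sm, tm) >= jaccard_threshold:
                matched_sel[i] = True
                matched_truth[j] = True
    precision = None if len(sel_masks) == 0 else float(matched_sel.mean())
    recall = 0.0 if len(truth_masks) == 0 else float(matched_truth.mean())
    return precision, recall


def log_from_counts(
    bpa_id: str,
    n_firings: int,
    n_accepted: int,
    n_covered: int,
    n_covered_accepted: int,
    feature: str = "flag",
    value: str = "covered",
) -> pd.DataFrame:
    """Deterministic per-row log matching published aggregate counts.

    Builds one BPA's firings with exactly ``n_accepted`` acceptances
    overall, of which ``n_covered_accepted`` fall inside the subgroup of
    ``n_covered`` firings where ``feature == value`` — the shape needed to
    reproduce a report row (original/predicted firings and acceptance
    rates) from its printed inputs.
    """
    if not (0 <= n_covered_accepted <= min(n_covered, n_accepted)):
        raise ValueError("inconsistent counts")
    if n_covered > n_firings or n_accepted > n_firings:
        raise ValueError("inconsistent counts")
    covered = np.arange(n_firings) < n_covered
    accepted = np.zeros(n_firings, dtype=bool)
    accepted[:n_covered_accepted] = True
    accepted[n_covered : n_covered + (n_accepted - n_covered_accepted)] = True
    t0 = pd.Timestamp("2019-01-01")
    return pd.DataFrame(
        {
            "bpa_id": bpa_id,
            "fired_at": [(t0 + pd.Timedelta(minutes=i)).isoformat() for i in range(n_firings)],
            "action": np.where(accepted, "single order", "Acknowledge/override Warning"),
            feature: np.where(covered, value, "other"),
        }
    )


def write_truth(truth: Sequence[PlantedRule], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in truth], fh, indent=1, sort_keys=True)


def read_truth(path) -> list:
    with open(path) as fh:
        return [PlantedRule.from_dict(d) for d in json.load(fh)]
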