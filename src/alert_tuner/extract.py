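"""Candidate-rule extraction: three explainers over the encoded log.

Three complementary techniques propose IF-THEN rules for situations where
users do not accept an alert:

* **Ensemble path mining** (global): bagged shallow decision trees are
  grown on bootstrap samples; every root-to-leaf path predicting
  non-acceptance is screened by its precision on the out-of-bag rows,
  generalised to a minimal sufficient conjunction, and deduplicated.
* **Boosted rule set** (global): discrete AdaBoost over depth-limited tree
  stumps; each round re-weights rows by exponential loss and the
  non-accepted leaves of each weak learner are emitted as rules carrying
  the round's weight.
* **Anchors** (local): for an individual firing the model predicts as not
  accepted, a beam search over the firing's own feature values finds the
  smallest conjunction under which perturbed samples (anchored features
  fixed, the rest resampled from reference marginals) are still predicted
  not accepted with high precision.

All three operate on the binary one-hot design matrix, so every mined
condition decodes to an equals / in-bin predicate over a source feature.
Tree paths also contain *negated* conditions (one-hot column == 0); after
simplification, negations on two-valued features are rewritten to the
complementary positive predicate and rules still containing negations are
discarded, since an exclusion criterion must be a positive conjunction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .log import DesignMatrix, FeatureSchema, build_design_matrix
from .rules import Predicate, Rule, RuleSet, rule_mask

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleConfig",
    "BoostedConfig",
    "AnchorConfig",
    "AnchorResult",
    "extract_ensemble_rules",
    "fit_boosted_rule_set",
    "adaboost_rounds",
    "anchor_explain",
    "drop_redundant_conditions",
]


# --------------------------------------------------------------------------
# shared condition machinery: a mined condition is (column index, sign)
# --------------------------------------------------------------------------

def _cond_mask(conditions, X: np.ndarray) -> np.ndarray:
    mask = np.ones(X.shape[0], dtype=bool)
    for j, positive in conditions:
        mask &= (X[:, j] == 1) if positive else (X[:, j] == 0)
    return mask


def drop_redundant_conditions(conditions, X: np.ndarray):
    """Remove conditions whose removal leaves the covered set unchanged.

    This is the covered-set-preserving simplification: the returned
    conjunction covers exactly the same rows of ``X`` as the input.
    """
    conds = list(conditions)
    full = _cond_mask(conds, X)
    changed = True
    while changed and len(conds) > 1:
        changed = False
        for i in range(len(conds)):
            reduced = conds[:i] + conds[i + 1 :]
            if np.array_equal(_cond_mask(reduced, X), full):
                conds = reduced
                changed = True
                break
    return conds


def _feature_columns(dm: DesignMatrix) -> dict:
    by_feature: dict = {}
    for j, pred in enumerate(dm.predicates):
        by_feature.setdefault(pred.feature, []).append(j)
    return by_feature


def _conditions_to_rule(
    conditions,
    dm: DesignMatrix,
    bpa_id: Optional[str],
    source: str,
    weight: Optional[float] = None,
) -> Optional[Rule]:
    """Decode mined conditions into a Rule; None when not expressible.

    A negated condition on a feature with exactly two encoded values is
    rewritten to the complementary positive predicate; any other negation
    makes the conjunction inexpressible as a positive rule.
    """
    by_feature = _feature_columns(dm)
    preds: dict = {}
    for j, positive in conditions:
        pred = dm.predicates[j]
        if not positive:
            siblings = [k for k in by_feature[pred.feature] if k != j]
            if len(siblings) != 1:
                return None
            pred = dm.predicates[siblings[0]]
        if pred.feature in preds and preds[pred.feature] != pred:
            return None  # contradictory conditions on one feature
        preds[pred.feature] = pred
    if not preds:
        return None
    try:
        return Rule(
            predicates=tuple(preds.values()), bpa_id=bpa_id, source=(source,), weight=weight
        )
    except ValueError:
        return None


def _tree_class1_paths(tree: DecisionTreeClassifier):
    """Root-to-leaf condition lists for leaves predicting the positive class."""
    t = tree.tree_
    paths = []

    def walk(node, conds):
        if t.children_left[node] == -1:  # leaf
            counts = t.value[node][0]
            if counts[-1] > counts[0] if len(counts) > 1 else False:
                paths.append(list(conds))
            return
        j = int(t.feature[node])
        walk(t.children_left[node], conds + [(j, False)])
        walk(t.children_right[node], conds + [(j, True)])

    walk(0, [])
    return paths


# --------------------------------------------------------------------------
# ensemble path mining
# --------------------------------------------------------------------------

@dataclass
class EnsembleConfig:
    n_estimators: int = 30
    max_depth: int = 3
    min_oob_precision: float = 0.95
    min_coverage: float = 0.01
    seed: int = 0


def extract_ensemble_rules(
    dm: DesignMatrix, config: EnsembleConfig = EnsembleConfig(), bpa_id: Optional[str] = None
) -> RuleSet:
    """Mine non-acceptance rules from a bagged ensemble of shallow trees.

    Each tree is grown on a bootstrap sample; candidate paths predicting
    non-acceptance are kept only when their precision on out-of-bag rows
    reaches ``min_oob_precision`` with coverage at least ``min_coverage``.
    Kept paths are generalised (a predicate is pruned whenever the
    shortened rule still clears both out-of-bag thresholds), simplified
    without changing their covered set, and deduplicated. Stored precision
    and coverage are recomputed on all supplied rows.
    """
    if not 0.0 < config.min_oob_precision <= 1.0:
        raise ValueError("min_oob_precision must lie in (0, 1]")
    X, y = dm.X, np.asarray(dm.y)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes are required")
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)

    def oob_ok(conds, oob_idx):
        mask = _cond_mask(conds, X[oob_idx])
        covered = mask.sum()
        if covered == 0 or covered / len(oob_idx) < config.min_coverage:
            return False
        return y[oob_idx][mask].mean() >= config.min_oob_precision

    rules = RuleSet()
    for _ in range(config.n_estimators):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0:
            continue
        tree = DecisionTreeClassifier(
            max_depth=config.max_depth, random_state=int(rng.integers(2**31))
        )
        tree.fit(X[boot], y[boot])
        for conds in _tree_class1_paths(tree):
            if not oob_ok(conds, oob):
                continue
            # generalise: prune predicates while the out-of-bag screen still holds
            conds = sorted(conds, key=lambda c: dm.predicates[c[0]].sort_key())
            changed = True
            while changed and len(conds) > 1:
                changed = False
                for i in range(len(conds)):
                    reduced = conds[:i] + conds[i + 1 :]
                    if oob_ok(reduced, oob):
                        conds = reduced
                        changed = True
                        break
            conds = drop_redundant_conditions(conds, X)
            rule = _conditions_to_rule(conds, dm, bpa_id, "ensemble")
            if rule is None:
                continue
            mask = _cond_mask(conds, X)
            rules.add(rule.with_stats(precision=y[mask].mean(), coverage=mask.mean()))
    return rules


# --------------------------------------------------------------------------
# boosted rule set (discrete AdaBoost over tree stumps)
# --------------------------------------------------------------------------

@dataclass
class BoostedConfig:
    n_rounds: int = 10
    max_depth: int = 1
    seed: int = 0


def adaboost_rounds(X: np.ndarray, y: np.ndarray, config: BoostedConfig):
    """Run discrete AdaBoost; yields (learner, alpha, error, weights_before, weights_after).

    Stops early on a perfect weak learner or when a round is no better than
    chance. The weak learners are depth-limited decision trees fitted with
    the current sample weights.
    """
    n = X.shape[0]
    w = np.full(n, 1.0 / n)
    rounds = []
    for t in range(config.n_rounds):
        stump = DecisionTreeClassifier(max_depth=config.max_depth, random_state=config.seed + t)
        stump.fit(X, y, sample_weight=w)
        pred = stump.predict(X)
        miss = pred != y
        err = float(np.sum(w[miss]) / np.sum(w))
        if err >= 0.5:
            if t == 0:
                logger.warning("round-1 weak learner no better than chance; no boosted rules")
            break
        if err == 0.0:
            alpha = 10.0  # perfect separation: finite surrogate for log(inf)
            rounds.append((stump, alpha, err, w.copy(), w.copy()))
            break
        alpha = 0.5 * np.log((1.0 - err) / err)
        w_before = w.copy()
        w = w * np.exp(np.where(miss, alpha, -alpha))
        w = w / w.sum()
        rounds.append((stump, alpha, err, w_before, w.copy()))
    return rounds


def fit_boosted_rule_set(
    dm: DesignMatrix, config: BoostedConfig = BoostedConfig(), bpa_id: Optional[str] = None
) -> RuleSet:
    """Sequentially fit weighted tree stumps and emit their non-accepted leaves as rules."""
    X, y = dm.X, np.asarray(dm.y)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes are required")
    rules = RuleSet()
    for stump, alpha, _err, _wb, _wa in adaboost_rounds(X, y, config):
        for conds in _tree_class1_paths(stump):
            conds = drop_redundant_conditions(
                sorted(conds, key=lambda c: dm.predicates[c[0]].sort_key()), X
            )
            rule = _conditions_to_rule(conds, dm, bpa_id, "boosted", weight=float(alpha))
            if rule is None:
                continue
            mask = _cond_mask(conds, X)
            if mask.sum() == 0:
                continue
            rules.add(rule.with_stats(precision=y[mask].mean(), coverage=mask.mean()))
    return rules


# --------------------------------------------------------------------------
# anchor-style local explanations
# --------------------------------------------------------------------------

@dataclass
class AnchorConfig:
    precision_threshold: float = 0.95
    beam_width: int = 3
    max_predicates: int = 4
    n_samples: int = 500
    seed: int = 0
    excluded_features: tuple = ()


@dataclass
class AnchorResult:
    status: str  # "found" | "empty_anchor" | "not_found"
    rule: Optional[Rule]
    precision: float
    coverage: Optional[float] = None


def anchor_explain(
    model,
    instance: pd.Series,
    reference_data: pd.DataFrame,
    schema: FeatureSchema,
    config: AnchorConfig = AnchorConfig(),
    bpa_id: Optional[str] = None,
) -> AnchorResult:
    """Find the smallest high-precision anchor for one non-accepted firing.

    Precision of a candidate anchor is the fraction of perturbed samples
    the model still labels not-accepted, where anchored features are fixed
    to the instance's values and every other feature is resampled
    independently from the reference data's marginals. If the empty anchor
    already reaches the threshold (the model predicts non-acceptance
    regardless of features), the result is ``empty_anchor``; if no
    conjunction within ``max_predicates`` reaches it, ``not_found``.
    """
    rng = np.random.default_rng(config.seed)
    tau = config.precision_threshold
    features = [f for f in schema.features if f not in config.excluded_features]

    inst_df = instance.to_frame().T
    X_inst = build_design_matrix(inst_df[schema.features], schema).X
    if model.predict(X_inst)[0] != 1:
        raise ValueError("anchors are defined for instances predicted not-accepted")

    candidates = []
    for f in features:
        v = instance[f]
        if pd.isna(v):
            continue
        candidates.append(schema.predicate_for(f, v))

    ref = reference_data.reset_index(drop=True)
    n_ref = len(ref)

    def perturbed_precision(anchor: tuple) -> float:
        cols = {}
        for f in schema.features:
            pos = rng.integers(0, n_ref, size=config.n_samples)
            cols[f] = ref[f].to_numpy()[pos]
        pert = pd.DataFrame(cols)
        for p in anchor:
            f = p.feature
            if p.op == "eq":
                pert[f] = p.value
            else:
                pert[f] = float(instance[f])
        Xp = build_design_matrix(pert[schema.features], schema).X
        return float(model.predict(Xp).mean())

    def anchor_coverage(anchor: tuple) -> float:
        mask = np.ones(n_ref, dtype=bool)
        for p in anchor:
            tmp_rule = Rule(predicates=(p,))
            mask &= rule_mask(tmp_rule, ref, schema)
        return float(mask.mean())

    cache: dict = {}

    def precision_of(anchor: tuple) -> float:
        key = tuple(sorted(p.column for p in anchor))
        if key not in cache:
            cache[key] = perturbed_precision(anchor)
        return cache[key]

    p0 = precision_of(())
    if p0 >= tau:
        return AnchorResult(status="empty_anchor", rule=None, precision=p0)

    beam = [()]
    max_k = min(config.max_predicates, len(candidates))
    for _size in range(1, max_k + 1):
        scored = []
        seen = set()
        for anchor in beam:
            used = {p.feature for p in anchor}
            for p in candidates:
                if p.feature in used:
                    continue
                new = tuple(sorted(anchor + (p,), key=Predicate.sort_key))
                key = tuple(q.column for q in new)
                if key in seen:
                    continue
                seen.add(key)
                scored.append((new, precision_of(new)))
        if not scored:
            break
        winners = [(a, pr, anchor_coverage(a)) for a, pr in scored if pr >= tau]
        if winners:
            winners.sort(key=lambda apc: (-apc[2], tuple(q.column for q in apc[0])))
            anchor, prec, cov = winners[0]
            rule = Rule(predicates=anchor, bpa_id=bpa_id, source=("anchor",))
            return AnchorResult(status="found", rule=rule, precision=prec, coverage=cov)
        scored.sort(key=lambda ap: (-ap[1], tuple(q.column for q in ap[0])))
        beam = [a for a, _ in scored[: config.beam_width]]
    return AnchorResult(status="not_found", rule=None, precision=max(cache.values()))
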