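"""Stage functions shared by the Model facade and the CLI.

Each stage is a pure function over in-memory objects; the CLI adds artifact
reading/writing around them, and ``AlertNonAcceptanceModel.fit`` chains them
in memory. Sub-seeds for the stochastic stages are derived from the single
pipeline seed via numpy's SeedSequence so that every stage is independently
replayable.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import extract as ex
from .classify import FiringModel, evaluate_classifier, train_classifier
from .config import PipelineConfig
from .log import (
    FeatureSchema,
    ResponseMapping,
    build_design_matrix,
    derive_outcomes,
    filter_alerts,
)
from .metrics import RuleMetrics, SelectionThresholds, metrics_table
from .rules import Rule, RuleSet, merge_rules
from .suggest import impact_report, make_suggestions

logger = logging.getLogger(__name__)

#: the BPA identity is copied into this feature column so the global model
#: can condition on it; it is excluded from anchor predicates (rule scope
#: already pins the BPA).
BPA_FEATURE = "bpa"


def stage_seeds(seed: int, n: int = 8) -> list:
    """Derive per-stage integer seeds (< 2**31) from the pipeline seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def preprocess(
    log: pd.DataFrame,
    config: PipelineConfig,
    mapping: ResponseMapping = ResponseMapping(),
):
    """Outcomes, alert-level filtering, train/test split, schema fit on train.

    Returns (filtered_log, schema, train_positions, test_positions); the
    filtered log has a fresh 0..n-1 index and an added BPA feature column.
    """
    pre = config.preprocessing
    if "outcome" not in log.columns:
        log = derive_outcomes(log, mapping)
    filtered = filter_alerts(log, pre.min_firings, pre.min_acceptances).reset_index(drop=True)
    if filtered.empty:
        raise ValueError("alert-level filtering removed every firing; nothing to analyse")
    filtered = filtered.copy()
    filtered[BPA_FEATURE] = filtered["bpa_id"].astype(str)

    cls = config.classifier
    n = len(filtered)
    if cls.temporal_split:
        order = np.argsort(filtered["fired_at"].to_numpy(), kind="stable")
        cut = int(round(n * (1.0 - cls.test_size)))
        train_pos, test_pos = np.sort(order[:cut]), np.sort(order[cut:])
    else:
        train_pos, test_pos = train_test_split(
            np.arange(n),
            test_size=cls.test_size,
            stratify=filtered["outcome"].to_numpy(),
            random_state=stage_seeds(config.seed)[0],
        )
        train_pos, test_pos = np.sort(train_pos), np.sort(test_pos)

    schema = FeatureSchema.fit(
        filtered.iloc[train_pos],
        n_bins=pre.n_bins,
        impute_strategy=pre.impute_strategy,
    )
    return filtered, schema, train_pos, test_pos


def train(
    filtered: pd.DataFrame,
    schema: FeatureSchema,
    train_pos: np.ndarray,
    test_pos: np.ndarray,
    config: PipelineConfig,
):
    """Fit the global non-acceptance classifier; evaluate on the held-out rows."""
    seeds = stage_seeds(config.seed)
    dm_train = build_design_matrix(filtered.iloc[train_pos], schema)
    dm_test = build_design_matrix(filtered.iloc[test_pos], schema)
    model = train_classifier(
        dm_train,
        family=config.classifier.family,
        search_budget=config.classifier.search_budget,
        seed=seeds[1],
    )
    eval_metrics = evaluate_classifier(
        model, dm_test, n_bootstrap=config.classifier.n_bootstrap, seed=seeds[2]
    )
    return model, eval_metrics


def _strip_bpa_predicates(rule: Rule) -> Optional[Rule]:
    preds = tuple(p for p in rule.predicates if p.feature != BPA_FEATURE)
    if not preds:
        return None
    if len(preds) == len(rule.predicates):
        return rule
    return Rule(
        predicates=preds,
        bpa_id=rule.bpa_id,
        source=rule.source,
        precision=rule.precision,
        coverage=rule.coverage,
        weight=rule.weight,
    )


def explain(
    filtered: pd.DataFrame,
    schema: FeatureSchema,
    train_pos: np.ndarray,
    model: FiringModel,
    config: PipelineConfig,
) -> RuleSet:
    """Run the three explainers per BPA on training rows; merge and deduplicate.

    The ensemble and boosted miners run on each BPA's own training rows;
    anchors explain a seeded sample of firings the global model predicts as
    not accepted, perturbing within the BPA's reference distribution.
    Semantic duplicates (identical covered sets on the full log) collapse
    to the shortest rule.
    """
    seeds = stage_seeds(config.seed)
    train_df = filtered.iloc[train_pos].reset_index(drop=True)
    dm_train = build_design_matrix(train_df, schema)
    rulesets = []
    bpas = sorted(train_df["bpa_id"].astype(str).unique())
    anchor_rng = np.random.default_rng(seeds[3])

    proba_all = model.predict(dm_train.X) if config.anchor.enabled else None

    for k, bpa in enumerate(bpas):
        bpa_mask = dm_train.bpa_ids == bpa
        sub = dm_train.subset(bpa_mask)
        if len(np.unique(sub.y)) < 2:
            logger.warning("BPA %s has a single outcome class; skipping rule mining", bpa)
            continue
        rulesets.append(
            ex.extract_ensemble_rules(sub, config.ensemble.build(seed=seeds[4] + k), bpa_id=bpa)
        )
        rulesets.append(
            ex.fit_boosted_rule_set(sub, config.boosted.build(seed=seeds[5] + k), bpa_id=bpa)
        )
        if config.anchor.enabled:
            ref = train_df.loc[bpa_mask].reset_index(drop=True)
            positives = np.flatnonzero(bpa_mask & (proba_all == 1))
            if len(positives) == 0:
                continue
            n_pick = min(config.anchor.n_instances_per_bpa, len(positives))
            picks = anchor_rng.choice(positives, size=n_pick, replace=False)
            anchors = RuleSet()
            for i, row in enumerate(np.sort(picks)):
                res = ex.anchor_explain(
                    model,
                    train_df.loc[row, schema.features],
                    ref[schema.features],
                    schema,
                    config.anchor.build(
                        seed=(seeds[6] + 1000 * k + i) % (2**31),
                        excluded_features=(BPA_FEATURE,),
                    ),
                    bpa_id=bpa,
                )
                if res.rule is not None:
                    stripped = _strip_bpa_predicates(res.rule)
                    if stripped is not None:
                        mask = dm_train.mask_for_rule(stripped)
                        if mask.any():
                            anchors.add(
                                stripped.with_stats(
                                    precision=float(dm_train.y[mask].mean()),
                                    coverage=float(mask[bpa_mask].mean()),
                                )
                            )
            rulesets.append(anchors)

    dm_full = build_design_matrix(filtered, schema)
    return merge_rules(*rulesets, dm=dm_full)


def select(
    candidates: Sequence[Rule],
    filtered: pd.DataFrame,
    schema: FeatureSchema,
    thresholds: SelectionThresholds,
    yates_correction: bool = False,
):
    """Score all candidates on the full filtered log and apply the screens."""
    table = metrics_table(candidates, filtered, schema, thresholds, yates_correction)
    selected = RuleSet()
    sel_metrics = []
    if len(table):
        for _, row in table[table["selected"]].iterrows():
            selected.add(candidates[int(row["rule_index"])])
            sel_metrics.append(
                RuleMetrics(
                    odds_ratio=row["odds_ratio"],
                    prob_low_acceptance=row["prob_low_acceptance"],
                    theta=row["theta"],
                    decrease_rate=row["decrease_rate"],
                    confidence=row["confidence"],
                    interest=row["interest"],
                    conviction=row["conviction"],
                    chi2_p=row["chi2_p"],
                )
            )
    return table, selected, sel_metrics


def report(
    filtered: pd.DataFrame,
    schema: FeatureSchema,
    selected: Sequence[Rule],
    sel_metrics: Optional[Sequence[RuleMetrics]] = None,
):
    """Render suggestions and compute the per-BPA impact report."""
    suggestions = make_suggestions(list(selected), sel_metrics if sel_metrics else None)
    impact = impact_report(filtered, suggestions, schema)
    return suggestions, impact
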