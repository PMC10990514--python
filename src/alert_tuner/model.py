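"""Model/Results facade for the whole alert-optimisation analysis.

``AlertNonAcceptanceModel`` wraps an alert-firing log (one row per firing:
``bpa_id``, ``fired_at``, ``action``, feature columns); ``fit()`` runs the
full analysis — outcome derivation, alert filtering, encoding, classifier
training, rule extraction, statistical screening — and returns an
``AlertOptimizationResults`` carrying the fitted classifier with its
held-out metrics, the candidate and selected rules, the rendered
suggestions, and the predicted impact, with a ``summary()`` table.

>>> from alert_tuner import AlertNonAcceptanceModel
>>> res = AlertNonAcceptanceModel.from_dataframe(log, seed=7).fit()
>>> print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import pipeline
from .classify import EvalMetrics, FiringModel
from .config import PipelineConfig
from .log import ACCEPTED, FeatureSchema, ResponseMapping, read_log
from .metrics import RuleMetrics
from .rules import RuleSet
from .suggest import ImpactReport, Suggestion, write_suggestions

__all__ = ["AlertNonAcceptanceModel", "AlertOptimizationResults"]


class AlertNonAcceptanceModel:
    """End-to-end model of alert non-acceptance fitted from a firing log."""

    def __init__(
        self,
        log: pd.DataFrame,
        config: Optional[PipelineConfig] = None,
        seed: Optional[int] = None,
        mapping: ResponseMapping = ResponseMapping(),
    ) -> None:
        if config is None:
            if seed is None:
                raise ValueError("provide a PipelineConfig or an explicit seed")
            config = PipelineConfig(seed=seed)
        elif seed is not None:
            config = config.model_copy(update={"seed": seed})
        required = {"bpa_id", "action"}
        missing = required - set(log.columns)
        if missing and "outcome" not in log.columns:
            raise KeyError(f"log is missing required columns: {sorted(missing)}")
        self.log = log
        self.config = config
        self.mapping = mapping

    @classmethod
    def from_dataframe(cls, log: pd.DataFrame, seed: int, config: Optional[PipelineConfig] = None):
        return cls(log, config=config, seed=seed)

    @classmethod
    def from_file(cls, path, seed: int, config: Optional[PipelineConfig] = None):
        return cls(read_log(path), config=config, seed=seed)

    def fit(self) -> "AlertOptimizationResults":
        cfg = self.config
        filtered, schema, train_pos, test_pos = pipeline.preprocess(self.log, cfg, self.mapping)
        firing_model, eval_metrics = pipeline.train(filtered, schema, train_pos, test_pos, cfg)
        candidates = pipeline.explain(filtered, schema, train_pos, firing_model, cfg)
        table, selected, sel_metrics = pipeline.select(
            candidates, filtered, schema, cfg.thresholds.build()
        )
        suggestions, impact = pipeline.report(filtered, schema, selected, sel_metrics)
        return AlertOptimizationResults(
            model=self,
            log=filtered,
            schema=schema,
            train_positions=train_pos,
            test_positions=test_pos,
            classifier=firing_model,
            classifier_metrics=eval_metrics,
            candidate_rules=candidates,
            rule_metrics=table,
            selected_rules=selected,
            selected_metrics=sel_metrics,
            suggestions=suggestions,
            impact=impact,
        )


@dataclass
class AlertOptimizationResults:
    """Everything a fitted run produced."""

    model: AlertNonAcceptanceModel
    log: pd.DataFrame
    schema: FeatureSchema
    train_positions: np.ndarray
    test_positions: np.ndarray
    classifier: FiringModel
    classifier_metrics: EvalMetrics
    candidate_rules: RuleSet
    rule_metrics: pd.DataFrame
    selected_rules: RuleSet
    selected_metrics: Sequence[RuleMetrics]
    suggestions: Sequence[Suggestion]
    impact: ImpactReport

    @property
    def n_firings(self) -> int:
        return len(self.log)

    @property
    def n_bpas(self) -> int:
        return int(self.log["bpa_id"].nunique())

    @property
    def acceptance_rate(self) -> float:
        return float((self.log["outcome"] == ACCEPTED).mean())

    def summary(self) -> str:
        cm = self.classifier_metrics
        lines = [
            "Alert non-acceptance analysis",
            "=" * 64,
            f"Firings (after filtering): {self.n_firings:>12,}",
            f"BPAs retained:             {self.n_bpas:>12,}",
            f"Overall acceptance rate:   {self.acceptance_rate:>12.3f}",
            "-" * 64,
            f"Classifier: {self.classifier.family}",
        ]
        for name in ("sensitivity", "precision", "f1", "accuracy", "auc"):
            pt, lo, hi = getattr(cm, name)
            lines.append(f"  {name:<12} {pt:0.3f} [{lo:0.3f}, {hi:0.3f}]")
        lines += [
            "-" * 64,
            f"Candidate rules:           {len(self.candidate_rules):>12,}",
            f"Selected suggestions:      {len(self.selected_rules):>12,}",
            f"Avg firing decrease (%):   {self.impact.average_decrease_pct:>12.1f}",
            f"Avg relative AR change (%):{self.impact.average_relative_ar_change_pct:>12.1f}",
            "=" * 64,
        ]
        for s in self.suggestions:
            lines.append(f"[{s.bpa_id}] {s.text}")
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write the run's artifacts (JSON/CSV) into a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "metrics.json", "w") as fh:
            json.dump(self.classifier_metrics.to_dict(), fh, indent=1, sort_keys=True)
        self.candidate_rules.to_json(out / "rules.json")
        self.rule_metrics.to_csv(out / "rule_metrics.csv", index=False)
        self.selected_rules.to_json(out / "selected_rules.json")
        write_suggestions(self.suggestions, out / "suggestions.json")
        self.impact.to_csv(out / "impact_report.csv")
        self.schema.to_json(out / "schema.json")
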