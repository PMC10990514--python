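"""Non-acceptance classifiers over encoded alert logs.

A single global model is trained to predict the probability that a firing
will *not* be accepted (positive class = not accepted), with the BPA
identity one-hot among the features. Four families are supported —
gradient-boosted trees (LightGBM), random forest, a small feed-forward
neural network, and a support vector machine — with hyperparameters chosen
by seeded random search maximising validation AUC within a fixed budget.
The fitted model anchors the local explanations and can supply tree
structures to the global rule miners.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = ["FiringModel", "EvalMetrics", "train_classifier", "evaluate_classifier"]

FAMILIES = (
    "gradient_boosted_trees",
    "random_forest",
    "neural_network",
    "support_vector_machine",
)


@dataclass
class FiringModel:
    """A fitted non-acceptance model with a fixed feature order."""

    family: str
    estimator: object
    feature_names: list

    def predict_proba(self, X) -> np.ndarray:
        """P(not accepted) per row."""
        import pandas as pd

        X = np.asarray(X, dtype=np.float32)
        # estimators are fitted on positional names: design-matrix column
        # names may contain characters the boosters mangle
        frame = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
        proba = self.estimator.predict_proba(frame)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1)]

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(np.int8)

    @property
    def is_tree_family(self) -> bool:
        return self.family in ("gradient_boosted_trees", "random_forest")

    def tree_structures(self):
        """Introspectable trees: sklearn trees for forests, the booster dump
        (split feature / threshold / children / leaf values) for LightGBM."""
        if self.family == "random_forest":
            return list(self.estimator.estimators_)
        if self.family == "gradient_boosted_trees":
            return self.estimator.booster_.dump_model()["tree_info"]
        raise AttributeError(f"{self.family} exposes no tree structures")


def _param_space(family: str, rng: np.random.Generator, n_rows: int) -> dict:
    if family == "gradient_boosted_trees":
        return {
            "n_estimators": int(rng.choice([100, 200, 400])),
            "learning_rate": float(rng.choice([0.03, 0.1, 0.2])),
            "num_leaves": int(rng.choice([15, 31, 63])),
            "min_child_samples": int(rng.choice([10, 20, 50])),
        }
    if family == "random_forest":
        return {
            "n_estimators": int(rng.choice([100, 200, 400])),
            "max_depth": int(rng.choice([6, 10, 16])),
            "min_samples_leaf": int(rng.choice([1, 5, 20])),
        }
    if family == "neural_network":
        layouts = [(32,), (64,), (64, 32)]
        return {
            "hidden_layer_sizes": layouts[int(rng.integers(len(layouts)))],
            "alpha": float(rng.choice([1e-4, 1e-3, 1e-2])),
            "learning_rate_init": float(rng.choice([1e-3, 3e-3])),
        }
    if family == "support_vector_machine":
        return {
            "C": float(rng.choice([0.1, 1.0, 10.0])),
            "gamma": rng.choice(["scale", "auto"]),
        }
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def _build(family: str, params: dict, seed: int):
    if family == "gradient_boosted_trees":
        import lightgbm as lgb

        return lgb.LGBMClassifier(
            objective="binary",
            random_state=seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
            **params,
        )
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "neural_network":
        params = dict(params)
        params["hidden_layer_sizes"] = tuple(int(h) for h in params["hidden_layer_sizes"])
        return MLPClassifier(random_state=seed, max_iter=300, **params)
    if family == "support_vector_machine":
        return SVC(probability=True, random_state=seed, **params)
    raise ValueError(f"unknown family {family!r}")


def train_classifier(
    dm,
    family: str = "gradient_boosted_trees",
    search_budget: int = 8,
    seed: int = 0,
    validation_fraction: float = 0.2,
) -> FiringModel:
    """Fit a family's model, tuning hyperparameters by seeded random search.

    ``search_budget`` configurations are sampled; each is fitted on an inner
    stratified training split and scored by AUC on the inner validation
    split; the best configuration is refitted on all supplied rows.
    """
    import pandas as pd

    X = pd.DataFrame(
        np.asarray(dm.X, dtype=np.float32), columns=[f"f{j}" for j in range(dm.X.shape[1])]
    )
    y = np.asarray(dm.y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(seed)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=validation_fraction, stratify=y, random_state=seed % (2**31)
    )
    best_auc, best_params = -np.inf, None
    for k in range(max(1, search_budget)):
        params = _param_space(family, rng, len(X_tr))
        est = _build(family, params, seed=seed)
        est.fit(X_tr, y_tr)
        proba = est.predict_proba(X_val)[:, list(est.classes_).index(1)]
        auc = roc_auc_score(y_val, proba)
        logger.debug("search %d/%d %s AUC=%.4f %s", k + 1, search_budget, family, auc, params)
        if auc > best_auc:
            best_auc, best_params = auc, params
    est = _build(family, best_params, seed=seed)
    est.fit(X, y)
    logger.info("trained %s (validation AUC %.4f, params %s)", family, best_auc, best_params)
    return FiringModel(family=family, estimator=est, feature_names=list(dm.columns))


@dataclass
class EvalMetrics:
    """Threshold-at-0.5 metrics plus AUC, each with a percentile-bootstrap 95% CI."""

    sensitivity: tuple
    precision: tuple
    f1: tuple
    accuracy: tuple
    auc: tuple

    def to_dict(self) -> dict:
        return {
            k: {"point": v[0], "ci_low": v[1], "ci_high": v[2]}
            for k, v in self.__dict__.items()
        }


def _point_metrics(y, proba, threshold=0.5):
    pred = proba >= threshold
    tp = np.sum(pred & (y == 1))
    fp = np.sum(pred & (y == 0))
    fn = np.sum(~pred & (y == 1))
    tn = np.sum(~pred & (y == 0))
    sens = tp / (tp + fn) if tp + fn else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) and not np.isnan(prec + sens) else np.nan
    acc = (tp + tn) / len(y)
    auc = roc_auc_score(y, proba) if len(np.unique(y)) == 2 else np.nan
    return np.array([sens, prec, f1, acc, auc])


def evaluate_classifier(
    model: FiringModel,
    dm,
    n_bootstrap: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalMetrics:
    """Held-out evaluation with percentile-bootstrap intervals over rows."""
    X, y = np.asarray(dm.X, dtype=np.float32), np.asarray(dm.y)
    if (y == 1).sum() == 0:
        raise ValueError("no positive (not-accepted) labels: sensitivity undefined")
    proba = model.predict_proba(X)
    point = _point_metrics(y, proba, threshold)
    rng = np.random.default_rng(seed)
    n = len(y)
    reps = np.empty((n_bootstrap, 5))
    for i in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        reps[i] = _point_metrics(y[idx], proba[idx], threshold)
    with warnings.catch_warnings():
        # a metric undefined in every replicate (e.g. F1 of a predictor that
        # never fires) propagates as NaN rather than warning
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(reps, 2.5, axis=0)
        hi = np.nanpercentile(reps, 97.5, axis=0)
    vals = [
        (float(point[j]), float(lo[j]), float(hi[j])) for j in range(5)
    ]
    return EvalMetrics(
        sensitivity=vals[0], precision=vals[1], f1=vals[2], accuracy=vals[3], auc=vals[4]
    )
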