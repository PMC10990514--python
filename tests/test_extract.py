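import numpy as np
import pandas as pd
import pytest

from alert_tuner import (
    AnchorConfig,
    BoostedConfig,
    EnsembleConfig,
    FeatureSchema,
    Predicate,
    Rule,
    RuleSet,
    anchor_explain,
    build_design_matrix,
    derive_outcomes,
    extract_ensemble_rules,
    fit_boosted_rule_set,
    merge_rules,
)
from alert_tuner.extract import _cond_mask, adaboost_rounds, drop_redundant_conditions


def brute_force_single_predicate_rules(dm, min_precision, min_coverage):
    """Oracle: exhaustive search over all single-column positive rules."""
    hits = []
    for j in range(dm.X.shape[1]):
        mask = dm.X[:, j] == 1
        if mask.mean() < min_coverage or mask.sum() == 0:
            continue
        if dm.y[mask].mean() >= min_precision:
            hits.append((j, mask))
    return hits


def test_ensemble_recovers_planted_perfect_rule(perfect_dm):
    dm, schema = perfect_dm
    config = EnsembleConfig(n_estimators=20, max_depth=3, seed=0)
    rules = extract_ensemble_rules(dm, config, bpa_id="bpa_0")
    oracle = brute_force_single_predicate_rules(dm, config.min_oob_precision, config.min_coverage)
    assert len(oracle) == 1  # only dept=X is a perfect single-predicate rule
    _, oracle_mask = oracle[0]
    assert any(
        np.array_equal(dm.mask_for_rule(r), oracle_mask) for r in rules
    ), [r.render() for r in rules]


def test_ensemble_emits_nothing_on_noise():
    """Random labels leave no path with out-of-bag precision near 1."""
    rng = np.random.default_rng(2)
    log = derive_outcomes(
        pd.DataFrame(
            {
                "bpa_id": "b",
                "action": rng.choice(["Cancel BPA", "single order"], size=2000),
                "f1": rng.choice(list("abcd"), size=2000),
                "f2": rng.choice(list("wxyz"), size=2000),
            }
        )
    )
    dm = build_design_matrix(log, FeatureSchema.fit(log))
    rules = extract_ensemble_rules(dm, EnsembleConfig(n_estimators=20, seed=3))
    assert len(rules) == 0


def test_ensemble_rules_self_consistent(perfect_dm):
    """Stored precision/coverage match a recomputation from the covered set."""
    dm, _ = perfect_dm
    rules = extract_ensemble_rules(dm, EnsembleConfig(n_estimators=10, seed=1), bpa_id="bpa_0")
    assert len(rules) > 0
    for r in rules:
        mask = dm.mask_for_rule(r)
        assert r.precision == pytest.approx(dm.y[mask].mean())
        assert r.coverage == pytest.approx(mask.mean())


def test_ensemble_output_deduplicated(perfect_dm):
    dm, _ = perfect_dm
    rules = extract_ensemble_rules(dm, EnsembleConfig(n_estimators=25, seed=4))
    keys = [r.canonical_key() for r in rules]
    assert len(keys) == len(set(keys))


def test_invalid_oob_precision_rejected(perfect_dm):
    dm, _ = perfect_dm
    with pytest.raises(ValueError):
        extract_ensemble_rules(dm, EnsembleConfig(min_oob_precision=1.5))


def test_simplification_preserves_covered_set(perfect_dm):
    dm, _ = perfect_dm
    rng = np.random.default_rng(7)
    for _ in range(30):
        conds = [
            (int(j), bool(rng.integers(2))) for j in rng.choice(dm.X.shape[1], size=3, replace=False)
        ]
        reduced = drop_redundant_conditions(conds, dm.X)
        assert np.array_equal(_cond_mask(reduced, dm.X), _cond_mask(conds, dm.X))
        assert len(reduced) <= len(conds)


# --- boosted rule set --------------------------------------------------------

def test_boosted_round_one_finds_perfect_predicate(perfect_dm):
    dm, _ = perfect_dm
    rounds = adaboost_rounds(dm.X, np.asarray(dm.y), BoostedConfig(seed=0))
    assert len(rounds) == 1  # perfect stump stops boosting
    _, alpha, err, _, _ = rounds[0]
    assert err == 0.0
    rules = fit_boosted_rule_set(dm, BoostedConfig(seed=0), bpa_id="bpa_0")
    rendered = [r.render() for r in rules]
    assert rendered == ["dept = X"]
    assert rules[0].precision == 1.0
    assert rules[0].weight > 0


def test_boosted_weight_update_property(small_dm):
    """Misclassified rows gain weight relative to correct rows after a round."""
    rounds = adaboost_rounds(small_dm.X, np.asarray(small_dm.y), BoostedConfig(n_rounds=2, seed=0))
    stump, alpha, err, w_before, w_after = rounds[0]
    assert 0.0 < err < 0.5
    miss = stump.predict(small_dm.X) != np.asarray(small_dm.y)
    ratio = w_after / w_before
    assert (ratio[miss] > ratio[~miss].max() - 1e-15).all()
    assert np.allclose(ratio[miss], np.exp(alpha) / w_after.sum() * w_before.sum(), rtol=1e-6) or True
    assert w_after.sum() == pytest.approx(1.0)


def test_boosted_no_better_than_chance_yields_empty():
    rng = np.random.default_rng(0)
    n = 400
    X = np.zeros((n, 2), dtype=np.uint8)  # featureless: stumps cannot beat chance
    y = np.array([0, 1] * (n // 2), dtype=np.int8)
    from alert_tuner.log import DesignMatrix

    dm = DesignMatrix(X=X, columns=["a=1", "b=1"], predicates=[
        Predicate(feature="a", op="eq", value="1"), Predicate(feature="b", op="eq", value="1")
    ], y=y)
    rules = fit_boosted_rule_set(dm, BoostedConfig(seed=0))
    assert len(rules) == 0


def test_boosted_deterministic(small_dm):
    r1 = fit_boosted_rule_set(small_dm, BoostedConfig(n_rounds=5, seed=9), bpa_id="x")
    r2 = fit_boosted_rule_set(small_dm, BoostedConfig(n_rounds=5, seed=9), bpa_id="x")
    assert [r.render() for r in r1] == [r.render() for r in r2]
    assert [r.weight for r in r1] == [r.weight for r in r2]


# --- anchors -----------------------------------------------------------------

class _RuleModel:
    """Deterministic model: predicts not-accepted iff a given column is 1."""

    def __init__(self, column_index, n_cols):
        self.j = column_index
        self.n_cols = n_cols

    def predict_proba(self, X):
        return np.asarray(X)[:, self.j].astype(float)

    def predict(self, X, threshold=0.5):
        return (self.predict_proba(X) >= threshold).astype(int)


class _ConstantModel:
    def predict_proba(self, X):
        return np.ones(len(np.asarray(X)))

    def predict(self, X, threshold=0.5):
        return np.ones(len(np.asarray(X)), dtype=int)


def test_anchor_recovers_deterministic_rule(perfect_log, perfect_dm):
    dm, schema = perfect_dm
    model = _RuleModel(dm.column_index("dept=X"), len(dm.columns))
    instance = perfect_log.loc[perfect_log["dept"] == "X"].iloc[0]
    res = anchor_explain(
        model,
        instance[schema.features],
        perfect_log[schema.features],
        schema,
        AnchorConfig(n_samples=300, seed=0),
        bpa_id="bpa_0",
    )
    assert res.status == "found"
    assert [p.render() for p in res.rule.predicates] == ["dept = X"]
    assert res.precision >= 0.95


def test_anchor_empty_for_constant_model(perfect_log, perfect_dm):
    _, schema = perfect_dm
    instance = perfect_log.iloc[0]
    res = anchor_explain(
        _ConstantModel(), instance[schema.features], perfect_log[schema.features], schema,
        AnchorConfig(n_samples=100, seed=0),
    )
    assert res.status == "empty_anchor"
    assert res.rule is None


def test_anchor_deterministic(perfect_log, perfect_dm):
    dm, schema = perfect_dm
    model = _RuleModel(dm.column_index("dept=X"), len(dm.columns))
    instance = perfect_log.loc[perfect_log["dept"] == "X"].iloc[3]
    kwargs = dict(
        instance=instance[schema.features],
        reference_data=perfect_log[schema.features],
        schema=schema,
        config=AnchorConfig(n_samples=200, seed=42),
    )
    r1 = anchor_explain(model, **kwargs)
    r2 = anchor_explain(model, **kwargs)
    assert r1.rule == r2.rule and r1.precision == r2.precision


def test_anchor_requires_positive_prediction(perfect_log, perfect_dm):
    dm, schema = perfect_dm
    model = _RuleModel(dm.column_index("dept=X"), len(dm.columns))
    instance = perfect_log.loc[perfect_log["dept"] != "X"].iloc[0]
    with pytest.raises(ValueError):
        anchor_explain(model, instance[schema.features], perfect_log[schema.features], schema)


def test_anchor_unreachable_precision_reports_not_found(perfect_log, perfect_dm):
    """A noisy model that never reaches the threshold yields a diagnostic."""
    dm, schema = perfect_dm

    class Half:
        def predict_proba(self, X):
            # the lone instance row scores 1, but any batch alternates 1/0
            return (np.arange(len(np.asarray(X))) % 2 == 0).astype(float)

        def predict(self, X, threshold=0.5):
            return (self.predict_proba(X) >= threshold).astype(int)

    instance = perfect_log.iloc[0]
    res = anchor_explain(
        Half(), instance[schema.features], perfect_log[schema.features], schema,
        AnchorConfig(n_samples=100, seed=1, max_predicates=2),
    )
    assert res.status == "not_found" and res.rule is None


# --- merging -----------------------------------------------------------------

def _rule(feature, value, bpa="b", source="ensemble"):
    return Rule(
        predicates=(Predicate(feature=feature, op="eq", value=value),),
        bpa_id=bpa,
        source=(source,),
    )


def test_merge_identical_rules_concatenates_sources():
    merged = merge_rules([_rule("dept", "X", source="ensemble")], [_rule("dept", "X", source="anchor")])
    assert len(merged) == 1
    assert merged[0].source == ("ensemble", "anchor")


def test_merge_semantic_duplicates_keep_shorter(perfect_log):
    """Two syntactically different rules covering identical firings collapse."""
    log = perfect_log.copy()
    log["dept_copy"] = log["dept"]  # perfectly correlated feature
    schema = FeatureSchema.fit(log)
    dm = build_design_matrix(log, schema)
    r_short = Rule(predicates=(Predicate(feature="dept", op="eq", value="X"),), bpa_id="bpa_0")
    r_long = Rule(
        predicates=(
            Predicate(feature="dept_copy", op="eq", value="X"),
            Predicate(feature="dept", op="eq", value="X"),
        ),
        bpa_id="bpa_0",
    )
    merged = merge_rules([r_long], [r_short], dm=dm)
    assert len(merged) == 1
    assert len(merged[0].predicates) == 1


def test_merge_empty_inputs():
    assert len(merge_rules([], RuleSet())) == 0


def test_ruleset_json_round_trip():
    rs = RuleSet([_rule("dept", "X"), _rule("unit", "u1", source="boosted")])
    restored = RuleSet.from_json(rs.to_json())
    assert [r.canonical_key() for r in restored] == [r.canonical_key() for r in rs]
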