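import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from alert_tuner import (
    ContingencyTable,
    FeatureSchema,
    Predicate,
    Rule,
    SelectionThresholds,
    compute_metrics,
    contingency,
    derive_outcomes,
    prob_low_acceptance,
    select_rules,
)
from alert_tuner.metrics import metrics_table


def brute_force_metrics(t, theta=0.02):
    """Definitional recomputation from raw (covered, outcome) pairs.

    Rebuilds the individual observations and evaluates every statistic from
    empirical probabilities; the odds ratio additionally cross-checks
    against statsmodels' 2x2 table implementation.
    """
    covered = np.array([1] * (t.a + t.b) + [0] * (t.c + t.d), dtype=bool)
    y = np.array([1] * t.a + [0] * t.b + [1] * t.c + [0] * t.d, dtype=int)
    n = len(y)
    p_x = covered.mean()
    p_y = (y == 1).mean()
    p_xy = (covered & (y == 1)).mean()
    p_x_ybar = (covered & (y == 0)).mean()
    conf = p_xy / p_x
    out = {
        "decrease_rate": p_x,
        "confidence": conf,
        "interest": 0.0 if p_xy == 0 else conf / p_y,
        "conviction": math.inf if p_x_ybar == 0 else p_x * (1 - p_y) / p_x_ybar,
        "prob_low_acceptance": float(stats.beta.cdf(theta, 1 + t.b, 1 + t.a)),
    }
    if min(t.a, t.b, t.c, t.d) == 0:
        out["odds_ratio"] = ((t.a + 0.5) * (t.d + 0.5)) / ((t.b + 0.5) * (t.c + 0.5))
    else:
        import statsmodels.api as sm

        out["odds_ratio"] = sm.stats.Table2x2(
            np.array([[t.a, t.c], [t.b, t.d]])
        ).oddsratio
    # Pearson chi-square from expected counts, 1 dof
    obs = np.array([[t.a, t.c], [t.b, t.d]], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        out["chi2_p"] = 1.0
    else:
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        out["chi2_p"] = float(stats.chi2.sf(chi2, df=1))
    return out


def test_hand_worked_table():
    m = compute_metrics(ContingencyTable(90, 10, 700, 300))
    assert m.odds_ratio == pytest.approx(3.857, abs=5e-4)
    assert m.decrease_rate == pytest.approx(0.0909, abs=5e-5)
    assert m.confidence == pytest.approx(0.90)
    assert m.interest == pytest.approx(1.253, abs=5e-4)
    assert m.conviction == pytest.approx(2.818, abs=5e-4)


def test_perfect_independence_table():
    m = compute_metrics(ContingencyTable(50, 50, 50, 50))
    assert m.odds_ratio == pytest.approx(1.0)
    assert m.interest == pytest.approx(1.0)
    assert m.conviction == pytest.approx(1.0)
    assert m.chi2_p == pytest.approx(1.0)


def test_zero_cell_conventions():
    m = compute_metrics(ContingencyTable(20, 0, 30, 50))
    assert m.confidence == 1.0
    assert m.conviction == math.inf
    haldane = (20.5 * 50.5) / (0.5 * 30.5)
    assert m.odds_ratio == pytest.approx(haldane)


def test_empty_coverage_rejected():
    with pytest.raises(ValueError):
        compute_metrics(ContingencyTable(0, 0, 10, 10))


@pytest.mark.parametrize(
    "a,b,theta,expected,tol",
    [
        (0, 0, 0.5, 0.5, 1e-12),  # uniform prior
        (984, 16, 1.0, 1.0, 1e-12),  # certainty bound
    ],
)
def test_prob_low_acceptance_limits(a, b, theta, expected, tol):
    assert prob_low_acceptance(a, b, theta) == pytest.approx(expected, abs=tol)


def test_prob_low_acceptance_worked_example():
    # 1000 firings, 16 accepted: posterior Beta(17, 985) evaluated at 0.02
    assert prob_low_acceptance(984, 16, 0.02) == pytest.approx(0.782, abs=1e-3)


@given(
    a=st.integers(0, 200),
    b=st.integers(0, 200),
    theta=st.floats(0.01, 0.99),
    dtheta=st.floats(0.0, 0.5),
)
@settings(deadline=None, max_examples=150)
def test_prob_low_acceptance_monotonicity(a, b, theta, dtheta):
    """Non-decreasing in theta and a; non-increasing in b."""
    p = prob_low_acceptance(a, b, theta)
    assert prob_low_acceptance(a, b, min(theta + dtheta, 1.0)) >= p - 1e-12
    assert prob_low_acceptance(a + 5, b, theta) >= p - 1e-12
    assert prob_low_acceptance(a, b + 5, theta) <= p + 1e-12


def test_metrics_agree_with_brute_force_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(200):
        a, c = rng.integers(0, 40, size=2)
        b, d = rng.integers(0, 40, size=2)
        if a + b == 0:
            a = 1
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        m = compute_metrics(t)
        ref = brute_force_metrics(t)
        for key, val in ref.items():
            got = getattr(m, key)
            if math.isinf(val):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(val, rel=1e-9, abs=1e-12), key


@given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(1, 50))
@settings(deadline=None, max_examples=100)
def test_odds_ratio_invariant_under_double_swap(a, b, c, d):
    """Swapping both rows and columns of the 2x2 table leaves OR unchanged."""
    m1 = compute_metrics(ContingencyTable(a, b, c, d))
    m2 = compute_metrics(ContingencyTable(d, c, b, a))
    assert m1.odds_ratio == pytest.approx(m2.odds_ratio)


# --- contingency counting on raw logs ---------------------------------------

def _log_with_rule():
    # 100 firings; rule covers 20 (18 not accepted); 60 of 80 uncovered not accepted
    rows = (
        [("X", "Cancel BPA")] * 18
        + [("X", "single order")] * 2
        + [("O", "Cancel BPA")] * 60
        + [("O", "single order")] * 20
    )
    log = pd.DataFrame(
        {"bpa_id": "b1", "action": [a for _, a in rows], "dept": [d for d, _ in rows]}
    )
    log = derive_outcomes(log)
    schema = FeatureSchema.fit(log)
    rule = Rule(predicates=(Predicate(feature="dept", op="eq", value="X"),), bpa_id="b1")
    return log, schema, rule


def test_contingency_counts():
    log, schema, rule = _log_with_rule()
    t = contingency(rule, log, schema)
    assert (t.a, t.b, t.c, t.d) == (18, 2, 60, 20)
    assert t.n == len(log)


def test_contingency_cover_nothing_and_everything():
    log, schema, _ = _log_with_rule()
    nothing = Rule(predicates=(Predicate(feature="dept", op="eq", value="Q"),), bpa_id="b1")
    t = contingency(nothing, log, schema)
    assert t.a == 0 and t.b == 0
    log_all = log.assign(dept="X")
    everything = Rule(predicates=(Predicate(feature="dept", op="eq", value="X"),), bpa_id="b1")
    t = contingency(everything, log_all, schema)
    assert t.c == 0 and t.d == 0


def test_contingency_empty_bpa_rejected():
    log, schema, rule = _log_with_rule()
    ghost = Rule(predicates=rule.predicates, bpa_id="no_such_bpa")
    with pytest.raises(ValueError):
        contingency(ghost, log, schema)


# --- selection ---------------------------------------------------------------

def test_selection_is_threshold_intersection():
    thresholds = SelectionThresholds()
    passing = compute_metrics(ContingencyTable(990, 5, 7000, 2005))
    assert all(thresholds.passes(passing).values())
    # same table but with enough covered acceptances to fail confidence only
    failing_conf = compute_metrics(ContingencyTable(90, 10, 700, 300))
    flags = thresholds.passes(failing_conf)
    assert not flags["confidence"]
    assert not all(flags.values())


def test_select_rules_on_log():
    # strong rule: 200 covered with 1 acceptance against a 12% acceptance base
    rows = (
        [("X", "Cancel BPA")] * 199
        + [("X", "single order")] * 1
        + [("O", "Cancel BPA")] * 1400
        + [("O", "single order")] * 200
    )
    log = derive_outcomes(
        pd.DataFrame(
            {"bpa_id": "b1", "action": [a for _, a in rows], "dept": [d for d, _ in rows]}
        )
    )
    schema = FeatureSchema.fit(log)
    strong = Rule(predicates=(Predicate(feature="dept", op="eq", value="X"),), bpa_id="b1")
    weak = Rule(predicates=(Predicate(feature="dept", op="eq", value="O"),), bpa_id="b1")
    selected = select_rules([strong, weak], log, schema)
    assert [r.render() for r in selected] == ["dept = X"]
    table = metrics_table([strong, weak], log, schema)
    assert list(table["selected"]) == [True, False]
    # the selected set is a subset of every individual screen's pass set
    sel = table[table["selected"]]
    for col in [c for c in table.columns if c.startswith("pass_")]:
        assert sel[col].all()


def test_select_empty_ruleset():
    log, schema, _ = _log_with_rule()
    assert len(select_rules([], log, schema)) == 0
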