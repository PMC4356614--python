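"""Visit-interval construction, association models, compounding arithmetic."""

import numpy as np
import pandas as pd
import pytest

import albunemia as ab
from albunemia.outcomes import (binary_association, build_intervals,
                                compound_hazard, count_association, cox_axis,
                                expected_false_positives, resolve_flags)

from conftest import one_factor_config


def _visits(rows):
    return pd.DataFrame(rows, columns=["subject", "age", "score",
                                       "death_age", "censor_age"])


def test_single_visit_with_death_yields_event_interval():
    iv = build_intervals(_visits([["s1", 70.0, 0.5, 75.0, 75.0]]))
    assert len(iv) == 1
    row = iv.iloc[0]
    assert (row["entry"], row["exit"], row["event"]) == (70.0, 75.0, 1)


def test_two_visits_with_death_split_censored_then_event():
    iv = build_intervals(_visits([["s1", 70.0, 0.5, 75.0, 75.0],
                                  ["s1", 72.0, 0.7, 75.0, 75.0]]))
    assert iv[["entry", "exit", "event"]].values.tolist() == [
        [70.0, 72.0, 0], [72.0, 75.0, 1]]
    assert iv["score"].tolist() == [0.5, 0.7]


def test_censored_subject_has_no_event():
    iv = build_intervals(_visits([["s1", 70.0, 0.1, np.nan, 78.0]]))
    assert iv["event"].sum() == 0
    assert iv.iloc[0]["exit"] == 78.0


def test_death_before_later_visit_raises():
    with pytest.raises(ab.DataConsistencyError):
        build_intervals(_visits([["s1", 70.0, 0.0, 71.0, 71.0],
                                 ["s1", 72.0, 0.0, 71.0, 71.0]]))


def test_interval_conservation_on_synthetic_panel(default_panel):
    _, panel, truth = default_panel
    visits = panel[["subject", "age", "death_age", "censor_age"]].copy()
    visits["score"] = truth["f1"].to_numpy()
    iv = build_intervals(visits)
    # events equal observed deaths
    deaths = panel.groupby("subject")["death_observed"].first().sum()
    assert iv["event"].sum() == deaths
    # per-subject interval durations add up to the follow-up span
    span = iv.groupby("subject").apply(
        lambda g: (g["exit"] - g["entry"]).sum(), include_groups=False)
    first_visit = panel.groupby("subject")["age"].min()
    end = panel.groupby("subject")["censor_age"].first()
    expected = (end - first_visit).loc[span.index]
    np.testing.assert_allclose(span, expected, atol=1e-9)


def test_cox_rescaled_scores_rescale_log_hazard():
    rng = np.random.default_rng(0)
    n = 800
    entry = rng.uniform(60, 80, n)
    score = rng.normal(0, 2, n)
    T = entry + rng.exponential(1 / (0.05 * np.exp(0.2 * score)))
    cens = entry + 8
    visits = pd.DataFrame({
        "subject": np.arange(n), "age": entry, "score": score,
        "death_age": np.where(T <= cens, T, np.nan),
        "censor_age": np.minimum(T, cens)})
    base = cox_axis(build_intervals(visits))
    doubled_visits = visits.assign(score=2 * score)
    doubled = cox_axis(build_intervals(doubled_visits))
    assert doubled.log_effect == pytest.approx(base.log_effect / 2, rel=1e-6)
    assert base.n_events == doubled.n_events


def test_cox_without_events_raises():
    with pytest.raises(ab.ValidationError, match="no events"):
        cox_axis(pd.DataFrame({"subject": ["a"], "entry": [70.0],
                               "exit": [72.0], "event": [0], "score": [0.0]}))


# -- count and binary outcomes ----------------------------------------------

def test_linear_and_poisson_agree_in_sign_and_recover_effect():
    rng = np.random.default_rng(1)
    n = 3000
    ages = rng.uniform(60, 90, n)
    score = rng.normal(0, 2, n)
    lam = np.exp(-0.3 + 0.12 * score)
    counts = np.minimum(rng.poisson(lam), 5)
    lin = count_association(score, counts, ages, family="linear")
    poi = count_association(score, counts, ages, family="poisson")
    assert np.sign(lin.effect) == np.sign(np.log(poi.effect)) == 1.0
    assert poi.ci[0] <= np.exp(0.12) <= poi.ci[1]


def test_score_free_counts_interval_covers_zero():
    rng = np.random.default_rng(2)
    n = 1000
    counts = rng.poisson(1.0, n)
    res = count_association(rng.normal(0, 1, n), counts,
                            rng.uniform(60, 90, n), family="linear")
    assert res.ci[0] <= 0.0 <= res.ci[1]


def test_non_integer_counts_rejected():
    with pytest.raises(ab.ValidationError):
        count_association(np.zeros(20), np.full(20, 0.5),
                          np.linspace(60, 80, 20), family="poisson")


def test_repeated_visits_use_clustered_estimators():
    rng = np.random.default_rng(3)
    n = 400
    subj = np.repeat(np.arange(n), 2)
    ages = rng.uniform(60, 90, 2 * n)
    score = rng.normal(0, 1, 2 * n)
    counts = rng.poisson(1.0, 2 * n)
    lin = count_association(score, counts, ages, family="linear",
                            subjects=subj)
    poi = count_association(score, counts, ages, family="poisson",
                            subjects=subj)
    assert lin.method == "MixedLM-ML"
    assert poi.method == "GEE-Poisson"


def test_logistic_recovers_simulated_odds_ratio():
    rng = np.random.default_rng(4)
    n = 4000
    ages = rng.uniform(50, 90, n)
    score = rng.normal(0, 1.5, n)
    p = 1 / (1 + np.exp(-(-1.5 + 0.3 * score)))
    flags = np.where(rng.random(n) < p, "positive", "negative")
    res = binary_association(score, flags, ages)
    assert res.ci[0] <= np.exp(0.3) <= res.ci[1]
    assert res.family == "logistic"


def test_score_free_flags_or_interval_covers_one():
    rng = np.random.default_rng(5)
    n = 1500
    flags = np.where(rng.random(n) < 0.3, "positive", "negative")
    res = binary_association(rng.normal(0, 1, n), flags,
                             rng.uniform(50, 90, n))
    assert res.ci[0] <= 1.0 <= res.ci[1]


def test_ambiguous_handling_changes_positive_count_exactly():
    rng = np.random.default_rng(6)
    n = 500
    flags = rng.choice(["positive", "negative", "ambiguous"], n,
                       p=[0.3, 0.6, 0.1])
    n_amb = int((flags == "ambiguous").sum())
    pos = resolve_flags(flags, "positive").sum()
    neg = resolve_flags(flags, "negative").sum()
    assert pos - neg == n_amb
    half = resolve_flags(flags, "half")
    assert half.sum() == neg + 0.5 * n_amb


def test_single_class_outcome_raises():
    with pytest.raises(ab.ValidationError, match="single class"):
        binary_association(np.random.default_rng(7).normal(size=50),
                           ["negative"] * 50, np.linspace(50, 90, 50))


# -- arithmetic -------------------------------------------------------------

def test_compound_hazard_worked_example():
    assert compound_hazard(1.1, 5) == pytest.approx(1.61051)
    assert round(compound_hazard(1.1, 5), 1) == 1.6
    assert compound_hazard(1.23, 0) == 1.0
    assert compound_hazard(1.06, 10) == pytest.approx(np.exp(10 * np.log(1.06)))
    with pytest.raises(ab.ValidationError):
        compound_hazard(0.0, 2)


def test_compound_hazard_monotone_in_delta():
    deltas = np.linspace(0, 10, 21)
    up = [compound_hazard(1.1, d) for d in deltas]
    down = [compound_hazard(0.9, d) for d in deltas]
    assert np.all(np.diff(up) > 0)
    assert np.all(np.diff(down) < 0)


def test_expected_false_positives():
    assert expected_false_positives(36, 0.05) == pytest.approx(1.8)
    assert expected_false_positives(0, 0.05) == 0.0
    assert expected_false_positives(3 * 6 * 2, 0.05) == pytest.approx(1.8)
    with pytest.raises(ab.ValidationError):
        expected_false_positives(10, 1.5)


def test_null_calibration_all_families():
    """Score-independent outcomes: 95% CIs cover the null >= 90% of the time."""
    covers = {"cox": 0, "linear": 0, "poisson": 0, "logistic": 0}
    reps = 30
    for rep in range(reps):
        rng = np.random.default_rng(100 + rep)
        n = 500
        ages = rng.uniform(60, 90, n)
        score = rng.normal(0, 1, n)
        T = ages + rng.exponential(1 / 0.08, n)
        cens = ages + 8
        visits = pd.DataFrame({
            "subject": np.arange(n), "age": ages, "score": score,
            "death_age": np.where(T <= cens, T, np.nan),
            "censor_age": np.minimum(T, cens)})
        cx = cox_axis(build_intervals(visits))
        covers["cox"] += cx.ci[0] <= 1.0 <= cx.ci[1]
        counts = rng.poisson(1.2, n)
        lin = count_association(score, counts, ages, family="linear")
        covers["linear"] += lin.ci[0] <= 0.0 <= lin.ci[1]
        poi = count_association(score, counts, ages, family="poisson")
        covers["poisson"] += poi.ci[0] <= 1.0 <= poi.ci[1]
        flags = np.where(rng.random(n) < 0.3, "positive", "negative")
        lg = binary_association(score, flags, ages)
        covers["logistic"] += lg.ci[0] <= 1.0 <= lg.ci[1]
    for family, k in covers.items():
        assert k >= 0.9 * reps, (family, k)
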