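"""Splitting, stratified discrimination, optimism, and adjustment."""

import numpy as np
import pandas as pd
import pytest

from linkedscore.survival import harrells_c
from linkedscore.validation import (
    StrataSpec,
    acute_condition_records,
    adjustment_analysis,
    default_strata,
    model_performance,
    optimism_bootstrap,
    split_cohort,
    stratified_performance,
)


def _records(n=600, seed=0, lp_col=False):
    rng = np.random.default_rng(seed)
    age = np.clip(rng.normal(55, 18, n), 20, 99)
    sex = rng.integers(0, 2, n)
    score = rng.poisson(2.0, n).astype(float)
    lp = 0.05 * (age - 55) + 0.3 * score
    t = np.minimum(np.ceil(rng.exponential(1 / (0.08 * np.exp(lp - lp.mean()))) * 365.25), 1826)
    return pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "time": t,
            "event": t < 1826,
            "age": age,
            "sex": sex,
            "score": score,
        }
    )


def test_split_is_disjoint_exhaustive_and_reproducible():
    recs = _records(1000)
    dev, val = split_cohort(recs, 0.5, seed=4)
    assert len(dev) == 500 and len(val) == 500
    assert set(dev["patient_id"]).isdisjoint(val["patient_id"])
    assert set(dev["patient_id"]) | set(val["patient_id"]) == set(recs["patient_id"])
    dev2, _ = split_cohort(recs, 0.5, seed=4)
    pd.testing.assert_frame_equal(dev, dev2)
    with pytest.raises(ValueError):
        split_cohort(recs, 1.5)


def test_single_stratum_equals_unstratified_c():
    recs = _records()
    spec = StrataSpec("age", [("all", 0, np.inf)])
    rep = stratified_performance(recs, {"score": recs["score"]}, spec)
    whole = harrells_c(recs["time"], recs["event"], recs["score"])
    assert rep.loc[0, "c"] == pytest.approx(whole.c, abs=1e-12)


def test_perfect_score_gives_c_one_everywhere():
    recs = _records()
    perfect = -recs["time"]  # earlier failure = higher risk
    rep = stratified_performance(recs, {"perfect": perfect}, default_strata("age"))
    nonempty = rep[rep["n"] > 5]
    assert (nonempty["c"].dropna() == 1.0).all()


def test_strata_match_filter_then_compute_oracle():
    recs = _records(800, seed=3)
    rep = stratified_performance(recs, {"score": recs["score"]}, default_strata("age"))
    for _, row in rep.iterrows():
        if row["n"] < 30 or not np.isfinite(row["c"]):
            continue
        lo = float(row["stratum"].split("-")[0].lstrip(">=")) if "-" in row["stratum"] else 90
        hi = lo + 10 if "-" in row["stratum"] else np.inf
        sub = recs[(recs["age"] >= lo) & (recs["age"] < hi)]
        direct = harrells_c(sub["time"], sub["event"], sub["score"]).c
        assert row["c"] == pytest.approx(direct, abs=1e-12)


def test_follow_up_year_strata_condition_on_survival():
    recs = _records(1200, seed=5)
    rep = stratified_performance(
        recs, {"score": recs["score"]}, default_strata("follow_up_year")
    )
    # year-k rows only involve patients surviving to year k
    at_risk_y1 = (recs["time"] > 365.25).sum()
    assert rep[rep["stratum"] == "1-2"]["n"].iloc[0] == at_risk_y1
    assert rep["n"].iloc[0] == len(recs)


def test_model_performance_reports_aic_and_c():
    recs = _records(900, seed=8)
    out = model_performance(recs, {"score": recs["score"]})
    assert {"score (continuous)", "score (categorical)"} <= set(out["model"])
    assert out["aic"].notna().all()
    cont = out[out["model"] == "score (continuous)"].iloc[0]
    assert 0.5 < cont["c"] < 1.0


def test_optimism_zero_for_data_ignoring_scorer():
    from linkedscore.experiments import fixed_scorer_pipeline

    recs = _records(700, seed=2)
    exps = pd.DataFrame(
        {"patient_id": np.repeat(recs["patient_id"], 2), "code": "X", "terminology": "READ"}
    )
    res = optimism_bootstrap(recs, exps, fixed_scorer_pipeline, B=10, seed=1)
    assert abs(res.optimism) < 3 * res.monte_carlo_se + 1e-9


def test_optimism_invariant_to_patient_order():
    from linkedscore.experiments import overfit_pipeline

    recs = _records(300, seed=6)
    exps = recs[["patient_id"]].assign(code="X", terminology="READ")
    a = optimism_bootstrap(recs, exps, overfit_pipeline, B=5, seed=9)
    shuffled = recs.sample(frac=1.0, random_state=3).reset_index(drop=True)
    b = optimism_bootstrap(shuffled, exps, overfit_pipeline, B=5, seed=9)
    # same replicate count and the same positive direction
    assert len(a.replicates) == len(b.replicates)
    assert (a.optimism > 0) == (b.optimism > 0)


def test_adjustment_recovers_time_split_condition_effects():
    """An acute condition with true 60-day log-HR 1.6 and late log-HR 0.3
    is recovered within 3 SEs by the split model."""
    rng = np.random.default_rng(13)
    n = 8000
    cond = rng.binomial(1, 0.3, n)
    age = np.clip(rng.normal(55, 10, n), 20, 95)
    t = np.empty(n)
    for i in range(n):
        # piecewise-exponential: elevated hazard for 60 days, then mild
        h1 = 0.002 * np.exp(1.6 * cond[i])
        h2 = 0.0005 * np.exp(0.3 * cond[i])
        t1 = rng.exponential(1 / h1)
        t[i] = t1 if t1 <= 60 else 60 + rng.exponential(1 / h2)
    t = np.ceil(np.minimum(t, 1826))
    recs = pd.DataFrame(
        {
            "time": t,
            "event": t < 1826,
            "age": age,
            "sex": rng.integers(0, 2, n),
            "condition": cond.astype(float),
        }
    )
    out = adjustment_analysis(recs, {"age_sex_only": None}, time_split=60)
    assert len(out) == 2
    early = out[out["window"] == "0-60d"].iloc[0]
    late = out[out["window"] == ">60d"].iloc[0]
    se_early = (np.log(early["ci_high"]) - np.log(early["hr"])) / 1.96
    se_late = (np.log(late["ci_high"]) - np.log(late["hr"])) / 1.96
    assert abs(np.log(early["hr"]) - 1.6) < 3 * se_early
    assert abs(np.log(late["hr"]) - 0.3) < 3 * se_late


def test_adjusting_for_true_predictor_attenuates_confounded_hr():
    """A condition with no direct effect but correlated with the true
    linear predictor: adjustment pulls its HR toward 1."""
    rng = np.random.default_rng(17)
    n = 6000
    frailty = rng.normal(0, 0.8, n)
    cond = (frailty + rng.normal(0, 0.5, n) > 0.8).astype(float)
    t = np.ceil(np.minimum(rng.exponential(1 / (0.05 * np.exp(frailty))) * 365.25, 1826))
    recs = pd.DataFrame(
        {
            "time": t,
            "event": t < 1826,
            "age": np.full(n, 60.0) + rng.normal(0, 5, n),
            "sex": rng.integers(0, 2, n),
            "condition": cond,
        }
    )
    out = adjustment_analysis(recs, {"crude": None, "adjusted": frailty})
    crude = out[out["model"] == "crude"]["hr"].iloc[0]
    adjusted = out[out["model"] == "adjusted"]["hr"].iloc[0]
    assert crude > 1.15
    assert abs(np.log(adjusted)) < abs(np.log(crude))


def test_adjustment_row_count_scales_with_models():
    recs = _records(500, seed=20).assign(condition=lambda d: (d["score"] > 2).astype(float))
    rng = np.random.default_rng(1)
    out = adjustment_analysis(
        recs,
        {
            "m1": None,
            "m2": recs["score"],
            "m3": recs["score"] + rng.normal(0, 0.1, len(recs)),
            "m4": rng.normal(size=len(recs)),
        },
        time_split=60,
    )
    assert len(out) == 8  # 4 models x 2 windows


def test_acute_condition_records_reanchor():
    recs = _records(400, seed=30)
    ev_day = pd.Series(np.nan, index=recs["patient_id"])
    cases = recs["patient_id"].iloc[:50]
    ev_day.loc[cases] = 5.0
    out = acute_condition_records(recs, ev_day, seed=1)
    assert set(out.columns) >= {"condition", "time", "event"}
    assert out["condition"].sum() <= 50
    assert (out["time"] > 0).all()


def test_excluded_category_yields_equal_scores(published_table):
    """Patients differing only by an excluded category get equal scores
    once it is dropped from the table."""
    from linkedscore.score_builder import drop_category
    from linkedscore.scorer import score_patient

    base = pd.DataFrame(
        {"patient_id": [1, 1], "code": ["J61..", "C10.."], "terminology": ["READ", "READ"]}
    )
    without = pd.DataFrame(
        {"patient_id": [2], "code": ["J61.."], "terminology": ["READ"]}
    )
    stripped = drop_category(published_table, "Diabetes")
    assert (
        score_patient(base, stripped).total == score_patient(without, stripped).total
    )
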