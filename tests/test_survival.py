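"""Cox fitting and discrimination metrics against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from linkedscore.survival import (
    ConvergenceError,
    fit_cox,
    fit_cox_arrays,
    harrells_c,
    lr_test,
    split_follow_up,
)


def test_three_subject_worked_example_matches_grid_search():
    """With subjects (t=1,x=1),(t=2,x=0),(t=3,x=1) all failing, the log
    partial likelihood is b - ln(2e^b+1) - ln(1+e^b); its maximizer from
    a dense grid search must match Newton-Raphson."""
    grid = np.linspace(-2, 2, 400001)
    ll = grid - np.log(2 * np.exp(grid) + 1) - np.log(1 + np.exp(grid))
    b_star = grid[np.argmax(ll)]
    fit = fit_cox_arrays(
        np.array([1.0, 0.0, 1.0]), np.array([1.0, 2.0, 3.0]), np.array([True] * 3)
    )
    assert fit.beta[0] == pytest.approx(b_star, abs=1e-3)
    assert fit.beta[0] == pytest.approx(-0.3466, abs=1e-3)


def test_duplicating_subjects_halves_variance():
    """The partial likelihood doubles, so beta is unchanged and the SE
    shrinks by sqrt(2) (Breslow ties: duplication creates new ties, and
    only Breslow's denominator is invariant to them)."""
    rng = np.random.default_rng(3)
    n = 120
    x = rng.binomial(1, 0.4, n).astype(float)
    t = np.ceil(rng.exponential(1 / np.exp(0.5 * x)) * 40)
    e = np.ones(n, bool)
    f1 = fit_cox_arrays(x, t, e, ties="breslow")
    f2 = fit_cox_arrays(np.tile(x, 2), np.tile(t, 2), np.tile(e, 2), ties="breslow")
    assert f2.beta[0] == pytest.approx(f1.beta[0], abs=1e-6)
    assert f2.se[0] == pytest.approx(f1.se[0] / np.sqrt(2), rel=1e-6)


def test_constant_covariate_is_inestimable():
    with pytest.raises(ConvergenceError, match="constant"):
        fit_cox_arrays(
            np.ones(5), np.arange(1.0, 6.0), np.array([True] * 5), names=["flat"]
        )


def test_zero_events_errors():
    with pytest.raises(ConvergenceError, match="no events"):
        fit_cox_arrays(np.arange(5.0), np.arange(1.0, 6.0), np.zeros(5, bool))


def test_perfect_separation_diagnosed():
    # the covariate perfectly orders an uncensored sample: monotone
    # likelihood, coefficient diverges
    t = np.arange(1.0, 21.0)
    x = (t > 10).astype(float)
    with pytest.raises(ConvergenceError):
        fit_cox_arrays(x, t, np.ones(20, bool), names=["sep"])


@pytest.mark.parametrize("ties", ["efron", "breslow"])
def test_agrees_with_lifelines(ties):
    """Independent implementation check on heavily tied data, with and
    without left truncation."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(7)
    n = 800
    X = np.column_stack(
        [rng.normal(size=n), rng.binomial(1, 0.3, n), rng.normal(size=n)]
    )
    lp = X @ np.array([0.5, -0.3, 0.2])
    T = rng.exponential(1 / np.exp(lp))
    C = rng.exponential(2.0, n)
    t = np.ceil(np.minimum(T, C) * 30)
    e = T <= C
    df = pd.DataFrame(X, columns=list("abc")).assign(t=t, e=e)
    fit = fit_cox_arrays(X, t, e, ties=ties)
    if ties == "efron":
        ref = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert np.abs(fit.beta - ref.params_.to_numpy()).max() < 1e-4
        assert np.abs(fit.se - ref.standard_errors_.to_numpy()).max() < 1e-4
        # left-truncated episodes
        entry = rng.uniform(0, t * 0.5)
        fitE = fit_cox_arrays(X, t, e, entry=entry)
        refE = lifelines.CoxPHFitter().fit(
            df.assign(entry=entry), "t", "e", entry_col="entry"
        )
        assert np.abs(fitE.beta - refE.params_.to_numpy()).max() < 1e-4
    else:
        # breslow: compare against efron only loosely (sanity: same sign,
        # similar scale) — the reference implementation is efron-only
        fit_e = fit_cox_arrays(X, t, e, ties="efron")
        assert np.abs(fit.beta - fit_e.beta).max() < 0.05


def test_aic_identity():
    rng = np.random.default_rng(1)
    x = rng.normal(size=60)
    t = np.ceil(rng.exponential(1, 60) * 20)
    fit = fit_cox_arrays(x, t, np.ones(60, bool))
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * len(fit.beta))


# ---------------------------------------------------------------------------
# Harrell's C


def _brute_c(t, e, s):
    num = den = 0.0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if i != j and t[i] < t[j] and e[i]:
                den += 1
                num += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
    return num / den


def test_concordance_trivial_orderings():
    t = np.array([1.0, 2.0, 3.0])
    e = np.ones(3, bool)
    assert harrells_c(t, e, np.array([3.0, 2.0, 1.0])).c == 1.0
    assert harrells_c(t, e, np.array([1.0, 2.0, 3.0])).c == 0.0
    assert harrells_c(t, e, np.array([1.0, 1.0, 1.0])).c == 0.5


def test_concordance_matches_exhaustive_pair_counting():
    rng = np.random.default_rng(11)
    done = 0
    while done < 50:
        n = int(rng.integers(4, 9))
        t = rng.integers(1, 6, n).astype(float)
        e = rng.random(n) < 0.7
        s = rng.integers(0, 4, n).astype(float)
        try:
            c = harrells_c(t, e, s).c
        except ValueError:
            continue
        assert c == pytest.approx(_brute_c(t, e, s), abs=1e-12)
        done += 1


def test_concordance_invariant_under_monotone_transform():
    rng = np.random.default_rng(5)
    t = np.ceil(rng.exponential(1, 300) * 50)
    e = rng.random(300) < 0.6
    s = rng.normal(size=300)
    c1 = harrells_c(t, e, s)
    c2 = harrells_c(t, e, np.exp(3 * s) + 7)
    assert c1.c == pytest.approx(c2.c, abs=1e-12)
    assert c1.n_pairs == c2.n_pairs


def test_concordance_undefined_without_usable_pairs():
    with pytest.raises(ValueError, match="usable"):
        harrells_c(np.array([5.0, 5.0]), np.array([True, True]), np.array([1.0, 2.0]))


def test_concordance_ci_covers_half_for_random_scores():
    rng = np.random.default_rng(9)
    t = np.ceil(rng.exponential(1, 2000) * 50)
    e = rng.random(2000) < 0.5
    s = rng.normal(size=2000)
    res = harrells_c(t, e, s)
    assert res.ci_low < 0.5 < res.ci_high


# ---------------------------------------------------------------------------
# follow-up splitting and the likelihood-ratio test


def test_split_follow_up_episodes():
    recs = pd.DataFrame({"time": [100.0, 30.0], "event": [True, True]})
    out = split_follow_up(recs, [60])
    first = out[(out["entry"] == 0) & (out["time"] == 60)]
    assert len(first) == 1 and not first["event"].iloc[0]
    late = out[(out["entry"] == 60) & (out["time"] == 100)]
    assert len(late) == 1 and late["event"].iloc[0]
    # short record passes through unchanged
    assert ((out["time"] == 30) & out["event"]).sum() == 1


def test_split_conserves_person_time_and_events(rng):
    n = 1000
    recs = pd.DataFrame(
        {
            "time": np.ceil(rng.exponential(300, n)) + 1,
            "event": rng.random(n) < 0.4,
        }
    )
    out = split_follow_up(recs, [60, 365, 730])
    assert (out["time"] - out["entry"]).sum() == pytest.approx(recs["time"].sum())
    assert out["event"].sum() == recs["event"].sum()


def test_split_rejects_bad_cutpoints():
    recs = pd.DataFrame({"time": [10.0], "event": [True]})
    with pytest.raises(ValueError):
        split_follow_up(recs, [60, 60])


def test_lr_test_identical_models_p_one(rng):
    recs = pd.DataFrame(
        {
            "time": np.ceil(rng.exponential(1, 100) * 30),
            "event": np.ones(100, bool),
            "x": rng.normal(size=100),
        }
    )
    fit = fit_cox(recs, ["x"])
    assert lr_test(fit, fit) == 1.0


def test_lr_test_null_p_values_uniform():
    """Adding a pure-noise covariate: the LR p-value is Uniform(0,1)
    under the null (KS test at alpha=0.01 over 500 simulations)."""
    from scipy import stats

    rng = np.random.default_rng(21)
    pvals = []
    for _ in range(500):
        n = 80
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        t = np.ceil(rng.exponential(1 / np.exp(0.3 * x)) * 25)
        e = np.ones(n, bool)
        recs = pd.DataFrame({"time": t, "event": e, "x": x, "z": noise})
        nested = fit_cox(recs, ["x"])
        full = fit_cox(recs, ["x", "z"])
        try:
            pvals.append(lr_test(nested, full))
        except ValueError:
            continue  # finite-sample wobble can break nesting numerically
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_lr_test_rejects_non_nested(rng):
    recs = pd.DataFrame(
        {
            "time": np.ceil(rng.exponential(1, 50) * 20),
            "event": np.ones(50, bool),
            "x": rng.normal(size=50),
            "z": rng.normal(size=50),
        }
    )
    fx = fit_cox(recs, ["x"])
    fz = fit_cox(recs, ["z"])
    with pytest.raises(ValueError):
        lr_test(fx, fz)
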