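"""Internal validation: discrimination, fit, optimism, strata, adjustment.

Mirrors the validation programme of a derived comorbidity score: a
random half-split of the cohort, Harrell's C and AIC for the score and
comparator indices, bootstrap optimism of the whole model-building
process, discrimination stratified by age / consultation rate /
follow-up year / deprivation, and the ability of the score to adjust a
chronic or acute condition's mortality association.

Optimism here is the standard bootstrap optimism: per replicate the full
derivation is re-run on a resample, and the difference between the
refitted score's apparent concordance (on the resample) and its test
concordance (on the original cohort) is averaged over replicates.
Follow-up-year strata condition on survival to the year's start (left
truncation), so each year's C describes prediction among those still at
risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import fit_cox_arrays, harrells_c

__all__ = [
    "StrataSpec",
    "split_cohort",
    "optimism_bootstrap",
    "OptimismResult",
    "stratified_performance",
    "model_performance",
    "adjustment_analysis",
    "chronic_condition_flag",
    "acute_condition_records",
    "default_strata",
]

DAYS_PER_YEAR = 365.25


def split_cohort(patients: pd.DataFrame, fraction: float = 0.5, seed: int = 0):
    """Random, disjoint, exhaustive patient-level split (development,
    validation); membership is reproducible from the seed."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = len(patients)
    perm = rng.permutation(n)
    k = int(round(fraction * n))
    dev = patients.iloc[np.sort(perm[:k])].reset_index(drop=True)
    val = patients.iloc[np.sort(perm[k:])].reset_index(drop=True)
    return dev, val


@dataclass
class OptimismResult:
    optimism: float
    replicates: list
    n_failed: int

    @property
    def monte_carlo_se(self) -> float:
        r = np.asarray(self.replicates)
        return float(r.std(ddof=1) / np.sqrt(len(r))) if len(r) > 1 else float("nan")


def _resample(records, exposures, idx):
    """Bootstrap-resample patients (with replacement), renumbering ids so
    duplicated patients keep independent event histories."""
    boot = records.iloc[idx].reset_index(drop=True).copy()
    old_ids = boot["patient_id"].to_numpy()
    boot["patient_id"] = np.arange(1, len(boot) + 1)
    if len(exposures):
        lookup = pd.DataFrame({"old": old_ids, "patient_id_new": boot["patient_id"]})
        ex = exposures.merge(lookup, left_on="patient_id", right_on="old", how="inner")
        ex = ex.drop(columns=["patient_id", "old"]).rename(
            columns={"patient_id_new": "patient_id"}
        )
    else:
        ex = exposures.copy()
    return boot, ex


def optimism_bootstrap(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    pipeline,
    B: int = 20,
    seed: int = 0,
) -> OptimismResult:
    """Harrell's bootstrap optimism of a score-building pipeline.

    ``pipeline(records, exposures)`` must return a scoring function
    ``f(records, exposures) -> per-patient risk scores`` aligned with the
    records it is given.  Per replicate: refit on a resample, then
    optimism_b = C(refit score on resample) - C(refit score on original).
    Replicates whose derivation fails are logged and skipped.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    records = records.reset_index(drop=True)
    reps, failed = [], 0
    n = len(records)
    t = records["time"].to_numpy(float)
    e = records["event"].to_numpy(bool)
    for _ in range(B):
        idx = rng.integers(0, n, n)
        boot_rec, boot_exp = _resample(records, exposures, idx)
        try:
            scorer_fn = pipeline(boot_rec, boot_exp)
            s_boot = np.asarray(scorer_fn(boot_rec, boot_exp), dtype=float)
            s_orig = np.asarray(scorer_fn(records, exposures), dtype=float)
            c_app = harrells_c(
                boot_rec["time"], boot_rec["event"], s_boot
            ).c
            c_test = harrells_c(t, e, s_orig).c
            reps.append(c_app - c_test)
        except Exception:
            failed += 1
    if not reps:
        raise RuntimeError(f"all {B} bootstrap replicates failed")
    return OptimismResult(
        optimism=float(np.mean(reps)), replicates=reps, n_failed=failed
    )


@dataclass
class StrataSpec:
    """Stratification request: variable plus exhaustive non-overlapping
    bins as (label, low, high) with high exclusive (inf allowed)."""

    variable: str  # age | consultations | follow_up_year | deprivation_quintile
    bins: list = field(default_factory=list)

    def __post_init__(self):
        for (l1, lo1, hi1), (l2, lo2, hi2) in zip(self.bins, self.bins[1:]):
            if hi1 > lo2:
                raise ValueError("strata bins overlap")


def default_strata(variable: str) -> StrataSpec:
    """The published stratifications: 10-year age bands 20 to >=90,
    consultation bands 0/1/2-3/4-7/8-13/>=14, follow-up years 0-1..4-5,
    deprivation quintiles."""
    if variable == "age":
        bins = [(f"{a}-{a + 9}", a, a + 10) for a in range(20, 90, 10)]
        bins.append((">=90", 90, float("inf")))
    elif variable == "consultations":
        bins = [
            ("0", 0, 1),
            ("1", 1, 2),
            ("2-3", 2, 4),
            ("4-7", 4, 8),
            ("8-13", 8, 14),
            (">=14", 14, float("inf")),
        ]
    elif variable == "follow_up_year":
        bins = [(f"{k}-{k + 1}", k, k + 1) for k in range(5)]
    elif variable == "deprivation_quintile":
        bins = [(str(q), q, q + 1) for q in range(1, 6)]
    else:
        raise ValueError(f"unknown stratification variable {variable!r}")
    return StrataSpec(variable=variable, bins=bins)


def _year_slice(records: pd.DataFrame, year_lo: float, year_hi: float):
    """Left-truncated records for one follow-up-year stratum: patients
    still at risk at the year's start, censored at its end."""
    lo_d, hi_d = year_lo * DAYS_PER_YEAR, year_hi * DAYS_PER_YEAR
    at_risk = records["time"] > lo_d
    sub = records[at_risk].copy()
    ended = sub["time"] <= hi_d
    sub["event"] = sub["event"] & ended
    sub["time"] = sub["time"].clip(upper=hi_d) - lo_d
    return sub


def stratified_performance(
    records: pd.DataFrame,
    scores: dict,
    strata: StrataSpec,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-stratum Harrell's C for each scored model.

    ``scores`` maps model name -> per-patient risk score aligned with
    ``records``.  Strata with no usable pairs are marked undefined (NaN)
    rather than dropped.
    """
    rows = []
    records = records.reset_index(drop=True)
    for label, lo, hi in strata.bins:
        if strata.variable == "follow_up_year":
            sub = _year_slice(records, lo, hi)
            mask = records.index.isin(sub.index)
        else:
            col = records[strata.variable]
            mask = (col >= lo) & (col < hi)
            sub = records[mask]
        for model, s in scores.items():
            s_arr = np.asarray(s, dtype=float)[np.asarray(mask)]
            row = {
                "variable": strata.variable,
                "stratum": label,
                "model": model,
                "n": len(sub),
            }
            try:
                res = harrells_c(sub["time"], sub["event"], s_arr, ci_level=ci_level)
                row.update(c=res.c, ci_low=res.ci_low, ci_high=res.ci_high)
            except ValueError:
                row.update(c=np.nan, ci_low=np.nan, ci_high=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def model_performance(
    records: pd.DataFrame,
    scores: dict,
    ci_level: float = 0.95,
    categorical_cap: int = 20,
) -> pd.DataFrame:
    """AIC and Harrell's C per model, continuous and (optionally)
    categorical use of each score.

    Each model is a Cox fit of its score adjusted for age and sex; C is
    computed on the fitted linear predictor.  ``"<name> (categorical)"``
    rows appear for integer-valued scores, entered as one indicator per
    attained value after capping at ``categorical_cap``.
    """
    rows = []
    recs = records.reset_index(drop=True)
    t = recs["time"].to_numpy(float)
    e = recs["event"].to_numpy(bool)
    base = np.column_stack([recs["age"].to_numpy(float), recs["sex"].to_numpy(float)])
    for model, s in scores.items():
        s = np.asarray(s, dtype=float)
        fit = fit_cox_arrays(
            np.column_stack([s, base]), t, e, names=[model, "age", "sex"]
        )
        lp = np.column_stack([s, base]) @ fit.beta
        res = harrells_c(t, e, lp, ci_level=ci_level)
        rows.append(
            {
                "model": f"{model} (continuous)",
                "aic": fit.aic,
                "c": res.c,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
        if np.allclose(s, np.round(s)):
            capped = np.minimum(s, categorical_cap).astype(int)
            levels = [v for v in np.unique(capped) if v != 0]
            if 0 < len(levels) <= 40:
                X = np.column_stack(
                    [(capped == v).astype(float) for v in levels] + [base]
                )
                names = [f"{model}={v}" for v in levels] + ["age", "sex"]
                fitc = fit_cox_arrays(X, t, e, names=names)
                lpc = X @ fitc.beta
                resc = harrells_c(t, e, lpc, ci_level=ci_level)
                rows.append(
                    {
                        "model": f"{model} (categorical)",
                        "aic": fitc.aic,
                        "c": resc.c,
                        "ci_low": resc.ci_low,
                        "ci_high": resc.ci_high,
                    }
                )
    return pd.DataFrame(rows)


def chronic_condition_flag(exposures: pd.DataFrame, codes: set, patient_ids) -> pd.Series:
    """Chronic-condition indicator: any window-filtered exposure whose
    (normalized) code is in ``codes``."""
    hit = exposures[exposures["code"].isin(codes)]["patient_id"].unique()
    return pd.Series(
        [pid in set(hit) for pid in patient_ids], index=patient_ids, dtype=bool
    )


def acute_condition_records(
    records: pd.DataFrame,
    event_day: pd.Series,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-anchor follow-up for an acute event analysis.

    Cases (finite ``event_day``) are followed from their first event;
    comparators from a random observed day of their own follow-up, so
    both arms share the immortal-time structure.  Returns records with a
    ``condition`` column; patients whose re-anchored follow-up is empty
    are dropped.
    """
    rng = np.random.default_rng(seed)
    recs = records.reset_index(drop=True).copy()
    ev_day = event_day.reindex(recs["patient_id"]).to_numpy(float)
    is_case = np.isfinite(ev_day)
    anchor = np.where(
        is_case, ev_day, np.floor(rng.random(len(recs)) * recs["time"].to_numpy())
    )
    new_time = recs["time"].to_numpy(float) - anchor
    keep = new_time > 0
    out = recs[keep].copy()
    out["time"] = new_time[keep]
    out["condition"] = is_case[keep].astype(float)
    return out


def adjustment_analysis(
    records: pd.DataFrame,
    models: dict,
    time_split: float | None = None,
    condition_col: str = "condition",
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Condition hazard ratios under different adjustment sets.

    ``models`` maps a label to an adjustment score array (aligned with
    ``records``) or None for the age/sex-only model.  With ``time_split``
    the condition effect is estimated separately before and after the
    cutpoint (episode splitting with a window-specific condition term).
    Returns one row per (model, window) with the condition HR and CI.
    """
    from .survival import split_follow_up

    rows = []
    recs = records.reset_index(drop=True)
    for label, s in models.items():
        covs = {"condition": recs[condition_col].to_numpy(float)}
        if s is not None:
            covs["score"] = np.asarray(s, dtype=float)
        covs["age"] = recs["age"].to_numpy(float)
        covs["sex"] = recs["sex"].to_numpy(float)
        df = recs[["time", "event"]].copy()
        for k, v in covs.items():
            df[k] = v
        if time_split is None:
            fit = fit_cox_arrays(
                df[list(covs)].to_numpy(float),
                df["time"].to_numpy(float),
                df["event"].to_numpy(bool),
                names=list(covs),
            )
            lo, hi = fit.ci("condition", ci_level)
            rows.append(
                {
                    "model": label,
                    "window": "all",
                    "hr": np.exp(fit.coef("condition")),
                    "ci_low": np.exp(lo),
                    "ci_high": np.exp(hi),
                }
            )
        else:
            episodes = split_follow_up(df, [time_split])
            early = (episodes["time"] <= time_split).to_numpy()
            cond = episodes["condition"].to_numpy(float)
            X = {
                "condition_early": cond * early,
                "condition_late": cond * ~early,
            }
            for k in covs:
                if k != "condition":
                    X[k] = episodes[k].to_numpy(float)
            fit = fit_cox_arrays(
                np.column_stack(list(X.values())),
                episodes["time"].to_numpy(float),
                episodes["event"].to_numpy(bool),
                names=list(X),
                entry=episodes["entry"].to_numpy(float),
            )
            for term, window in (
                ("condition_early", f"0-{int(time_split)}d"),
                ("condition_late", f">{int(time_split)}d"),
            ):
                lo, hi = fit.ci(term, ci_level)
                rows.append(
                    {
                        "model": label,
                        "window": window,
                        "hr": np.exp(fit.coef(term)),
                        "ci_low": np.exp(lo),
                        "ci_high": np.exp(hi),
                    }
                )
    return pd.DataFrame(rows)
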