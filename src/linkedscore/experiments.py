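"""Reproducible benchmark experiments on the synthetic linkage.

These are the quantitative checks the package makes of itself: structure
of the packaged published table, the integer weight rule against the
published hazard ratios, survival-core oracles, shrinkage calibration,
end-to-end parameter recovery on the desk-scale preset, the all-null
false-positive control, and the direction/calibration of bootstrap
optimism.  Both the test suite and ``scripts/acceptance.py`` run these;
every number is computed at call time.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import published_weight_table
from .coding import (
    ExposureWindow,
    MappingTable,
    extract_exposures,
    hospitalisation_flag,
)
from .pipeline import derive_score
from .score_builder import round_half_up_weight
from .scorer import score_patient
from .shrinkage import HierarchySpec
from .survival import fit_cox_arrays, harrells_c
from .synthetic import (
    GeneratorConfig,
    INDEX_DATE,
    generate,
    paper_scale_preset,
    survival_records,
)
from .validation import optimism_bootstrap

#: published hazard ratio -> printed weight pairs used to check the
#: w = round(10 ln HR) rule (metastases, chromosomal anomalies, multiple
#: sclerosis, cirrhosis)
WEIGHT_RULE_CASES = [(2.9, 11), (2.0, 7), (2.4, 9), (1.6, 5)]


def _cohort(config: GeneratorConfig):
    patients, events, mapping_df, truth = generate(config)
    records = survival_records(patients)
    mapping = MappingTable(
        dict(zip(mapping_df["icd_subchapter"], mapping_df["read_subchapter"]))
    )
    window = ExposureWindow(INDEX_DATE)
    exposures = extract_exposures(events, window)
    hosp = hospitalisation_flag(
        events, INDEX_DATE, patient_ids=records["patient_id"]
    )
    return records, exposures, mapping, hosp, truth


# ---------------------------------------------------------------------------
# published table structure and the weight rule


def published_table_checks() -> dict:
    table = published_weight_table()
    return {
        "n_categories": len(table.categories),
        "n_dual_weight": table.n_dual_weight,
        "max_weight": table.max_weight,
    }


def weight_rule_checks() -> dict:
    derived = [round_half_up_weight(math.log(hr)) for hr, _ in WEIGHT_RULE_CASES]
    printed = [w for _, w in WEIGHT_RULE_CASES]
    return {
        "derived": derived,
        "printed": printed,
        "n_matching": sum(d == p for d, p in zip(derived, printed)),
    }


def toy_scoring_checks() -> dict:
    """Hand-computed totals from the published weights on toy patients."""
    table = published_weight_table()
    results = {}
    # Read cirrhosis code only -> 5
    p1 = pd.DataFrame(
        {"patient_id": [1], "code": ["J61.."], "terminology": ["READ"]}
    )
    results["cirrhosis_read_only"] = score_patient(p1, table).total
    # dementia coded in both settings -> the higher (ICD) weight 7
    p2 = pd.DataFrame(
        {
            "patient_id": [2, 2],
            "code": ["E00..", "F00"],
            "terminology": ["READ", "ICD10"],
        }
    )
    results["dementia_dual_source"] = score_patient(p2, table).total
    # stack categories 12+11+5 = 28, capped at 20
    p3 = pd.DataFrame(
        {
            "patient_id": [3, 3, 3],
            "code": ["B22..", "B57..", "J61.."],
            "terminology": ["READ"] * 3,
        }
    )
    s3 = score_patient(p3, table, cap=20)
    results["stacked_uncapped"] = score_patient(p3, table).total
    results["stacked_capped"] = s3.total
    results["stacked_capped_flag"] = bool(s3.capped)
    return results


# ---------------------------------------------------------------------------
# survival-core oracles


def cox_oracle_check() -> dict:
    """3-subject worked dataset vs a grid search over the closed-form
    log partial likelihood b - ln(2 e^b + 1) - ln(1 + e^b)."""
    fit = fit_cox_arrays(
        np.array([1.0, 0.0, 1.0]),
        np.array([1.0, 2.0, 3.0]),
        np.array([True, True, True]),
    )
    grid = np.linspace(-2, 2, 400001)
    ll = grid - np.log(2 * np.exp(grid) + 1) - np.log(1 + np.exp(grid))
    b_grid = grid[np.argmax(ll)]
    return {
        "beta_hat": float(fit.beta[0]),
        "beta_grid": float(b_grid),
        "abs_error": abs(float(fit.beta[0]) - float(b_grid)),
    }


def concordance_oracle_check(n_datasets: int = 50, seed: int = 0) -> dict:
    """Harrell's C vs exhaustive pair counting on random tiny datasets."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    done = 0
    while done < n_datasets:
        n = int(rng.integers(4, 9))
        t = rng.integers(1, 6, n).astype(float)
        e = rng.random(n) < 0.7
        s = rng.integers(0, 4, n).astype(float)
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if i != j and t[i] < t[j] and e[i]:
                    den += 1
                    num += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
        if den == 0:
            continue
        c = harrells_c(t, e, s).c
        max_err = max(max_err, abs(c - num / den))
        done += 1
    return {"n_datasets": done, "max_abs_error": max_err}


# ---------------------------------------------------------------------------
# shrinkage calibration


def conjugate_oracle_check(seed: int = 0) -> dict:
    """Fixed-variance conjugate configuration: sigma_code = se = 0.2,
    group mean 0.1, estimate 0.5 -> posterior mean 0.3 exactly."""
    from .shrinkage import fit_hierarchy

    est = pd.DataFrame(
        {
            "code": ["X1"],
            "terminology": ["READ"],
            "subchapter": ["X1"],
            "log_hr": [0.5],
            "se": [0.2],
            "group": ["READ:X1"],
            "chapter_unit": ["READ:X"],
            "status": ["ok"],
        }
    )
    spec = HierarchySpec(
        sigma_code_fixed=0.2, sigma_sub_fixed=0.2, fixed_group_mean=0.1, seed=seed
    )
    ps = fit_hierarchy(est, spec)
    post_mean = float(ps.codes["median"].iloc[0])
    return {"posterior_median": post_mean, "expected": 0.3, "abs_error": abs(post_mean - 0.3)}


def shrinkage_mse_replicate(seed: int, n_patients: int = 5000) -> dict:
    """On-model replicate: MSE of shrunk vs raw code-level log-HRs
    against the generator truth (estimable codes only)."""
    from .shrinkage import attach_hierarchy, estimate_code_hazards, fit_hierarchy

    cfg = GeneratorConfig(
        n_patients=n_patients,
        seed=seed,
        p0=0.6,
        baseline_hazard=0.0097,
        base_prevalence=0.04,
        severity_prevalence_factor=2.5,
    )
    records, exposures, mapping, _, truth = _cohort(cfg)
    est = estimate_code_hazards(records, exposures)
    est = attach_hierarchy(est, mapping)
    ok = est[est["status"] == "ok"].reset_index(drop=True)
    post = fit_hierarchy(
        est, HierarchySpec(seed=seed, chains=2, warmup=500, draws=500)
    )
    merged = ok.merge(
        post.codes[["code", "terminology", "median"]], on=["code", "terminology"]
    )
    true_vals = np.array(
        [truth.code_effects[(t, c)] for t, c in zip(merged["terminology"], merged["code"])]
    )
    mse_raw = float(np.mean((merged["log_hr"] - true_vals) ** 2))
    mse_shrunk = float(np.mean((merged["median"] - true_vals) ** 2))
    return {"mse_raw": mse_raw, "mse_shrunk": mse_shrunk, "n_codes": len(merged)}


# ---------------------------------------------------------------------------
# end-to-end recovery, null control


def recovery_replicate(seed: int, n_patients: int = 30_000) -> dict:
    """One desk-scale derivation; compares the derived weight table with
    the generator's non-null group effects."""
    cfg = paper_scale_preset(n_patients=n_patients, seed=seed)
    records, exposures, mapping, hosp, truth = _cohort(cfg)
    res = derive_score(
        records,
        exposures,
        mapping,
        hierarchy_spec=HierarchySpec(seed=seed),
        hospitalisation=hosp,
    )
    weights = res.weights.rows.set_index("category")["weight"].to_dict()
    rows = []
    for gid, beta in truth.nonnull_groups.items():
        label = gid.split(":", 1)[1]
        w = weights.get(label)
        rows.append(
            {
                "category": label,
                "beta_true": beta,
                "target_weight": round_half_up_weight(beta),
                "derived_weight": w,
                "present": w is not None,
                "within_2": w is not None and abs(w - round_half_up_weight(beta)) <= 2,
            }
        )
    extra = [c for c in weights if c not in {r["category"] for r in rows}]
    return {"rows": rows, "extra_categories": extra, "n_weighted": len(weights)}


def null_control(seed: int, n_patients: int = 30_000) -> dict:
    """All-null cohort: fraction of candidate groups receiving a weight
    under the 99% selection rule (false-positive control)."""
    cfg = paper_scale_preset(n_patients=n_patients, seed=seed)
    cfg.fixed_group_effects = ()
    cfg.p0 = 1.0
    records, exposures, mapping, hosp, _ = _cohort(cfg)
    res = derive_score(
        records,
        exposures,
        mapping,
        hierarchy_spec=HierarchySpec(seed=seed),
        hospitalisation=hosp,
    )
    n_candidates = res.estimates["group"].nunique()
    n_weighted = res.weights.rows["category"].nunique()
    return {
        "n_candidate_groups": int(n_candidates),
        "n_weighted": int(n_weighted),
        "fraction": n_weighted / n_candidates,
    }


# ---------------------------------------------------------------------------
# bootstrap optimism


def fixed_scorer_pipeline(records, exposures):
    """A scoring rule fixed a priori (distinct exposure count): ignores
    the outcome data entirely, so its bootstrap optimism is ~0."""

    def scorer(recs, exps):
        counts = exps.groupby("patient_id")["code"].nunique()
        return counts.reindex(recs["patient_id"], fill_value=0).to_numpy(float)

    return scorer


def overfit_pipeline(records, exposures):
    """Overfit by design: memorizes each training patient's observed
    outcome (plus per-patient noise), the canonical recipe for apparent
    performance that does not transfer."""
    rng = np.random.default_rng(len(records))
    memo = dict(
        zip(
            records["patient_id"],
            records["event"].to_numpy(float) + 0.01 * rng.random(len(records)),
        )
    )

    def scorer(recs, exps):
        return np.array([memo.get(pid, 0.5) for pid in recs["patient_id"]])

    return scorer


def optimism_experiments(seed: int, n_patients: int = 5000, B: int = 20) -> dict:
    cfg = GeneratorConfig(
        n_patients=n_patients,
        seed=seed,
        p0=0.6,
        baseline_hazard=0.0097,
        base_prevalence=0.04,
        severity_prevalence_factor=2.5,
    )
    records, exposures, *_ = _cohort(cfg)
    fixed = optimism_bootstrap(
        records, exposures, fixed_scorer_pipeline, B=B, seed=seed
    )
    over = optimism_bootstrap(
        records, exposures, overfit_pipeline, B=B, seed=seed + 1
    )
    over_pos = int(np.sum(np.asarray(over.replicates) > 0))
    return {
        "fixed_optimism": fixed.optimism,
        "fixed_mc_se": fixed.monte_carlo_se,
        "fixed_within_2se": bool(
            abs(fixed.optimism) <= 2 * fixed.monte_carlo_se
        ),
        "overfit_optimism": over.optimism,
        "overfit_positive_replicates": over_pos,
        "B": B,
    }
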