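"""Hierarchical Bayesian re-estimation of per-code hazard ratios.

Stage one screens every observed code with its own age/sex-adjusted Cox
fit, giving a per-code log hazard ratio and standard error.  Stage two
re-estimates those log-HRs in a three-level normal-means hierarchy —
codes within mapped Read subchapters within chapters — so that sparse
codes borrow strength from their group while well-supported codes keep
their own signal:

    y_c      ~ Normal(theta_c, se_c^2)        (observed estimate)
    theta_c  ~ Normal(mu_sub(c), sigma_code^2)
    mu_sub   ~ Normal(mu_chap(sub), sigma_sub^2)
    mu_chap  ~ Normal(0, 1000^2)              (flat on the log scale)

ICD-10 codes attach to the mapped Read subchapter where a mapping
exists, so a disease coded in both settings shares one group.  The
posterior is simulated by a Gibbs sampler: every mean is conditionally
conjugate, and the two Half-Normal(0,1) scale hyperparameters are
updated by slice sampling.  Convergence is checked with split-R-hat
across independent seeded chains.

Selection applies the published rule: a code is kept when its own 99%
credible interval, or its subchapter group's, lies wholly above hazard
ratio 1.2 (read one-sided in the harmful direction — the score has no
protective categories; a symmetric variant is available but off).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coding import ExposureWindow, MappingTable, Terminology, extract_exposures
from .survival import ConvergenceError, fit_cox_arrays

__all__ = [
    "HierarchySpec",
    "PosteriorSummary",
    "estimate_code_hazards",
    "fit_hierarchy",
    "select_codes",
    "attach_hierarchy",
]


def attach_hierarchy(estimates: pd.DataFrame, mapping: MappingTable) -> pd.DataFrame:
    """Assign each code its group (subchapter-level unit) and chapter.

    Read codes group under their own subchapter; ICD-10 codes under the
    mapped Read subchapter when the mapping provides one, else under
    their ICD subchapter.  Unit ids are prefixed with the terminology
    that owns them (``READ:C2``, ``ICD10:K7``) so the two letter spaces
    cannot collide.
    """
    groups, chapters = [], []
    for term, sub in zip(estimates["terminology"], estimates["subchapter"]):
        if term == Terminology.ICD10.value:
            target = mapping.map_group(sub)
            if target != "unmapped":
                groups.append(f"READ:{target}")
                chapters.append(f"READ:{target[0]}")
                continue
        groups.append(f"{term}:{sub}")
        chapters.append(f"{term}:{sub[0]}")
    out = estimates.copy()
    out["group"] = groups
    out["chapter_unit"] = chapters
    return out


def estimate_code_hazards(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    codes: pd.DataFrame | None = None,
    window: ExposureWindow | None = None,
    events: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One univariable age/sex-adjusted Cox fit per observed code.

    ``records`` is the per-patient survival table (patient_id, time,
    event, age, sex); ``exposures`` the window-filtered exposure set.
    Alternatively pass raw ``events`` plus a ``window`` and the filtering
    happens here.  Returns a table with columns code, terminology,
    subchapter, chapter, log_hr, se, n_exposed, status.  Codes whose fit
    is impossible (never exposed before the cutoff, exposure for every
    patient) or whose likelihood is monotone are flagged via ``status``
    rather than silently dropped.
    """
    sr = records.set_index("patient_id")
    if events is not None:
        if window is None:
            raise ValueError("events given without an exposure window")
        exposures = extract_exposures(events, window)
    if codes is None:
        codes = exposures[["code", "terminology", "subchapter", "chapter"]].drop_duplicates()
    n = len(sr)
    base = np.column_stack([sr["age"].to_numpy(float), sr["sex"].to_numpy(float)])
    stop = sr["time"].to_numpy(float)
    ev = sr["event"].to_numpy(bool)
    pos = {pid: i for i, pid in enumerate(sr.index)}
    rows = []
    by_code = exposures.groupby(["code", "terminology"])["patient_id"].unique()
    for _, crow in codes.iterrows():
        key = (crow["code"], crow["terminology"])
        pids = by_code.get(key, np.array([]))
        x = np.zeros(n)
        idx = [pos[p] for p in pids if p in pos]
        x[idx] = 1.0
        n_exp = int(x.sum())
        log_hr, se, status = np.nan, np.nan, "ok"
        if n_exp == 0:
            status = "inestimable:never_observed"
        elif n_exp == n:
            status = "inestimable:no_contrast"
        else:
            try:
                fit = fit_cox_arrays(
                    np.column_stack([x, base]),
                    stop,
                    ev,
                    names=["code", "age", "sex"],
                )
                log_hr, se = fit.coef("code"), fit.se_of("code")
            except ConvergenceError:
                status = "monotone_likelihood"
        rows.append(
            {
                "code": crow["code"],
                "terminology": crow["terminology"],
                "subchapter": crow["subchapter"],
                "chapter": crow["chapter"],
                "log_hr": log_hr,
                "se": se,
                "n_exposed": n_exp,
                "status": status,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class HierarchySpec:
    """Hierarchy priors and sampler settings.

    The top-level prior is Normal(0, 1000^2) on the log scale (flat for
    all practical purposes); the between-code and between-subchapter
    scales get Half-Normal(0, 1) priors unless fixed.
    """

    top_sd: float = 1000.0
    sigma_code_prior_sd: float = 1.0
    sigma_sub_prior_sd: float = 1.0
    sigma_code_fixed: float | None = None
    sigma_sub_fixed: float | None = None
    fixed_group_mean: float | None = None  # pins mu_sub (conjugate oracle checks)
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    level: float = 0.99
    rhat_threshold: float = 1.05


@dataclass
class PosteriorSummary:
    """Posterior medians and central credible intervals for every code,
    subchapter group and chapter, plus convergence diagnostics."""

    codes: pd.DataFrame  # code, terminology, group, median, lo, hi, rhat
    groups: pd.DataFrame  # unit, median, lo, hi, rhat
    chapters: pd.DataFrame
    level: float
    max_rhat: float

    def table(self) -> pd.DataFrame:
        a = self.codes.assign(level_name="code").rename(columns={"code": "unit"})
        b = self.groups.assign(level_name="subchapter")
        c = self.chapters.assign(level_name="chapter")
        cols = ["unit", "level_name", "median", "lo", "hi", "rhat"]
        return pd.concat([a[cols + ["group"]], b[cols], c[cols]], ignore_index=True)


def _slice_sample(rng, x0, logf, width=0.5, max_steps=50):
    """One univariate slice-sampling update (stepping-out; Neal 2003)."""
    logy = logf(x0) + np.log(rng.random())
    u = rng.random() * width
    lo, hi = x0 - u, x0 + (width - u)
    for _ in range(max_steps):
        if logf(lo) <= logy:
            break
        lo -= width
    for _ in range(max_steps):
        if logf(hi) <= logy:
            break
        hi += width
    for _ in range(100):
        x1 = lo + rng.random() * (hi - lo)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-R-hat over (chains, draws, params)."""
    c, d, p = draws.shape
    half = d // 2
    segs = np.concatenate([draws[:, :half, :], draws[:, half : 2 * half, :]], axis=0)
    m, nn = segs.shape[0], segs.shape[1]
    means = segs.mean(axis=1)
    B = nn * means.var(axis=0, ddof=1)
    W = segs.var(axis=1, ddof=1).mean(axis=0)
    var_plus = (nn - 1) / nn * W + B / nn
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(W > 0, rhat, 1.0)


def fit_hierarchy(estimates: pd.DataFrame, spec: HierarchySpec) -> PosteriorSummary:
    """Gibbs-sample the three-level normal-means posterior.

    ``estimates`` must carry columns code, terminology, log_hr, se,
    group, chapter_unit (see :func:`attach_hierarchy`); rows with a
    non-"ok" status or non-finite estimates are excluded up front.
    Raises on split-R-hat above ``spec.rhat_threshold``.
    """
    est = estimates.copy()
    if "status" in est.columns:
        est = est[est["status"] == "ok"]
    est = est[np.isfinite(est["log_hr"]) & np.isfinite(est["se"]) & (est["se"] > 0)]
    est = est.reset_index(drop=True)
    if len(est) == 0:
        raise ValueError("no usable code-level estimates")

    y = est["log_hr"].to_numpy(float)
    s2 = est["se"].to_numpy(float) ** 2
    group_ids, g_idx = np.unique(est["group"], return_inverse=True)
    chap_of_group = (
        est.groupby("group")["chapter_unit"].first().reindex(group_ids).to_numpy()
    )
    chap_ids, h_idx = np.unique(chap_of_group, return_inverse=True)
    m, G, H = len(y), len(group_ids), len(chap_ids)
    n_g = np.bincount(g_idx, minlength=G).astype(float)
    n_h = np.bincount(h_idx, minlength=H).astype(float)
    tau0_2 = spec.top_sd**2

    total = spec.warmup + spec.draws
    keep_theta = np.empty((spec.chains, spec.draws, m))
    keep_mu = np.empty((spec.chains, spec.draws, G))
    keep_chap = np.empty((spec.chains, spec.draws, H))
    keep_sig = np.empty((spec.chains, spec.draws, 2))

    for chain in range(spec.chains):
        rng = np.random.default_rng((spec.seed, chain))
        theta = y.copy()
        mu = np.bincount(g_idx, weights=y, minlength=G) / np.maximum(n_g, 1)
        if spec.fixed_group_mean is not None:
            mu[:] = spec.fixed_group_mean
        mu_ch = np.bincount(h_idx, weights=mu, minlength=H) / np.maximum(n_h, 1)
        sig_c = spec.sigma_code_fixed or (0.3 + 0.2 * chain / max(1, spec.chains - 1))
        sig_s = spec.sigma_sub_fixed or (0.3 + 0.2 * chain / max(1, spec.chains - 1))
        for it in range(total):
            # sigma_code | mu, y with theta integrated out: the collapsed
            # likelihood y_c ~ N(mu_g(c), s_c^2 + sigma^2) mixes far better
            # than conditioning on sampled theta
            if spec.sigma_code_fixed is None:
                resid2 = (y - mu[g_idx]) ** 2
                lam_c = 0.5 / spec.sigma_code_prior_sd**2

                def logf_c(sig):
                    if sig <= 1e-6 or sig > 50:
                        return -np.inf
                    v = s2 + sig**2
                    return float(
                        -0.5 * np.sum(np.log(v)) - 0.5 * np.sum(resid2 / v)
                    ) - lam_c * sig**2

                sig_c = _slice_sample(rng, sig_c, logf_c)
            # group-level sufficient statistics with theta collapsed:
            # each group's weighted mean m_g has variance 1/W_g about mu_g
            v = s2 + sig_c**2
            W_g = np.bincount(g_idx, weights=1.0 / v, minlength=G)
            m_g = np.bincount(g_idx, weights=y / v, minlength=G) / W_g
            # sigma_sub | y, sigma_code, mu_chap with mu_sub ALSO collapsed
            # (m_g ~ N(mu_chap, 1/W_g + sigma_sub^2)); joint collapsing of
            # theta and mu_sub removes the funnel that pins the scales
            if spec.sigma_sub_fixed is None and spec.fixed_group_mean is None:
                lam_s = 0.5 / spec.sigma_sub_prior_sd**2
                dev2 = (m_g - mu_ch[h_idx]) ** 2

                def logf_s(sig):
                    if sig <= 1e-6 or sig > 50:
                        return -np.inf
                    u = 1.0 / W_g + sig**2
                    return float(
                        -0.5 * np.sum(np.log(u)) - 0.5 * np.sum(dev2 / u)
                    ) - lam_s * sig**2

                sig_s = _slice_sample(rng, sig_s, logf_s)
            # mu_chap | m_g, scales (theta and mu_sub collapsed), flat top
            u_g = 1.0 / W_g + sig_s**2
            prec_h = np.bincount(h_idx, weights=1.0 / u_g, minlength=H) + 1.0 / tau0_2
            mean_h = np.bincount(h_idx, weights=m_g / u_g, minlength=H) / prec_h
            mu_ch = mean_h + rng.standard_normal(H) / np.sqrt(prec_h)
            # mu_sub | y, mu_chap, scales (theta collapsed; conjugate)
            if spec.fixed_group_mean is None:
                prec_g = W_g + 1.0 / sig_s**2
                mean_g = (W_g * m_g + mu_ch[h_idx] / sig_s**2) / prec_g
                mu = mean_g + rng.standard_normal(G) / np.sqrt(prec_g)
            # theta_c | y, mu, sigma_code (conjugate draw for summaries)
            prec = 1.0 / s2 + 1.0 / sig_c**2
            mean = (y / s2 + mu[g_idx] / sig_c**2) / prec
            theta = mean + rng.standard_normal(m) / np.sqrt(prec)
            if it >= spec.warmup:
                k = it - spec.warmup
                keep_theta[chain, k] = theta
                keep_mu[chain, k] = mu
                keep_chap[chain, k] = mu_ch
                keep_sig[chain, k] = (sig_c, sig_s)

    alpha = (1.0 - spec.level) / 2.0

    def _summarize(draws, names):
        flat = draws.reshape(-1, draws.shape[-1])
        med = np.median(flat, axis=0)
        lo = np.quantile(flat, alpha, axis=0)
        hi = np.quantile(flat, 1.0 - alpha, axis=0)
        rhat = _split_rhat(draws) if spec.chains > 1 else np.ones(len(names))
        return pd.DataFrame(
            {"unit": names, "median": med, "lo": lo, "hi": hi, "rhat": rhat}
        )

    codes_df = _summarize(keep_theta, est["code"].tolist())
    codes_df.insert(1, "terminology", est["terminology"].tolist())
    codes_df["group"] = est["group"].tolist()
    codes_df = codes_df.rename(columns={"unit": "code"})
    groups_df = _summarize(keep_mu, list(group_ids))
    chapters_df = _summarize(keep_chap, list(chap_ids))
    sig_df = _summarize(keep_sig, ["sigma_code", "sigma_sub"])
    monitored = np.concatenate(
        [codes_df["rhat"], groups_df["rhat"], sig_df["rhat"]]
    )
    max_rhat = float(np.nanmax(monitored))
    if max_rhat > spec.rhat_threshold:
        worst = sig_df if sig_df["rhat"].max() == max_rhat else codes_df
        raise RuntimeError(
            f"chains not converged: max split-R-hat {max_rhat:.3f} "
            f"> {spec.rhat_threshold} (worst units: "
            f"{worst.nlargest(3, 'rhat').iloc[:, 0].tolist()})"
        )
    return PosteriorSummary(
        codes=codes_df,
        groups=groups_df,
        chapters=chapters_df,
        level=spec.level,
        max_rhat=max_rhat,
    )


def select_codes(
    posterior: PosteriorSummary,
    hr_threshold: float = 1.2,
    level: float = 0.99,
    symmetric: bool = False,
) -> pd.DataFrame:
    """Apply the interval-exclusion selection rule.

    A code is selected when its credible interval lies above the hazard
    ratio threshold (lower bound > threshold), or its subchapter group's
    does; the reason (code vs group) is recorded.  With ``symmetric``,
    intervals wholly below 1/threshold also select (off by default: the
    published score has no protective categories).
    """
    if abs(level - posterior.level) > 1e-9:
        raise ValueError(
            f"posterior summarized at level {posterior.level}, not {level}"
        )
    log_thr = np.log(hr_threshold)
    grp = posterior.groups.set_index("unit")
    rows = []
    for _, r in posterior.codes.iterrows():
        code_hit = r["lo"] > log_thr
        g = grp.loc[r["group"]]
        group_hit = g["lo"] > log_thr
        if symmetric:
            code_hit = code_hit or (r["hi"] < -log_thr)
            group_hit = group_hit or (g["hi"] < -log_thr)
        if code_hit:
            reason = "code"
        elif group_hit:
            reason = "group"
        else:
            reason = ""
        rows.append(
            {
                "code": r["code"],
                "terminology": r["terminology"],
                "group": r["group"],
                "selected": bool(code_hit or group_hit),
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)
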