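"""Cox proportional-hazards fitting and discrimination metrics.

All downstream stages — per-code screening, the multivariable weighting
model, and the validation analyses — consume this module.  The partial
likelihood is maximized by Newton–Raphson with step-halving, with Efron's
tie correction by default (day-resolution EHR data has heavy ties;
Breslow is available for oracle comparisons).  Counting-process entry
times are supported so follow-up can be split into (start, stop] episodes
for time-stratified analyses.

Harrell's C is computed by exhaustive pair counting (vectorized in
blocks), with a leave-one-out jackknife standard error on the Somers'-D
scale, mirroring the somersD approach used for published comorbidity
scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxFit",
    "ConcordanceResult",
    "ConvergenceError",
    "fit_cox",
    "fit_cox_arrays",
    "harrells_c",
    "split_follow_up",
    "lr_test",
]


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (monotone likelihood,
    collinearity, or no events)."""


@dataclass
class CoxFit:
    """Maximum partial-likelihood fit of a Cox model.

    ``aic`` is -2*loglik + 2*(number of estimated coefficients);
    reported hazard ratios are exp(beta).
    """

    names: list
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str = "efron"

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.beta)

    def coef(self, name) -> float:
        return float(self.beta[self.names.index(name)])

    def se_of(self, name) -> float:
        return float(self.se[self.names.index(name)])

    def ci(self, name, level: float = 0.95) -> tuple:
        z = stats.norm.ppf(0.5 + level / 2.0)
        b, s = self.coef(name), self.se_of(name)
        return (b - z * s, b + z * s)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {
                "term": self.names,
                "coef": self.beta,
                "se": self.se,
                "hr": np.exp(self.beta),
                "ci_low": np.exp(self.beta - z * self.se),
                "ci_high": np.exp(self.beta + z * self.se),
            }
        )


def _tri_expand(vals, p):
    """Symmetric (p,p) matrix from its upper-triangle values."""
    H = np.zeros((p, p))
    iu = np.triu_indices(p)
    H[iu] = vals
    H[(iu[1], iu[0])] = vals
    return H


class _CoxData:
    """Beta-independent risk-set structure, computed once per fit.

    Subjects at risk at event time ``ts[k]`` are exactly those with
    ``a_i <= k <= b_i``; sums over risk sets come from difference arrays
    accumulated with bincount and a cumulative sum, so each likelihood
    evaluation is O(n p^2) with no per-event-time Python loop.  Efron's
    tie correction is applied as one vectorized term per (event time,
    within-tie index) pair.
    """

    def __init__(self, X, stop, event, entry, ties):
        ts = np.unique(stop[event])
        K = len(ts)
        a = np.searchsorted(ts, entry, side="right")
        b = np.searchsorted(ts, stop, side="right") - 1
        keep = b >= a  # subjects in at least one risk set
        self.K, self.p = K, X.shape[1]
        self.Xr = np.ascontiguousarray(X[keep])
        self.event_rows = event[keep]
        # difference-array indices: +w enters at a, -w leaves after b
        self.cat_idx = np.concatenate([a[keep], b[keep] + 1])
        self.iu = np.triu_indices(self.p)
        self.cat_X = np.vstack([self.Xr, self.Xr])
        n_tri = len(self.iu[0])
        # precompute pairwise-product columns only when they fit comfortably
        self.dense_outer = n_tri * len(self.cat_X) <= 20_000_000
        self.cat_XX = (
            self.cat_X[:, self.iu[0]] * self.cat_X[:, self.iu[1]]
            if self.dense_outer
            else None
        )
        # deaths, grouped by event time (ascending) for the tie fractions
        death_k_raw = np.searchsorted(ts, stop[keep][self.event_rows])
        order = np.argsort(death_k_raw, kind="stable")
        self.death_k = death_k_raw[order]
        Xd = self.Xr[self.event_rows][order]
        self.Xd = Xd
        self.XdXd = (
            Xd[:, self.iu[0]] * Xd[:, self.iu[1]] if self.dense_outer else None
        )
        d_k = np.bincount(self.death_k, minlength=K)
        ne = len(self.death_k)
        self.kk = np.repeat(np.arange(K), d_k)
        jj = np.arange(ne) - np.repeat(np.cumsum(d_k) - d_k, d_k)
        self.frac = jj / d_k[self.kk] if ties == "efron" else np.zeros(ne)
        self.grad_const = Xd.sum(axis=0)

    def _cumdiff(self, weights, cols):
        """bincount-accumulate signed difference columns, then cumsum."""
        K = self.K
        out = np.empty((K, cols.shape[1]))
        for j in range(cols.shape[1]):
            d = np.bincount(self.cat_idx, weights * cols[:, j], minlength=K + 2)
            out[:, j] = np.cumsum(d[: K + 1])[:K]
        return out

    def loglik_grad_hess(self, beta):
        p, K = self.p, self.K
        eta = self.Xr @ beta
        shift = eta.max() if len(eta) else 0.0
        w = np.exp(eta - shift)  # shift cancels in every ratio
        wcat = np.concatenate([w, -w])
        d0 = np.bincount(self.cat_idx, wcat, minlength=K + 2)
        S0 = np.cumsum(d0[: K + 1])[:K]
        S1 = self._cumdiff(wcat, self.cat_X)
        n_tri = len(self.iu[0])
        # deaths reordered to match the death_k grouping
        wd = np.exp(self.Xd @ beta - shift)
        D0 = np.bincount(self.death_k, wd, minlength=K)
        D1 = np.empty((K, p))
        for j in range(p):
            D1[:, j] = np.bincount(self.death_k, wd * self.Xd[:, j], minlength=K)
        S2t = np.empty((K, n_tri))
        D2t = np.empty((K, n_tri))
        for c in range(n_tri):
            i, j = self.iu[0][c], self.iu[1][c]
            col = (
                self.cat_XX[:, c]
                if self.dense_outer
                else self.cat_X[:, i] * self.cat_X[:, j]
            )
            d = np.bincount(self.cat_idx, wcat * col, minlength=K + 2)
            S2t[:, c] = np.cumsum(d[: K + 1])[:K]
            dcol = (
                self.XdXd[:, c]
                if self.dense_outer
                else self.Xd[:, i] * self.Xd[:, j]
            )
            D2t[:, c] = np.bincount(self.death_k, wd * dcol, minlength=K)
        kk, frac = self.kk, self.frac
        phi0 = S0[kk] - frac * D0[kk]
        phi1 = S1[kk] - frac[:, None] * D1[kk]
        phi2t = S2t[kk] - frac[:, None] * D2t[kk]
        ll = float((self.Xd @ beta).sum() - len(wd) * shift - np.log(phi0).sum())
        r = phi1 / phi0[:, None]
        grad = self.grad_const - r.sum(axis=0)
        hess = _tri_expand(-(phi2t / phi0[:, None]).sum(axis=0), p)
        hess += np.einsum("jp,jq->pq", r, r)
        return ll, grad, hess


def fit_cox_arrays(
    X: np.ndarray,
    stop: np.ndarray,
    event: np.ndarray,
    names=None,
    entry: np.ndarray | None = None,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 60,
) -> CoxFit:
    """Fit a Cox model from raw arrays (see :func:`fit_cox`)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event, dtype=bool)
    n, p = X.shape
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if entry is None:
        if (stop <= 0).any():
            raise ValueError("durations must be positive")
        entry = np.full(n, -np.inf)
    else:
        entry = np.asarray(entry, dtype=float)
        if np.any(entry >= stop):
            raise ValueError("entry times must precede stop times")
    if event.sum() == 0:
        raise ConvergenceError("no events: partial likelihood is constant")
    col_sd = X.std(axis=0)
    if np.any(col_sd == 0):
        bad = [names[i] for i in np.flatnonzero(col_sd == 0)]
        raise ConvergenceError(f"covariate(s) constant across subjects: {bad}")

    data = _CoxData(X, stop, event, entry, ties)
    beta = np.zeros(p)
    ll, grad, hess = data.loglik_grad_hess(beta)
    ll_null = ll
    # absolute gradient tolerance scaled by the number of events, since the
    # log partial likelihood (and its round-off floor) grows with them
    tol_eff = tol * max(1.0, float(event.sum()))
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol_eff:
            break
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            bad = names[int(np.argmin(np.diag(info)))]
            raise ConvergenceError(
                f"singular information matrix (near-collinear covariate {bad!r})"
            ) from exc
        # step-halving keeps the likelihood monotone (up to round-off)
        for _ in range(25):
            cand = beta + step
            ll_new, grad_new, hess_new = data.loglik_grad_hess(cand)
            if ll_new >= ll - 1e-9 * (1.0 + abs(ll)):
                break
            step = step / 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > 40:
            bad = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"monotone likelihood: coefficient for {bad!r} diverges "
                "(perfect separation)"
            )
    else:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(max |gradient| = {np.max(np.abs(grad)):.2e})"
        )
    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("information matrix not invertible at optimum") from exc
    se = np.sqrt(np.diag(cov))
    runaway = (np.abs(beta) > 10) & (se > 10)
    if runaway.any():
        bad = names[int(np.argmax(np.abs(beta) * runaway))]
        raise ConvergenceError(
            f"monotone likelihood: coefficient for {bad!r} diverges "
            "(perfect separation)"
        )
    return CoxFit(
        names=names,
        beta=beta,
        se=se,
        cov=cov,
        loglik=ll,
        loglik_null=ll_null,
        n=n,
        n_events=int(event.sum()),
        ties=ties,
    )


def fit_cox(
    records: pd.DataFrame,
    covariates,
    duration_col: str = "time",
    event_col: str = "event",
    entry_col: str | None = None,
    ties: str = "efron",
    **kwargs,
) -> CoxFit:
    """Fit a Cox proportional-hazards model on a records table.

    ``records`` needs a positive duration column, a boolean event column,
    optionally an entry column for left-truncated (start, stop] episodes,
    and one numeric column per requested covariate.
    """
    covariates = list(covariates)
    X = records[covariates].to_numpy(dtype=float)
    entry = records[entry_col].to_numpy(dtype=float) if entry_col else None
    return fit_cox_arrays(
        X,
        records[duration_col].to_numpy(dtype=float),
        records[event_col].to_numpy(dtype=bool),
        names=covariates,
        entry=entry,
        ties=ties,
        **kwargs,
    )


@dataclass
class ConcordanceResult:
    """Harrell's C with a jackknife standard error and normal-theory CI
    computed on the Somers'-D scale (D = 2C - 1)."""

    c: float
    se: float
    ci_low: float
    ci_high: float
    level: float
    n_pairs: int

    def __iter__(self):
        yield from (self.c, self.ci_low, self.ci_high)


class _Fenwick:
    """Binary indexed tree over score ranks (counts)."""

    def __init__(self, m: int):
        self.m = m
        self.tree = [0] * (m + 1)
        self.size = 0

    def add(self, r: int) -> None:  # 0-based rank
        self.size += 1
        i = r + 1
        while i <= self.m:
            self.tree[i] += 1
            i += i & (-i)

    def prefix(self, r: int) -> int:  # count of ranks <= r
        if r < 0:
            return 0
        s = 0
        i = min(r + 1, self.m)
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return s


def harrells_c(
    time,
    event,
    score,
    ci_level: float = 0.95,
) -> ConcordanceResult:
    """Harrell's concordance over usable pairs.

    A pair is usable when the shorter follow-up ends in an event (pairs
    with identical times are not usable).  Concordant = the usable pair's
    earlier failure has the higher score; tied scores count 1/2.  The
    standard error is the leave-one-subject-out jackknife (exact, from
    per-subject pair counts), giving CIs that match the somersD route.
    Pair counting runs in O(n log n) via Fenwick trees over score ranks.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    score = np.asarray(score, dtype=float)
    n = len(time)
    uniq, rank = np.unique(score, return_inverse=True)
    m = len(uniq)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    # tie groups of equal follow-up time, ascending
    starts = np.flatnonzero(np.r_[True, t_sorted[1:] != t_sorted[:-1]])
    ends = np.r_[starts[1:], n]
    num_i = np.zeros(n)  # concordance weight of pairs involving i
    den_i = np.zeros(n)  # usable pairs involving i

    # role "later member of the pair": against events at strictly earlier times
    te = _Fenwick(m)
    for s0, s1 in zip(starts, ends):
        members = order[s0:s1]
        for j in members:
            r = rank[j]
            den_i[j] += te.size
            less = te.prefix(r - 1)
            eq = te.prefix(r) - less
            # earlier failure concordant when its score is higher
            num_i[j] += (te.size - less - eq) + 0.5 * eq
        for j in members:
            if event[j]:
                te.add(rank[j])

    # role "earlier (failing) member": against all subjects at later times
    tl = _Fenwick(m)
    total_num = 0.0
    total_den = 0
    for s0, s1 in zip(starts[::-1], ends[::-1]):
        members = order[s0:s1]
        for i in members:
            if not event[i]:
                continue
            r = rank[i]
            den_i[i] += tl.size
            total_den += tl.size
            less = tl.prefix(r - 1)
            eq = tl.prefix(r) - less
            w = less + 0.5 * eq
            num_i[i] += w
            total_num += w
        for i in members:
            tl.add(rank[i])

    D = float(total_den)
    if D == 0:
        raise ValueError("no usable pairs: concordance undefined")
    N = total_num
    c = N / D
    # exact leave-one-out values from per-subject pair counts
    with np.errstate(invalid="ignore", divide="ignore"):
        c_loo = (N - num_i) / (D - den_i)
    c_loo = np.where(den_i == D, c, c_loo)
    var = (n - 1) / n * np.sum((c_loo - c_loo.mean()) ** 2)
    se_c = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    # CI built on Somers' D = 2C-1 then mapped back (linear, so symmetric)
    d_lo, d_hi = (2 * c - 1) - z * 2 * se_c, (2 * c - 1) + z * 2 * se_c
    return ConcordanceResult(
        c=float(c),
        se=se_c,
        ci_low=float(max(0.0, (d_lo + 1) / 2)),
        ci_high=float(min(1.0, (d_hi + 1) / 2)),
        level=ci_level,
        n_pairs=int(round(D)),
    )


def split_follow_up(records: pd.DataFrame, cutpoints) -> pd.DataFrame:
    """Split each record's follow-up at the given cutpoints (days).

    Returns counting-process episodes with columns ``entry``, ``time``
    (episode stop), ``event`` plus all other input columns carried over.
    Events land in the final episode; total person-time is conserved.
    """
    cutpoints = list(cutpoints)
    if any(c2 <= c1 for c1, c2 in zip(cutpoints, cutpoints[1:])):
        raise ValueError("cutpoints must be strictly increasing")
    if any(c <= 0 for c in cutpoints):
        raise ValueError("cutpoints must be positive")
    base_entry = (
        records["entry"].to_numpy(dtype=float)
        if "entry" in records.columns
        else np.zeros(len(records))
    )
    stop = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=bool)
    rows, entries, stops, events = [], [], [], []
    bounds = np.array(cutpoints, dtype=float)
    for i in range(len(records)):
        cuts = bounds[(bounds > base_entry[i]) & (bounds < stop[i])]
        edges = np.concatenate([[base_entry[i]], cuts, [stop[i]]])
        for j in range(len(edges) - 1):
            rows.append(i)
            entries.append(edges[j])
            stops.append(edges[j + 1])
            events.append(event[i] and j == len(edges) - 2)
    out = records.drop(columns=["entry"], errors="ignore").iloc[rows].reset_index(drop=True)
    out["entry"] = entries
    out["time"] = stops
    out["event"] = events
    return out


def lr_test(nested: CoxFit, full: CoxFit) -> float:
    """Likelihood-ratio test of a nested Cox model against a fuller one.

    Returns the chi-squared p-value on the difference in parameter counts.
    """
    if not set(nested.names) <= set(full.names):
        raise ValueError("models are not nested (covariates not a subset)")
    if (nested.n, nested.n_events) != (full.n, full.n_events):
        raise ValueError("models were fitted on different records")
    stat = 2.0 * (full.loglik - nested.loglik)
    df = len(full.names) - len(nested.names)
    if stat < -1e-6:
        raise ValueError(
            "full model has lower likelihood than nested model; "
            "models cannot be truly nested"
        )
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(max(stat, 0.0), df))
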