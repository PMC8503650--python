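"""Survival machinery: Kaplan–Meier, log-rank, univariate Cox, and the
maximally selected rank-statistic cutpoint.

Conventions used throughout: ``event == 1`` means the event (death or
relapse) was observed, ``event == 0`` means right censoring; times are in
months and must be non-negative.  Cox fits use Efron's tie correction and
Newton–Raphson on the partial likelihood.  The cutpoint search maximizes the
standardized log-rank statistic over admissible splits; the p-value reported
downstream comes from the post-split log-rank test and is therefore
optimistic (the split is selected to maximize it) — callers comparing
cutpoints formally need an adjusted reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CoxFit",
    "CutpointResult",
    "KaplanMeierCurve",
    "kaplan_meier",
    "logrank_test",
    "cox_univariate",
    "best_cutpoint",
    "dichotomized_km",
]

MONOTONE_BETA_BOUND = 15.0


@dataclass
class KaplanMeierCurve:
    """Right-continuous product-limit estimate; callable as S(t)."""

    times: np.ndarray     # distinct event times, increasing
    survival: np.ndarray  # S(t) just after each event time
    n: int
    n_events: int

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        surv = np.concatenate([[1.0], self.survival])
        out = surv[idx]
        return float(out) if out.ndim == 0 else out


@dataclass
class CoxFit:
    beta: float
    se: float
    hr: float
    ci95: tuple[float, float]
    wald_p: float
    n: int
    n_events: int
    converged: bool = True
    score_chi2: float = field(default=np.nan)

    @property
    def log2_hr(self) -> float:
        return self.beta / np.log(2)


@dataclass
class CutpointResult:
    cutpoint: float
    max_statistic: float      # |standardized log-rank statistic| at the split
    group_sizes: tuple[int, int]  # (n_low, n_high); low = score <= cutpoint
    minprop: float


def _validate_times(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-D arrays of equal length")
    if (t < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return t, e.astype(int)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

def kaplan_meier(times, events) -> KaplanMeierCurve:
    """Product-limit estimator (via lifelines)."""
    from lifelines import KaplanMeierFitter

    t, e = _validate_times(times, events)
    if len(t) == 0:
        raise ValueError("empty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_["KM_estimate"]
    event_times = np.unique(t[e == 1])
    surv = sf.reindex(event_times, method="ffill").to_numpy(dtype=float)
    return KaplanMeierCurve(event_times, surv, n=len(t), n_events=int(e.sum()))


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

def logrank_test(times, events, groups) -> tuple[float, float, int]:
    """K-sample log-rank test: (chi2, p, df).

    Observed-minus-expected statistic accumulated over shared event times
    with the hypergeometric covariance; df = K − 1.
    """
    t, e = _validate_times(times, events)
    g = np.asarray(groups)
    labels, gidx = np.unique(g, return_inverse=True)
    K = len(labels)
    if K < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    counts = np.bincount(gidx, minlength=K)
    if (counts == 0).any():
        raise ValueError("empty group")
    if e.sum() == 0:
        raise ValueError("no events observed")

    order = np.argsort(t, kind="stable")
    t, e, gidx = t[order], e[order], gidx[order]
    n = len(t)

    O = np.zeros(K)
    E = np.zeros(K)
    V = np.zeros((K, K))
    at_risk = counts.astype(float).copy()
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        tied = slice(i, j)
        d = e[tied].sum()
        if d > 0:
            n_tot = at_risk.sum()
            d_g = np.bincount(gidx[tied], weights=e[tied], minlength=K)
            O += d_g
            E += d * at_risk / n_tot
            if n_tot > 1:
                c = d * (n_tot - d) / (n_tot - 1)
                p_g = at_risk / n_tot
                V += c * (np.diag(p_g) - np.outer(p_g, p_g))
        for k in np.bincount(gidx[tied], minlength=K).nonzero()[0]:
            at_risk[k] -= np.sum(gidx[tied] == k)
        i = j

    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff) if diff.size else 0.0
    chi2 = max(chi2, 0.0)
    df = K - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, p, df


# ---------------------------------------------------------------------------
# univariate Cox (Newton–Raphson, Efron ties)
# ---------------------------------------------------------------------------

def _cox_derivatives(beta: float, x, t, e):
    """(loglik, score U, information I) of the Efron partial likelihood.

    Arrays must be sorted by ascending time.
    """
    w = np.exp(beta * x)
    # suffix sums: risk set at time t[i] = indices i..n-1 among sorted times
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((x * w)[::-1])[::-1]
    s2 = np.cumsum((x * x * w)[::-1])[::-1]

    loglik = U = I = 0.0
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = np.flatnonzero(e[i:j]) + i
        d = len(ev)
        if d > 0:
            S0r, S1r, S2r = s0[i], s1[i], s2[i]
            wd = w[ev]
            S0d = wd.sum()
            S1d = (x[ev] * wd).sum()
            S2d = (x[ev] ** 2 * wd).sum()
            loglik += beta * x[ev].sum()
            U += x[ev].sum()
            for l in range(d):
                f = l / d
                den = S0r - f * S0d
                u1 = S1r - f * S1d
                u2 = S2r - f * S2d
                loglik -= np.log(den)
                U -= u1 / den
                I += u2 / den - (u1 / den) ** 2
        i = j
    return loglik, U, I


def cox_univariate(x, times, events, max_iter: int = 50,
                   tol: float = 1e-9) -> CoxFit:
    """Univariate Cox proportional-hazards fit with Efron tie handling.

    Converges when |Δbeta| < ``tol``; a monotone-likelihood divergence
    (|beta| exceeding 15) yields a flagged non-converged result rather than
    an exception.  ``score_chi2`` is the score test statistic at beta = 0.
    """
    x = np.asarray(x, dtype=float)
    t, e = _validate_times(times, events)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    if e.sum() < 2:
        raise ValueError("need at least 2 events")

    order = np.argsort(t, kind="stable")
    xs, ts, es = x[order], t[order], e[order]

    beta = 0.0
    converged = False
    score_chi2 = np.nan
    I = np.nan
    for it in range(max_iter):
        _, U, I = _cox_derivatives(beta, xs, ts, es)
        if it == 0 and I > 0:
            score_chi2 = U * U / I
        if I <= 0:
            break
        step = U / I
        beta_new = beta + step
        if abs(beta_new) > MONOTONE_BETA_BOUND:
            beta = beta_new
            break
        if abs(step) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    if abs(beta) > MONOTONE_BETA_BOUND:
        converged = False
    if np.isfinite(I) and I > 0:
        _, _, I = _cox_derivatives(beta, xs, ts, es)
    se = 1.0 / np.sqrt(I) if I > 0 else np.inf
    hr = float(np.exp(beta))
    with np.errstate(over="ignore"):
        lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    wald_p = float(2 * stats.norm.sf(abs(z)))
    return CoxFit(
        beta=float(beta), se=float(se), hr=hr, ci95=(float(lo), float(hi)),
        wald_p=wald_p, n=len(x), n_events=int(e.sum()),
        converged=converged, score_chi2=float(score_chi2),
    )


# ---------------------------------------------------------------------------
# maximally selected rank statistic
# ---------------------------------------------------------------------------

def _logrank_scores(t: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Per-sample log-rank (Nelson–Aalen) scores a_i = e_i − Λ̂(t_i).

    The scores sum to zero exactly; the standardized statistic of any binary
    split is a permutation-variance linear rank statistic in them.
    """
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    n = len(ts)
    cumhaz_sorted = np.empty(n)
    at_risk = n
    cum = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        d = es[i:j].sum()
        cum += d / at_risk
        cumhaz_sorted[i:j] = cum
        at_risk -= j - i
        i = j
    a = np.empty(n)
    a[order] = es - cumhaz_sorted
    return a


def best_cutpoint(score, times, events, minprop: float = 0.1) -> CutpointResult:
    """Maximally selected rank-statistic cutpoint for a prognostic score.

    Every split between consecutive distinct score values whose two groups
    both contain at least ``minprop`` of the samples is evaluated with the
    standardized log-rank statistic; the split with the largest absolute
    statistic wins, ties going to the more balanced split, then to the
    smaller cutpoint.  The returned cutpoint is the midpoint of the two
    adjacent score values ("low" = score ≤ cutpoint).
    """
    score = np.asarray(score, dtype=float)
    t, e = _validate_times(times, events)
    n = len(score)
    if n < 10:
        raise ValueError("best_cutpoint requires at least 10 samples")
    if np.ptp(score) == 0:
        raise ValueError("score is constant")
    if not (0 < minprop < 0.5):
        raise ValueError("minprop must be in (0, 0.5)")

    a = _logrank_scores(t, e)
    ssq = float((a**2).sum())
    if ssq == 0:
        raise ValueError("no events: rank statistic degenerate")

    order = np.argsort(score, kind="stable")
    s_sorted = score[order]
    cum = np.cumsum(a[order])

    m = np.arange(1, n)  # low-group size for split after position m-1
    valid = (s_sorted[:-1] < s_sorted[1:]) & (m >= np.ceil(n * minprop)) \
        & (n - m >= np.ceil(n * minprop))
    if not valid.any():
        raise ValueError("no candidate split satisfies the minprop constraint")

    var = m * (n - m) / (n * (n - 1.0)) * ssq
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(valid, np.abs(cum[:-1]) / np.sqrt(var), -np.inf)
    best = np.lexsort((s_sorted[:-1], np.abs(m - n / 2.0), -z))[0]
    cut = 0.5 * (s_sorted[best] + s_sorted[best + 1])
    return CutpointResult(
        cutpoint=float(cut),
        max_statistic=float(z[best]),
        group_sizes=(int(m[best]), int(n - m[best])),
        minprop=minprop,
    )


def dichotomized_km(score, cutpoint: float, times, events):
    """Split at a cutpoint ("high" = score > cutpoint) and compare groups.

    Returns (CoxFit of the binary high indicator, log-rank p, per-group KM
    curves as a dict with keys "low"/"high").
    """
    score = np.asarray(score, dtype=float)
    t, e = _validate_times(times, events)
    high = (score > cutpoint).astype(int)
    if high.sum() == 0 or high.sum() == len(high):
        raise ValueError("cutpoint produces an empty group")
    fit = cox_univariate(high, t, e)
    _, p, _ = logrank_test(t, e, high)
    km = {
        "low": kaplan_meier(t[high == 0], e[high == 0]),
        "high": kaplan_meier(t[high == 1], e[high == 1]),
    }
    return fit, p, km
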