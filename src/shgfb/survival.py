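"""Survival analyses for F/B stratification of metastasis-free survival.

Implements the statistical workflow applied to per-patient ln F/B values:

* quartile assignment by rank (Q1 = lowest F/B), with larger groups placed in
  the lower quartiles when the cohort size is not divisible by 4;
* the Kaplan-Meier product-limit estimator with censoring bookkeeping;
* Cox proportional-hazards fits by Newton-Raphson on the partial likelihood
  with the Efron tie correction, and nested-model partial likelihood ratio
  tests;
* the paired/unpaired t comparison of bulk vs interface F/B;
* the S-ODX dichotomization at the TAILORx cutoff (26) and the Q1 vs Q2-Q4
  binary grouping.

The Cox fitter is deliberately self-contained (analytic gradient and Hessian,
step-halving line search, convergence at gradient norm < 1e-8) so that its
behavior on small cohorts is fully specified; tests cross-check it against an
independent implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "CoxFit",
    "QuartileAssignment",
    "ConvergenceError",
    "quartile_assign",
    "km_estimate",
    "cox_loglik",
    "cox_fit",
    "lrt",
    "two_covariate_cox",
    "region_compare",
    "sodx_split",
    "q1_vs_rest",
    "quartile_km_analysis",
]

SODX_CUTOFF = 26.0


class ConvergenceError(RuntimeError):
    """Raised when the Cox Newton iteration diverges (e.g. monotone likelihood)."""


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate with at-risk counts and censoring marks."""

    event_times: np.ndarray  # distinct event times, increasing
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    n_events: np.ndarray  # events at each event time
    censor_times: np.ndarray  # observed censoring times (tick marks)

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass(frozen=True)
class CoxFit:
    """A fitted Cox proportional-hazards model."""

    coefficients: np.ndarray  # log hazard ratios
    std_errors: np.ndarray
    log_partial_likelihood: float
    null_log_partial_likelihood: float
    lrt_statistic: float
    lrt_df: int
    lrt_p: float
    n: int
    n_events: int
    covariate_names: tuple[str, ...]


@dataclass(frozen=True)
class QuartileAssignment:
    """Per-patient quartile labels (Q1 = lowest values) and boundary values."""

    labels: np.ndarray  # strings "Q1".."Q4", aligned with the input order
    boundaries: tuple[float, float, float]
    group_sizes: tuple[int, int, int, int]


def quartile_assign(values, ids=None) -> QuartileAssignment:
    """Rank patients by value and split into four near-equal ordered groups.

    When n mod 4 != 0 the extra members go to the *lower* quartiles, so n=95
    gives sizes (24, 24, 24, 23). Ties are broken by a stable sort on
    (value, id) for determinism. Boundaries are the largest value in each of
    Q1..Q3.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("values must be 1-D")
    n = v.size
    if n < 4:
        raise ValueError("need at least 4 values for quartiles")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    ids = np.asarray(ids if ids is not None else np.arange(n))
    order = np.lexsort((ids, v))  # stable: value first, then id
    base, rem = divmod(n, 4)
    sizes = tuple(base + (1 if q < rem else 0) for q in range(4))
    labels = np.empty(n, dtype=object)
    bounds = []
    start = 0
    for q, size in enumerate(sizes):
        members = order[start : start + size]
        labels[members] = f"Q{q + 1}"
        if q < 3:
            bounds.append(float(v[members[-1]]))
        start += size
    return QuartileAssignment(
        labels=labels.astype(str), boundaries=tuple(bounds), group_sizes=sizes
    )


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    At each distinct event time t_i with d_i events among n_i at risk the
    survival multiplies by (1 - d_i / n_i).
    """
    t = np.asarray(times, dtype=np.float64)
    d = np.asarray(events)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != d.shape:
        raise ValueError("times and events must have equal length")
    if (t <= 0).any():
        raise ValueError("times must be positive")
    if not np.isin(d, (0, 1)).all():
        raise ValueError("events must be 0/1")
    d = d.astype(int)
    event_times = np.unique(t[d == 1])
    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    n_ev = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, ti in enumerate(event_times):
        n_i = int((t >= ti).sum())
        d_i = int(((t == ti) & (d == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv[i], at_risk[i], n_ev[i] = s, n_i, d_i
    return SurvivalCurve(
        event_times=event_times,
        survival=surv,
        at_risk=at_risk,
        n_events=n_ev,
        censor_times=np.sort(t[d == 0]),
    )


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron ties)


def _prepare(times, events, covariates):
    t = np.asarray(times, dtype=np.float64)
    d = np.asarray(events).astype(int)
    X = np.asarray(covariates, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if t.shape[0] != d.shape[0] or X.shape[0] != t.shape[0]:
        raise ValueError("times, events and covariates must align")
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")
    if d.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {j} is constant")
    order = np.argsort(t, kind="stable")
    return t[order], d[order], X[order]


def cox_loglik(beta, times, events, covariates):
    """Efron partial log-likelihood with analytic gradient and information matrix.

    Inputs must be pre-sorted ascending in time (as produced by the fitter);
    returns (loglik, gradient, information).
    """
    t, d, X = times, events, covariates
    n, p = X.shape
    beta = np.asarray(beta, dtype=np.float64)
    eta = X @ beta
    eta = eta - eta.max()  # guard exp overflow; cancels in ratios and up to const in ll
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = wX[:, :, None] * X[:, None, :]
    # suffix sums: risk set at time t = {i : t_i >= t}; times sorted ascending
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wX[::-1], axis=0)[::-1]
    s2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        tied = [k for k in range(i, j) if d[k] == 1]
        if tied:
            dk = len(tied)
            c0 = w[tied].sum()
            c1 = wX[tied].sum(axis=0)
            c2 = wXX[tied].sum(axis=0)
            ll += float(eta[tied].sum())
            grad += X[tied].sum(axis=0)
            for l in range(dk):
                f = l / dk
                d0 = s0[i] - f * c0
                d1 = s1[i] - f * c1
                d2 = s2[i] - f * c2
                ll -= np.log(d0)
                grad -= d1 / d0
                info += d2 / d0 - np.outer(d1, d1) / d0**2
        i = j
    # undo the eta shift's constant contribution to ll: each event term added
    # (eta_k - log d0) where both eta and d0 were shifted identically, so ll
    # is already exact up to the common shift cancelling. Nothing to undo.
    return ll, grad, info


def cox_fit(
    times,
    events,
    covariates,
    covariate_names: tuple[str, ...] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxFit:
    """Maximize the Efron partial likelihood by Newton-Raphson.

    Converges when the gradient norm drops below ``tol``; uses step-halving
    when a full Newton step would decrease the likelihood. Diverging
    coefficients (|beta| > 40, the signature of a monotone likelihood /
    perfect separation) raise :class:`ConvergenceError`.
    """
    t, d, X = _prepare(times, events, covariates)
    p = X.shape[1]
    if covariate_names is None:
        covariate_names = tuple(f"x{j}" for j in range(p))
    if len(covariate_names) != p:
        raise ValueError("covariate_names length mismatch")
    # scale covariates for numerical stability; rescale coefficients after
    scale = X.std(axis=0, ddof=0)
    Xs = (X - X.mean(axis=0)) / scale
    beta = np.zeros(p)
    ll, grad, info = cox_loglik(beta, t, d, Xs)
    ll_null = ll
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "singular information matrix (collinear covariates?)"
            ) from exc
        if np.linalg.cond(info) > 1e12:
            raise ConvergenceError("ill-conditioned information matrix (collinearity)")
        new_beta = beta + step
        new_ll, new_grad, new_info = cox_loglik(new_beta, t, d, Xs)
        halvings = 0
        # tolerate float noise in ll near the optimum; halve only on real overshoot
        drop_tol = 1e-9 * max(1.0, abs(ll))
        while new_ll < ll - drop_tol and halvings < 30:
            step /= 2
            new_beta = beta + step
            new_ll, new_grad, new_info = cox_loglik(new_beta, t, d, Xs)
            halvings += 1
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.abs(beta).max() > 40:
            raise ConvergenceError(
                "coefficient diverging: monotone partial likelihood "
                "(perfect separation of events by a covariate)"
            )
    else:
        warnings.warn("Cox Newton iteration did not converge", stacklevel=2)
    cov_beta = np.linalg.inv(info)
    # undo standardization
    coef = beta / scale
    se = np.sqrt(np.diag(cov_beta)) / scale
    lrt_stat = max(2.0 * (ll - ll_null), 0.0)
    return CoxFit(
        coefficients=coef,
        std_errors=se,
        log_partial_likelihood=float(ll),
        null_log_partial_likelihood=float(ll_null),
        lrt_statistic=float(lrt_stat),
        lrt_df=p,
        lrt_p=float(stats.chi2.sf(lrt_stat, p)),
        n=int(t.size),
        n_events=int(d.sum()),
        covariate_names=tuple(covariate_names),
    )


def lrt(full: CoxFit, null: CoxFit) -> tuple[float, float]:
    """Partial likelihood ratio test of a nested Cox model pair."""
    df = full.lrt_df - null.lrt_df
    if df < 0:
        raise ValueError("null model has more covariates than full model")
    if full.n != null.n or full.n_events != null.n_events:
        raise ValueError("models fit on different data; not nested")
    if df == 0:
        return 0.0, 1.0
    stat = 2.0 * (full.log_partial_likelihood - null.log_partial_likelihood)
    if stat < -1e-6:
        raise ValueError("full model has lower likelihood than null; not nested")
    stat = max(stat, 0.0)
    return float(stat), float(stats.chi2.sf(stat, df))


def two_covariate_cox(
    times, events, fb_bulk, fb_interface
) -> tuple[CoxFit, dict[str, float]]:
    """Joint bulk+interface Cox fit with drop-one LRT p-values per covariate.

    The per-covariate p-value answers "does this covariate add information
    when the other is already in the model".
    """
    X = np.column_stack([np.asarray(fb_bulk, float), np.asarray(fb_interface, float)])
    if np.ptp(X[:, 0] - X[:, 1]) == 0:
        raise ValueError("bulk and interface covariates are identical (collinear)")
    full = cox_fit(times, events, X, covariate_names=("ln_fb_bulk", "ln_fb_interface"))
    p_values = {}
    for j, name in enumerate(full.covariate_names):
        reduced = cox_fit(times, events, X[:, [1 - j]], covariate_names=(full.covariate_names[1 - j],))
        _, p = lrt(full, reduced)
        p_values[name] = p
    return full, p_values


def region_compare(fb_bulk, fb_interface, paired: bool = True) -> tuple[float, float]:
    """Two-sided t comparison of bulk vs interface F/B (paired by default)."""
    a = np.asarray(fb_bulk, dtype=np.float64)
    b = np.asarray(fb_interface, dtype=np.float64)
    if min(a.size, b.size) < 3:
        raise ValueError("need at least 3 observations per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires matched samples")
        diff = a - b
        if np.ptp(diff) == 0:
            if diff[0] == 0:
                return 0.0, 1.0
            raise ValueError(
                "all paired differences identical and nonzero: zero variance, "
                "t statistic undefined"
            )
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def sodx_split(
    records: pd.DataFrame, cutoff: float = SODX_CUTOFF
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort at the S-ODX cutoff: (< cutoff, >= cutoff).

    Rows with missing S-ODX are dropped with a warning. An empty side is
    allowed but warned about.
    """
    if "sodx" not in records.columns:
        raise ValueError("records lack an 'sodx' column")
    missing = records["sodx"].isna()
    if missing.any():
        warnings.warn(f"excluding {int(missing.sum())} records without S-ODX", stacklevel=2)
        records = records[~missing]
    low = records[records["sodx"] < cutoff]
    high = records[records["sodx"] >= cutoff]
    if low.empty or high.empty:
        warnings.warn("one S-ODX group is empty at this cutoff", stacklevel=2)
    return low, high


def q1_vs_rest(assignment: QuartileAssignment) -> np.ndarray:
    """Binary grouping: True for Q1 (lowest F/B), False for Q2-Q4."""
    return assignment.labels == "Q1"


def quartile_km_analysis(
    values, times, events, ids=None
) -> tuple[QuartileAssignment, dict[str, SurvivalCurve]]:
    """Quartile-stratified Kaplan-Meier curves keyed by quartile label."""
    assignment = quartile_assign(values, ids)
    t = np.asarray(times, float)
    d = np.asarray(events)
    curves = {
        q: km_estimate(t[assignment.labels == q], d[assignment.labels == q])
        for q in ("Q1", "Q2", "Q3", "Q4")
    }
    return assignment, curves
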