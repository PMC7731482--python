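"""Independent brute-force oracles used to validate the implementation.

Everything here is written naively (plain loops, direct formula evaluation)
and must stay independent of the code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_otsu(image: np.ndarray, levels=range(256)) -> int:
    """Exhaustive minimizer of weighted within-class variance over 8-bit levels.

    Foreground = pixels > t. Returns the smallest level attaining the minimum.
    """
    x = np.asarray(image).ravel().astype(float)
    n = x.size
    best_t, best_obj = None, math.inf
    for t in levels:
        bg = x[x <= t]
        fg = x[x > t]
        if bg.size == 0 or fg.size == 0:
            continue
        obj = (bg.size / n) * bg.var() + (fg.size / n) * fg.var()
        if obj < best_obj - 1e-15:
            best_obj, best_t = obj, t
    return best_t


def brute_force_min_window_fraction(binary: np.ndarray, k: int) -> float:
    """Minimum nonzero fraction over every fully-interior k-by-k window position."""
    h, w = binary.shape
    best = 1.0
    for i in range(h - k + 1):
        for j in range(w - k + 1):
            frac = binary[i : i + k, j : j + k].sum() / (k * k)
            best = min(best, frac)
    return best


def brute_force_window_size(image: np.ndarray, windows, factor=0.6, empty_fraction=0.05):
    """Hand enumeration of the window-size search: smallest admissible size.

    Returns (size, admissible_flag); admissible_flag False means every size
    failed and the largest was returned as fallback.
    """
    binary = (image > factor * image.mean()).astype(int)
    chosen = None
    for k in windows:
        if brute_force_min_window_fraction(binary, k) >= empty_fraction:
            chosen = k
        else:
            break
    if chosen is None:
        return windows[0], False
    return chosen, True


def naive_cox_loglik(beta: float, times, events, x) -> float:
    """Breslow partial log-likelihood for one covariate, plain loops.

    Valid as an oracle on data without tied event times (Breslow == Efron).
    """
    t = np.asarray(times, float)
    d = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in range(t.size):
        if d[i] == 1:
            risk = np.exp(beta * x[t >= t[i]]).sum()
            ll += beta * x[i] - math.log(risk)
    return ll


def naive_node_deviance(events, cumhaz) -> float:
    """Direct evaluation of the one-step deviance formula, plain loop."""
    d = np.asarray(events, float)
    lam = np.asarray(cumhaz, float)
    theta = d.sum() / lam.sum()
    total = 0.0
    for di, li in zip(d, lam):
        mu = theta * li
        if di > 0:
            total += di * math.log(di / mu) - (di - mu)
        else:
            total += mu  # d=0: 0*log0 = 0, -(0 - mu) = mu
    return 2.0 * total


def naive_nelson_aalen_at(times, events, eval_times) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated by direct counting."""
    t = np.asarray(times, float)
    d = np.asarray(events, int)
    out = []
    for s in np.asarray(eval_times, float):
        total = 0.0
        for ti in np.unique(t[(d == 1) & (t <= s)]):
            total += ((t == ti) & (d == 1)).sum() / (t >= ti).sum()
        out.append(total)
    return np.array(out)


def naive_best_split(data, covariates, cumhaz, min_size, min_events):
    """Independent exhaustive split search using naive_node_deviance."""
    d = data["event"].to_numpy(int)
    lam = np.asarray(cumhaz, float)
    parent = naive_node_deviance(d, lam)
    best = None
    for var in covariates:
        x = data[var].to_numpy(float)
        for cut in np.unique(x):
            left = x < cut
            right = ~left
            if left.sum() < min_size or right.sum() < min_size:
                continue
            if d[left].sum() < min_events or d[right].sum() < min_events:
                continue
            imp = parent - (
                naive_node_deviance(d[left], lam[left])
                + naive_node_deviance(d[right], lam[right])
            )
            if best is None or imp > best[2] + 1e-12:
                best = (var, cut, imp)
    return best
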