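"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, obvious way (loops,
sort-and-slice, scipy generic optimization) and shares no code with the
package paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def brute_bin_means(clock_hours, lux):
    """Per-half-hour-bin pooled means via an explicit loop."""
    sums = np.zeros(48)
    counts = np.zeros(48, dtype=int)
    for t, v in zip(clock_hours, lux):
        k = int(t // 0.5)
        sums[k] += v
        counts[k] += 1
    means = np.full(48, np.nan)
    means[counts > 0] = sums[counts > 0] / counts[counts > 0]
    return means, counts


def sort_slice_groups(values, cutpoints):
    """Quantile-threshold group assignment by explicit comparison loops."""
    values = np.asarray(values, float)
    thresholds = [np.quantile(values, c / 100.0) for c in cutpoints]
    labels = [f"{lo:g}-{hi:g}%" for lo, hi in zip(cutpoints[:-1], cutpoints[1:])]
    out = []
    for v in values:
        assigned = labels[-1]  # top group keeps the maximum
        for g in range(len(labels) - 1):
            if thresholds[g] <= v < thresholds[g + 1]:
                assigned = labels[g]
                break
        out.append(assigned)
    return np.array(out, dtype=object)


def prs_double_loop(dosages, betas):
    """S_i = sum_j beta_j g_ij as an explicit double loop."""
    n, m = dosages.shape
    scores = np.zeros(n)
    for i in range(n):
        for j in range(m):
            scores[i] += betas[j] * dosages[i, j]
    return scores


def efron_neg_loglik(beta, X, time, status):
    """Negative Cox partial log-likelihood with Efron tie handling."""
    beta = np.asarray(beta, float)
    eta = X @ beta
    theta = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[status == 1]):
        D = np.flatnonzero((time == t) & (status == 1))
        R = np.flatnonzero(time >= t)
        d = len(D)
        S_R = theta[R].sum()
        S_D = theta[D].sum()
        ll += eta[D].sum()
        for el in range(d):
            ll -= np.log(S_R - (el / d) * S_D)
    return -ll


def efron_neg_grad(beta, X, time, status):
    beta = np.asarray(beta, float)
    eta = X @ beta
    theta = np.exp(eta)
    grad = np.zeros_like(beta)
    for t in np.unique(time[status == 1]):
        D = np.flatnonzero((time == t) & (status == 1))
        R = np.flatnonzero(time >= t)
        d = len(D)
        S_R = theta[R].sum()
        S_D = theta[D].sum()
        xw_R = X[R].T @ theta[R]
        xw_D = X[D].T @ theta[D]
        grad += X[D].sum(axis=0)
        for el in range(d):
            grad -= (xw_R - (el / d) * xw_D) / (S_R - (el / d) * S_D)
    return -grad


def fit_cox_bruteforce(X, time, status):
    """Maximize the Efron partial likelihood with a generic optimizer."""
    X = np.asarray(X, float)
    res = minimize(
        efron_neg_loglik,
        np.zeros(X.shape[1]),
        args=(X, np.asarray(time, float), np.asarray(status, int)),
        jac=efron_neg_grad,
        method="BFGS",
        options={"gtol": 1e-12, "maxiter": 500},
    )
    return res.x
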