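"""Independent reference implementations used to cross-check the package.

Everything here is written as literally as possible (explicit loops, the
textbook formulas) and must stay independent of the vectorised code paths
it checks.
"""

from __future__ import annotations

import math

import numpy as np


def higuchi_fd_naive(x, kmax: int) -> float:
    """Literal triple-loop Higuchi estimator (1-based indexing as published).

    For k = 1..kmax and m = 1..k, with n = floor((N - m) / k):

        L_m(k) = [ sum_{i=1..n} |x_{m+ik} - x_{m+(i-1)k}| ] * (N-1)/(n*k) / k

    L(k) is the mean over m; FD is minus the OLS slope of ln L(k) on ln k.
    """
    x = list(map(float, x))
    n_tot = len(x)
    ln_k, ln_l = [], []
    for k in range(1, kmax + 1):
        lm_values = []
        for m in range(1, k + 1):
            n = (n_tot - m) // k
            total = 0.0
            for i in range(1, n + 1):
                total += abs(x[m + i * k - 1] - x[m + (i - 1) * k - 1])
            lm_values.append(total * (n_tot - 1) / (n * k) / k)
        lk = sum(lm_values) / len(lm_values)
        if lk > 0:
            ln_k.append(math.log(k))
            ln_l.append(math.log(lk))
    n = len(ln_k)
    sx, sy = sum(ln_k), sum(ln_l)
    sxx = sum(v * v for v in ln_k)
    sxy = sum(a * b for a, b in zip(ln_k, ln_l))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    return -slope


def bh_stepup_naive(p_raw) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule.

    Sort ascending, scale p_(i) by m/i, then enforce monotonicity from the
    largest rank downward and cap at 1.
    """
    p = np.asarray(p_raw, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    # p_(i) divided by its rank fraction i/m
    scaled = p[order] / (np.arange(1, m + 1) / m)
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, scaled[i])
        adj[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def holm_naive(p_raw) -> np.ndarray:
    """Holm step-down adjusted p-values by the literal rule."""
    p = np.asarray(p_raw, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
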