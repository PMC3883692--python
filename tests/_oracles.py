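"""Independent reference implementations used as test oracles.

These are deliberately plain, loop-based transcriptions of the published
formulas (empirical Bayes variance shrinkage, externally studentized
residuals, chance misclassification rates), kept free of any code from the
package under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special, stats


def reference_trigamma_inverse(x: float, iterations: int = 100) -> float:
    """Invert trigamma by bisection (slow, robust)."""
    lo, hi = 1e-8, 1e8
    for _ in range(iterations):
        mid = math.sqrt(lo * hi)
        if special.polygamma(1, mid) > x:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def reference_moderated_t(group_a: np.ndarray, group_b: np.ndarray):
    """Step-by-step moderated two-sample t over a metabolite ensemble.

    Returns dict with delta, s2, d0, s0_sq, s2_post, t, df_total, p.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_a, m = a.shape
    n_b = b.shape[0]
    delta = np.empty(m)
    s2 = np.empty(m)
    for j in range(m):
        xa, xb = a[:, j], b[:, j]
        delta[j] = xa.mean() - xb.mean()
        ssa = ((xa - xa.mean()) ** 2).sum()
        ssb = ((xb - xb.mean()) ** 2).sum()
        s2[j] = (ssa + ssb) / (n_a + n_b - 2)
    d = float(n_a + n_b - 2)

    # moment matching on log variances
    e = np.array([math.log(v) - special.digamma(d / 2) + math.log(d / 2) for v in s2])
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2)
    if evar > 0:
        d0 = 2.0 * reference_trigamma_inverse(float(evar))
        s0_sq = math.exp(emean + special.digamma(d0 / 2) - math.log(d0 / 2))
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
        s2_post = np.full(m, s0_sq)
        df_total = math.inf

    t = delta / np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return {
        "delta": delta,
        "s2": s2,
        "d0": d0,
        "s0_sq": s0_sq,
        "s2_post": s2_post,
        "t": t,
        "df_total": df_total,
        "p": p,
    }


def reference_pooled_t(group_a: np.ndarray, group_b: np.ndarray):
    """Ordinary pooled two-sample t per metabolite (the d0 = 0 limit)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_a, n_b = a.shape[0], b.shape[0]
    out = []
    for j in range(a.shape[1]):
        res = stats.ttest_ind(a[:, j], b[:, j], equal_var=True)
        out.append(res.statistic)
    return np.asarray(out)


def reference_studentized_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Externally studentized residuals of an OLS fit, cell by cell."""
    n = len(y)
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    resid = y - H @ y
    rank = int(round(np.trace(H)))
    df = n - rank
    out = np.full(n, np.nan)
    sse = float(resid @ resid)
    for i in range(n):
        h = H[i, i]
        if 1 - h < 1e-10 or df < 2:
            continue
        s2_i = (sse - resid[i] ** 2 / (1 - h)) / (df - 1)
        if s2_i <= 0:
            out[i] = np.inf * np.sign(resid[i])
        else:
            out[i] = resid[i] / math.sqrt(s2_i * (1 - h))
    return out


def chance_error_rate(labels: np.ndarray) -> float:
    """Misclassification rate of always predicting the modal class."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    return 1.0 - counts.max() / counts.sum()
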