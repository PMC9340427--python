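"""Independent oracles used by the tests.

These deliberately avoid the library's own fitting code paths: the linear
oracle solves the normal equations directly, and the exponential oracle is
an exhaustive coarse grid search over (TD, tau) with the linear parameters
(TSIb, A) profiled by ``numpy.linalg.lstsq`` at every node.
"""

import numpy as np


def ols_normal_equations(t, y):
    """Closed-form OLS line fit via the 2x2 normal equations."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    intercept, slope = coef
    resid = y - X @ coef
    sstot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / sstot if sstot > 0 else np.nan
    return slope, intercept, r2


def grid_oracle_rss(t, y):
    """Best RSS of the delayed exponential on a coarse (TD, tau) grid.

    TD in {0, 5, ..., 60} s, tau in {5, 10, ..., 120} s; at each node
    TSIb and A are profiled by linear least squares on the basis
    [1, 1 - exp(-(t-TD)+/tau)].
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    best = np.inf
    for td in range(0, 61, 5):
        for tau in range(5, 121, 10):
            g = 1.0 - np.exp(-np.clip(t - td, 0.0, None) / tau)
            X = np.column_stack([np.ones_like(t), g])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ coef) ** 2))
            best = min(best, rss)
    return best


def synthetic_recovery(rng, n=240):
    """One noisy recovery segment with parameters in realistic ranges."""
    tsib = rng.uniform(45.0, 65.0)
    amp = rng.uniform(20.0, 35.0)
    td = rng.uniform(5.0, 60.0)
    tau = rng.uniform(15.0, 90.0)
    t = np.arange(n, dtype=float)
    rise = np.clip(t - td, 0.0, None)
    y = tsib + amp * (1.0 - np.exp(-rise / tau)) + rng.normal(0.0, 1.0, n)
    return t, y, (tsib, amp, td, tau)
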