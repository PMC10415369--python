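"""Independent reference computations used to cross-check the pipeline.

Each oracle recomputes a quantity by a route disjoint from the implementation
it checks: a generic numeric minimizer for the logistic objective, explicit
normal-equation inversion for OLS, sorted-array interpolation for percentile
intervals, and brute-force kernel evaluation for Gaussian smoothing.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def logistic_fit_reference(X, y01, cost=1.0):
    """Minimize C*sum log(1+exp(-y(w.x+b))) + ||w||^2/2 by generic BFGS."""
    X = np.asarray(X, dtype=float)
    y = 2.0 * np.asarray(y01, dtype=float) - 1.0  # {0,1} -> {-1,+1}
    n, p = X.shape

    def objective(theta):
        w, b = theta[:p], theta[p]
        z = y * (X @ w + b)
        # log(1+exp(-z)) computed stably
        loss = np.logaddexp(0.0, -z).sum()
        return cost * loss + 0.5 * w @ w

    def grad(theta):
        w, b = theta[:p], theta[p]
        z = y * (X @ w + b)
        s = -y / (1.0 + np.exp(z))
        return np.concatenate([cost * (X.T @ s) + w, [cost * s.sum()]])

    res = minimize(
        objective,
        np.zeros(p + 1),
        jac=grad,
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 5000},
    )
    return res.x[:p], res.x[p]


def ols_reference(X, y):
    """Normal equations solved by explicit matrix inversion."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.inv(X.T @ X) @ (X.T @ y)


def percentile_interval_reference(values, level):
    """Equal-tail quantiles by direct sorted-array linear interpolation."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def quantile(q):
        h = q * (n - 1)
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    alpha = (1.0 - level) / 2.0
    return quantile(alpha), quantile(1.0 - alpha)


def gaussian_smooth_reference(vol, fwhm_mm, voxel_size_mm, truncate=4.0):
    """Direct evaluation of the truncated separable Gaussian kernel.

    Convolves by explicit summation with reflective boundary handling; only
    meaningful for small volumes.
    """
    vol = np.asarray(vol, dtype=float)
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    radius = int(truncate * sigma + 0.5)
    offsets = np.arange(-radius, radius + 1)
    kernel1d = np.exp(-(offsets**2) / (2.0 * sigma**2))
    kernel1d /= kernel1d.sum()

    def reflect(i, n):
        # scipy 'reflect' mode: (d c b a | a b c d | d c b a)
        period = 2 * n
        i = np.abs(i) % period
        return np.where(i >= n, period - 1 - i, i)

    out = vol
    for axis in range(3):
        acc = np.zeros_like(out)
        n = out.shape[axis]
        idx = np.arange(n)
        for k, off in enumerate(offsets):
            src = reflect(idx + off, n)
            acc += kernel1d[k] * np.take(out, src, axis=axis)
        out = acc
    return out
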