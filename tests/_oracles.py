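"""Independent reference implementations used to cross-check the package."""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize

from genepart.reml import reml_loglik


def iid_gaussian_reml(y: np.ndarray, sigma2: float) -> float:
    """Closed-form restricted log-likelihood of i.i.d. N(mu, sigma2) with mu
    profiled out: the model V = sigma2 I, X = 1."""
    y = np.asarray(y, dtype=float)
    n = y.size
    ss = float(np.sum((y - y.mean()) ** 2))
    return -0.5 * (
        (n - 1) * math.log(2 * math.pi)
        + n * math.log(sigma2)
        + math.log(n / sigma2)
        + ss / sigma2
    )


def grid_polish_reml(y, gmats, weights=None):
    """Brute-force maximizer of the restricted likelihood: coarse grid over
    variance fractions of Var(y), then Nelder-Mead polish from the best grid
    point.  Independent of the AI-REML update path."""
    y = np.asarray(y, dtype=float)
    vp = float(np.var(y, ddof=1))
    k = len(gmats)
    fracs = np.array([0.01, 0.1, 0.25, 0.5, 0.75, 1.0, 1.5]) * vp

    def negll(theta):
        theta = np.maximum(theta, 1e-12 * vp)
        try:
            return -reml_loglik(y, list(zip(gmats, theta[:-1])), weights, theta[-1])
        except np.linalg.LinAlgError:
            return np.inf

    best, best_val = None, np.inf
    grids = np.meshgrid(*([fracs] * (k + 1)), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    for pt in pts:
        v = negll(pt)
        if v < best_val:
            best, best_val = pt, v
    res = minimize(negll, best, method="Nelder-Mead",
                   options=dict(xatol=1e-10, fatol=1e-12, maxiter=4000, maxfev=4000))
    theta = np.maximum(res.x, 1e-12 * vp)
    return theta, -res.fun


def bh_reference(p: np.ndarray) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q
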