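"""Restricted maximum likelihood for one- and two-GRM linear mixed models.

The partitioned model is

    y = 1 mu + g_S + g_notS + e,
    g_S ~ N(0, G_S s2_S),  g_notS ~ N(0, G_notS s2_notS),  e ~ N(0, D s2_e),

with D a fixed diagonal matrix of residual weights (identity, or
r^2 / (1 - r^2) from deregressed-proof reliabilities).  The simple model
collapses the two genetic terms into one all-marker GRM; the two models are
nested because G s2_g = G_S s2_g m_S / m + G_notS s2_g m_notS / m whenever
the GRMs come from one partition of the same scaled marker matrix.

Estimation is average-information (AI) REML on the variance components with
intercept-only fixed effects.  AI steps that would leave the admissible
region, or that fail to improve the restricted likelihood after
step-halving, fall back to an EM-REML step; components are clamped at a
tiny positive boundary.  Likelihood ratios are twice the difference of the
restricted log-likelihoods of the partitioned and simple models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotrf, dpotri

from .grm import GRM

log = logging.getLogger(__name__)

__all__ = [
    "VarianceFit",
    "LikelihoodRatio",
    "residual_weights",
    "reml_loglik",
    "fit_simple",
    "fit_partitioned",
    "likelihood_ratio",
    "h2_set",
    "expected_h2",
    "qc_fit",
    "FAILURE_FLAGS",
]

#: QC flags that mark a fit as unusable downstream (excluded from null
#: tables and criteria); ``near_zero_component`` is advisory only, since a
#: variance estimate at the zero boundary is a legitimate REML solution.
FAILURE_FLAGS = frozenset({"negative_lr", "variance_inflation", "not_converged"})

_NEG_LR_TOL = 1e-4


@dataclass
class VarianceFit:
    """REML estimates for one model fit.

    ``components`` maps component names to variance estimates:
    ``{"g": ...}`` for the simple model, ``{"S": ..., "notS": ...}`` for the
    partitioned model.  ``m_per_component`` carries the marker counts behind
    each GRM (used by the nested-model identity and H2 bookkeeping).
    """

    model: str
    components: dict[str, float]
    sigma2_e: float
    loglik: float
    n_iter: int
    converged: bool
    qc_flags: set[str] = field(default_factory=set)
    m_per_component: dict[str, int] = field(default_factory=dict)
    sample_variance: float = float("nan")

    @property
    def sigma2_S(self) -> float:
        return self.components["S"]

    @property
    def sigma2_notS(self) -> float:
        return self.components["notS"]

    @property
    def sigma2_g(self) -> float:
        return self.components["g"]


@dataclass
class LikelihoodRatio:
    """LR = 2 (loglik_full - loglik_null), truncated at zero for tiny
    negative values; df and p-value are attached by the empirical-null
    stage once a reference distribution is selected."""

    lr: float
    raw_lr: float
    df_used: object = None
    p_value: float | None = None
    qc_flags: set[str] = field(default_factory=set)


def residual_weights(reliabilities: np.ndarray | None, min_reliability: float = 0.01) -> np.ndarray | None:
    """Diagonal residual weights r^2 / (1 - r^2) from DRP reliabilities.

    ``None`` (reliabilities absent) means unit weights / identity D.
    Reliabilities below ``min_reliability`` or at/above 1 are rejected so
    that every weight stays positive and finite.
    """
    if reliabilities is None:
        return None
    r = np.asarray(reliabilities, dtype=float)
    if np.any(r < 0):
        raise ValueError("negative reliability")
    if np.any(r >= 1):
        raise ValueError("reliability must be < 1 (infinite weight)")
    if np.any(r < min_reliability):
        raise ValueError(f"reliability below the configured floor {min_reliability}")
    return r * r / (1.0 - r * r)


def _as_weights(weights: np.ndarray | None, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights length does not match y")
    if np.any(w <= 0):
        raise ValueError("residual weights must be positive")
    return w


def reml_loglik(
    y: np.ndarray,
    components: list[tuple[GRM | np.ndarray, float]],
    weights: np.ndarray | None = None,
    sigma2_e: float = 1.0,
) -> float:
    """Restricted log-likelihood of ``y`` with intercept-only fixed effects.

    ``components`` is a list of (GRM, variance) pairs; the residual
    covariance is diag(1 / weights) * sigma2_e.  Includes the
    -(n - 1)/2 log(2 pi) constant so that closed-form Gaussian REML values
    match exactly.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    w = _as_weights(weights, n)
    V = np.diag(sigma2_e / w)
    for G, s2 in components:
        mat = G.matrix if isinstance(G, GRM) else np.asarray(G)
        if s2 < 0:
            raise ValueError("negative variance component")
        V += s2 * mat
    try:
        c, low = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError("V is not positive definite") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    ones = np.ones(n)
    Vi_y = cho_solve((c, low), y, check_finite=False)
    Vi_1 = cho_solve((c, low), ones, check_finite=False)
    xtvx = float(ones @ Vi_1)
    yPy = float(y @ Vi_y) - float(ones @ Vi_y) ** 2 / xtvx
    return -0.5 * ((n - 1) * math.log(2.0 * math.pi) + logdet + math.log(xtvx) + yPy)


def _sym_inverse_from_chol(V: np.ndarray) -> tuple[np.ndarray, float]:
    """(V^-1, log|V|) via LAPACK Cholesky; raises on non-PD input."""
    c, info = dpotrf(V, lower=1, overwrite_a=0)
    if info != 0:
        raise np.linalg.LinAlgError("V is not positive definite")
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    vi, info = dpotri(c, lower=1)
    if info != 0:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError("inversion failed")
    vi = np.tril(vi) + np.tril(vi, -1).T
    return vi, logdet


class _REMLProblem:
    """Shared state for AI-REML over k genetic matrices plus the residual.

    Parameter vector theta = (s2_1, ..., s2_k, s2_e); matrices are the GRMs
    followed by diag(1/weights).
    """

    def __init__(self, y: np.ndarray, gmats: list[np.ndarray], weights: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        self.n = self.y.size
        self.gmats = gmats
        self.dinv = 1.0 / weights  # residual covariance diagonal per unit s2_e
        self.k = len(gmats)

    def build_V(self, theta: np.ndarray) -> np.ndarray:
        V = np.diag(theta[-1] * self.dinv)
        for j, Gm in enumerate(self.gmats):
            V += theta[j] * Gm
        return V

    def loglik_only(self, theta: np.ndarray) -> float:
        n, y = self.n, self.y
        V = self.build_V(theta)
        c, info = dpotrf(V, lower=1)
        if info != 0:
            return -np.inf
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        from scipy.linalg import solve_triangular

        z = solve_triangular(c, np.column_stack([y, np.ones(n)]), lower=True, check_finite=False)
        zy, z1 = z[:, 0], z[:, 1]
        xtvx = float(z1 @ z1)
        yPy = float(zy @ zy) - float(z1 @ zy) ** 2 / xtvx
        return -0.5 * ((n - 1) * math.log(2.0 * math.pi) + logdet + math.log(xtvx) + yPy)

    def score_ai(self, theta: np.ndarray):
        """Restricted loglik, gradient, AI matrix and EM update at theta."""
        n, y = self.n, self.y
        V = self.build_V(theta)
        Vi, logdet = _sym_inverse_from_chol(V)
        a = Vi.sum(axis=1)  # V^-1 1
        xtvx = float(a.sum())
        Vi_y = Vi @ y
        Py = Vi_y - a * (float(a @ y) / xtvx)
        yPy = float(y @ Py)
        ll = -0.5 * ((n - 1) * math.log(2.0 * math.pi) + logdet + math.log(xtvx) + yPy)

        k = self.k
        grad = np.empty(k + 1)
        T = np.empty((n, k + 1))
        quad = np.empty(k + 1)
        trPM = np.empty(k + 1)
        diag_vi = np.diag(Vi)
        for j in range(k + 1):
            if j < k:
                Gm = self.gmats[j]
                tr_vm = float(np.sum(Vi * Gm))
                aMa = float(a @ (Gm @ a))
                T[:, j] = Gm @ Py
            else:
                tr_vm = float(diag_vi @ self.dinv)
                aMa = float((a * self.dinv) @ a)
                T[:, j] = self.dinv * Py
            trPM[j] = tr_vm - aMa / xtvx
            quad[j] = float(Py @ T[:, j])
            grad[j] = -0.5 * (trPM[j] - quad[j])
        PT = Vi @ T - np.outer(a, (a @ T) / xtvx)
        AI = 0.5 * (T.T @ PT)
        em_step = theta**2 * (quad - trPM) / n
        return ll, grad, AI, em_step


def _ai_reml(
    y: np.ndarray,
    gmats: list[np.ndarray],
    weights: np.ndarray,
    start: np.ndarray,
    max_iter: int = 100,
    tol_ll: float = 1e-8,
    tol_grad: float = 1e-6,
) -> tuple[np.ndarray, float, int, bool]:
    """Maximize the restricted likelihood over non-negative components."""
    prob = _REMLProblem(y, gmats, weights)
    vp = float(np.var(y, ddof=1))
    eps = 1e-10 * vp
    theta = np.maximum(np.asarray(start, dtype=float), eps)
    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll_new, grad, AI, em_step = prob.score_ai(theta)
        # projected gradient: components pinned at the boundary with an
        # inward-negative gradient do not count against convergence
        pg = grad.copy()
        pg[(theta <= eps * 1.0001) & (grad < 0)] = 0.0
        if np.isfinite(ll) and abs(ll_new - ll) / (abs(ll) + 1.0) < tol_ll:
            ll = ll_new
            converged = True
            break
        if float(np.linalg.norm(pg)) < tol_grad:
            ll = ll_new
            converged = True
            break
        ll = ll_new
        theta = _step(prob, theta, ll, grad, AI, em_step, eps)
    final_ll = prob.loglik_only(theta)
    if final_ll < ll - 1e-9:  # pragma: no cover - defensive
        final_ll = ll
    return theta, final_ll, it, converged


def _step(prob, theta, ll, grad, AI, em_step, eps):
    """One AI update with step-halving, falling back to EM.

    Components an unconstrained AI step would drive negative are pinned at
    the boundary and the AI system is re-solved for the free components
    (active-set update), so a single boundary component does not stall the
    whole fit."""
    k1 = theta.size
    free = np.ones(k1, dtype=bool)
    delta = None
    for _ in range(k1):
        try:
            sub = AI[np.ix_(free, free)] + 1e-10 * np.eye(int(free.sum()))
            d = np.zeros(k1)
            d[free] = np.linalg.solve(sub, grad[free])
        except np.linalg.LinAlgError:
            break
        cand = theta + d
        cand[~free] = eps
        neg = cand < 0
        if not neg.any():
            delta = d
            break
        free &= ~neg
        if not free.any():
            break
    if delta is not None:
        frac = 1.0
        for _ in range(6):
            cand = theta + frac * delta
            cand[~free] = eps
            if np.all(cand >= 0):
                cand = np.maximum(cand, eps)
                ll_cand = prob.loglik_only(cand)
                if ll_cand >= ll - 1e-10:
                    return cand
            frac *= 0.5
    # EM-REML fallback: monotone, stays in the admissible region
    cand = np.maximum(theta + em_step, eps)
    if prob.loglik_only(cand) > -np.inf:
        return cand
    return theta  # pragma: no cover - defensive


def _start_values(y: np.ndarray, m_counts: list[int]) -> np.ndarray:
    """Null-hypothesis start: half the variance residual, half genetic split
    proportionally to marker counts."""
    vp = float(np.var(y, ddof=1))
    m_tot = sum(m_counts)
    genetic = [0.5 * vp * mc / m_tot for mc in m_counts]
    return np.array(genetic + [0.5 * vp])


def fit_simple(y: np.ndarray, G_all: GRM, weights: np.ndarray | None = None, **kw) -> VarianceFit:
    """REML fit of the one-genetic-component (infinitesimal) model."""
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    w = _as_weights(weights, y.size)
    theta, ll, it, conv = _ai_reml(y, [G_all.matrix], w, _start_values(y, [G_all.m_used]), **kw)
    fit = VarianceFit(
        model="simple",
        components={"g": float(theta[0])},
        sigma2_e=float(theta[1]),
        loglik=ll,
        n_iter=it,
        converged=conv,
        m_per_component={"g": G_all.m_used},
        sample_variance=float(np.var(y, ddof=1)),
    )
    if not conv:
        fit.qc_flags.add("not_converged")
    return fit


def fit_partitioned(y: np.ndarray, G_S: GRM, G_notS: GRM, weights: np.ndarray | None = None, **kw) -> VarianceFit:
    """REML fit of the two-genetic-component model for a marker partition."""
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    w = _as_weights(weights, y.size)
    start = _start_values(y, [G_S.m_used, G_notS.m_used])
    theta, ll, it, conv = _ai_reml(y, [G_S.matrix, G_notS.matrix], w, start, **kw)
    fit = VarianceFit(
        model="partitioned",
        components={"S": float(theta[0]), "notS": float(theta[1])},
        sigma2_e=float(theta[2]),
        loglik=ll,
        n_iter=it,
        converged=conv,
        m_per_component={"S": G_S.m_used, "notS": G_notS.m_used},
        sample_variance=float(np.var(y, ddof=1)),
    )
    if not conv:
        fit.qc_flags.add("not_converged")
    return fit


def likelihood_ratio(full: VarianceFit, null: VarianceFit) -> LikelihoodRatio:
    """LR = 2 (loglik_full - loglik_null).

    The partitioned model nests the simple one, so at convergence the LR is
    non-negative up to numerical noise: values in (-1e-4, 0) are truncated
    to 0, anything more negative keeps its value and is flagged."""
    if full.model != "partitioned" or null.model != "simple":
        raise ValueError("expected a partitioned full model and a simple null model")
    raw = 2.0 * (full.loglik - null.loglik)
    flags: set[str] = set()
    lr = raw
    if raw < 0:
        if raw > -_NEG_LR_TOL:
            lr = 0.0
        else:
            flags.add("negative_lr")
    return LikelihoodRatio(lr=lr, raw_lr=raw, qc_flags=flags)


def h2_set(fit: VarianceFit) -> float:
    """Proportion of genomic variance captured by the set:
    s2_S / (s2_S + s2_notS)."""
    if fit.model != "partitioned":
        raise ValueError("h2_set requires a partitioned fit")
    num, den = fit.sigma2_S, fit.sigma2_S + fit.sigma2_notS
    if den <= 0:
        raise ZeroDivisionError("both genetic components are zero; h2_set undefined")
    return float(num / den)


def expected_h2(m_S: int, m: int) -> float:
    """Infinitesimal expectation: a set of m_S of m markers accounts for
    m_S / m of the genomic variance."""
    if not (0 < m_S < m):
        raise ValueError("require 0 < m_S < m")
    return m_S / m


def qc_fit(fit: VarianceFit, sample_phenotypic_variance: float | None = None) -> set[str]:
    """Flag meaningless REML solutions.

    - ``near_zero_component``: any variance below 1e-6 x the sample
      phenotypic variance (advisory; boundary solutions are valid).
    - ``variance_inflation``: total estimated variance above 4 x the sample
      phenotypic variance.
    - ``not_converged`` propagated from the optimizer.
    Flags are added to ``fit.qc_flags`` and returned.
    """
    vp = fit.sample_variance if sample_phenotypic_variance is None else sample_phenotypic_variance
    allvar = list(fit.components.values()) + [fit.sigma2_e]
    if any(v < 1e-6 * vp for v in allvar):
        fit.qc_flags.add("near_zero_component")
    if sum(allvar) > 4.0 * vp:
        fit.qc_flags.add("variance_inflation")
    return set(fit.qc_flags)
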