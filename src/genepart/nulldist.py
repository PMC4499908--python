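"""Competitive empirical null from random gene groups.

Random gene groups generate the null distribution of the likelihood ratio
and of the explained-variance share under the competitive hypothesis that
all markers contribute alike: a target marker count is drawn uniformly,
genes are sampled uniformly without replacement until the union of their
markers reaches the target, and the two-component model is fitted to each
group.  Monotone quantile-regression curves of the 50th and 95th
percentiles of LR and H2_set against group size provide the empirical
thresholds (LR95, H2_95); a chi-square reference (df 1, df 2 or a 50:50
mixture) is selected by Kolmogorov-Smirnov distance for classical p-values
with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog
from statsmodels.stats.multitest import multipletests

from .data import DataError
from .grm import GRM, ScaledMarkerMatrix, build_full_grm, partition_grms
from .mapping import FeatureSet, MarkerGeneIndex
from .reml import (
    FAILURE_FLAGS,
    VarianceFit,
    fit_partitioned,
    fit_simple,
    h2_set,
    likelihood_ratio,
    qc_fit,
)

log = logging.getLogger(__name__)

__all__ = [
    "ThresholdCurve",
    "DfSelection",
    "sample_random_gene_group",
    "build_null_distribution",
    "fit_threshold_curve",
    "evaluate_criteria",
    "select_chi2_df",
    "pathway_pvalues",
]


# ---------------------------------------------------------------------------
# random gene groups
# ---------------------------------------------------------------------------


def sample_random_gene_group(
    rng: np.random.Generator,
    index: MarkerGeneIndex,
    max_target: int = 50_000,
    focal_genes: set[str] | None = None,
    name: str = "random",
) -> FeatureSet:
    """Draw one random gene group.

    A target marker count is drawn uniformly from {1, ..., max_target};
    genes with at least one mapped marker are then drawn uniformly without
    replacement until the unique-marker union first reaches the target.  If
    the gene universe is exhausted first, the full union is returned with
    ``exhausted=True`` and a warning.
    """
    if max_target < 1:
        raise ValueError("max_target must be >= 1")
    genes = index.mapped_genes()
    if not genes:
        raise DataError("no genes with mapped markers")
    target = int(rng.integers(1, max_target + 1))
    order = rng.permutation(len(genes))
    seen = np.zeros(index.n_markers, dtype=bool)
    picked: list[str] = []
    count = 0
    exhausted = True
    for gi in order:
        gid = genes[gi]
        picked.append(gid)
        mk = index.gene_markers[gid]
        new = mk[~seen[mk]]
        seen[new] = True
        count += new.size
        if count >= target:
            exhausted = False
            break
    if exhausted:
        log.warning("gene universe exhausted before reaching target %d (union %d)", target, count)
    focal = bool(focal_genes and set(picked) & set(focal_genes))
    return FeatureSet(
        name,
        np.nonzero(seen)[0],
        contains_focal=focal,
        genes=tuple(picked),
        target=target,
        exhausted=exhausted,
    )


def build_null_distribution(
    y: np.ndarray,
    w: ScaledMarkerMatrix,
    index: MarkerGeneIndex,
    n_groups: int,
    seed: int,
    weights: np.ndarray | None = None,
    max_target: int | None = None,
    focal_genes: set[str] | None = None,
    simple_fit: VarianceFit | None = None,
    g_all: GRM | None = None,
) -> tuple[pd.DataFrame, VarianceFit]:
    """Fit the two-component model to ``n_groups`` random gene groups.

    The simple model is fitted once and reused for every likelihood ratio.
    Per-group child seeds are spawned deterministically from ``seed``; the
    batch is bit-for-bit reproducible.  Failed fits are recorded with
    ``excluded=True``, never aborting the batch.

    Returns the null table (one row per group: group, m_S, target, h2_set,
    lr, contains_focal, converged, flags, excluded) and the simple fit.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be positive")
    if max_target is None:
        max_target = default_max_target(index)
    if g_all is None:
        g_all = build_full_grm(w)
    if simple_fit is None:
        simple_fit = fit_simple(y, g_all, weights)
    children = np.random.SeedSequence(seed).spawn(n_groups)
    rows = []
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        fs = sample_random_gene_group(rng, index, max_target, focal_genes, name=f"rg{b:05d}")
        row = {
            "group": fs.name,
            "m_S": fs.m_S,
            "target": fs.target,
            "contains_focal": fs.contains_focal,
            "h2_set": np.nan,
            "lr": np.nan,
            "raw_lr": np.nan,
            "converged": False,
            "flags": "",
            "excluded": True,
        }
        try:
            if fs.m_S >= w.m:
                raise DataError("group covers every marker")
            gs, gn = partition_grms(w, fs, g_all)
            fit = fit_partitioned(y, gs, gn, weights)
            lrt = likelihood_ratio(fit, simple_fit)
            fit.qc_flags |= lrt.qc_flags
            qc_fit(fit)
            flags = set(fit.qc_flags)
            row.update(
                h2_set=h2_set(fit),
                lr=lrt.lr,
                raw_lr=lrt.raw_lr,
                converged=fit.converged,
                flags=",".join(sorted(flags)),
                excluded=bool(flags & FAILURE_FLAGS),
            )
        except Exception as exc:  # noqa: BLE001 - per-sample failures recorded
            row["flags"] = f"error:{type(exc).__name__}"
            log.warning("group %s failed: %s", fs.name, exc)
        rows.append(row)
    return pd.DataFrame(rows), simple_fit


def default_max_target(index: MarkerGeneIndex) -> int:
    """Scale the sampling-target ceiling to the panel: one fifth of the
    mapped markers, capped at the reference 50 000."""
    return max(1, min(50_000, round(0.2 * index.n_mapped_markers)))


# ---------------------------------------------------------------------------
# monotone quantile threshold curves
# ---------------------------------------------------------------------------


@dataclass
class ThresholdCurve:
    """Monotone non-decreasing percentile threshold as a function of group
    size, piecewise linear between knots and clamped outside the fitted
    range."""

    tau: float
    statistic: str
    stratum: str
    knots: np.ndarray
    values: np.ndarray
    lam: float

    def __call__(self, sizes) -> np.ndarray | float:
        out = np.interp(np.asarray(sizes, dtype=float), self.knots, self.values)
        return float(out) if np.isscalar(sizes) else out


def _pinball(y: np.ndarray, yhat: np.ndarray, tau: float) -> float:
    r = y - yhat
    return float(np.mean(np.where(r >= 0, tau * r, (tau - 1.0) * r)))


def _hat_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """n x K piecewise-linear interpolation weights (rows sum to 1)."""
    K = knots.size
    B = np.zeros((x.size, K))
    xi = np.clip(x, knots[0], knots[-1])
    seg = np.clip(np.searchsorted(knots, xi, side="right") - 1, 0, K - 2)
    left, right = knots[seg], knots[seg + 1]
    t = np.where(right > left, (xi - left) / np.where(right > left, right - left, 1.0), 0.0)
    B[np.arange(x.size), seg] = 1.0 - t
    B[np.arange(x.size), seg + 1] += t
    return B


def _monotone_quantile_lp(x: np.ndarray, y: np.ndarray, tau: float, lam: float, knots: np.ndarray) -> np.ndarray:
    """Pinball loss + total-variation penalty on the slope, subject to a
    non-decreasing shape, solved as a linear program (HiGHS)."""
    n, K = x.size, knots.size
    B = _hat_basis(x, knots)
    h = np.diff(knots)
    # variables: theta (K), u (n), v (n), w (K-2)
    nw = max(K - 2, 0)
    nvar = K + 2 * n + nw
    cost = np.concatenate([np.zeros(K), np.full(n, tau / n), np.full(n, (1 - tau) / n), np.full(nw, lam)])
    # equality: B theta + u - v = y
    A_eq = np.zeros((n, nvar))
    A_eq[:, :K] = B
    A_eq[:, K : K + n] = np.eye(n)
    A_eq[:, K + n : K + 2 * n] = -np.eye(n)
    # inequalities: -(theta_{k+1} - theta_k) <= 0 (monotone);
    # +-(slope_{k+1} - slope_k) <= w_k (TV of the derivative)
    rows = []
    rhs = []
    for k in range(K - 1):
        r = np.zeros(nvar)
        r[k] = 1.0
        r[k + 1] = -1.0
        rows.append(r)
        rhs.append(0.0)
    for k in range(nw):
        d = np.zeros(K)
        d[k] = 1.0 / h[k]
        d[k + 1] = -1.0 / h[k] - 1.0 / h[k + 1]
        d[k + 2] = 1.0 / h[k + 1]
        for sign in (1.0, -1.0):
            r = np.zeros(nvar)
            r[:K] = sign * d
            r[K + 2 * n + k] = -1.0
            rows.append(r)
            rhs.append(0.0)
    A_ub = np.vstack(rows) if rows else None
    b_ub = np.asarray(rhs) if rows else None
    bounds = [(None, None)] * K + [(0, None)] * (2 * n + nw)
    res = linprog(cost, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - defensive
        raise RuntimeError(f"quantile LP failed: {res.message}")
    return res.x[:K]


_LAMBDA_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


def _cv_lambda(x: np.ndarray, y: np.ndarray, tau: float, knots: np.ndarray, n_folds: int = 5) -> float:
    """Pick the TV penalty by 5-fold cross-validated pinball loss.

    Folds interleave observations sorted by size, so each fold spans the
    whole size range; the grid is scaled by the response spread per unit
    size so it is dimensionless across statistics."""
    order = np.argsort(x, kind="stable")
    folds = np.empty(x.size, dtype=int)
    folds[order] = np.arange(x.size) % n_folds
    span = max(float(np.ptp(y)), 1e-12)
    best_lam, best_loss = None, np.inf
    for lam0 in _LAMBDA_GRID:
        lam = lam0 * span
        loss = 0.0
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            theta = _monotone_quantile_lp(x[tr], y[tr], tau, lam, knots)
            loss += _pinball(y[te], np.interp(np.clip(x[te], knots[0], knots[-1]), knots, theta), tau)
        if loss < best_loss - 1e-12:
            best_loss, best_lam = loss, lam
    return best_lam


def fit_threshold_curve(
    samples: pd.DataFrame,
    statistic: str = "lr",
    tau: float = 0.95,
    stratum: str = "all",
    lam: float | None = None,
    n_knots: int = 12,
    min_samples: int = 50,
) -> ThresholdCurve:
    """Fit the monotone percentile curve of ``statistic`` against group size.

    ``samples`` is a null table from :func:`build_null_distribution`;
    excluded rows are dropped, and ``stratum`` restricts to groups with
    (``focal``) or without (``non_focal``) a focal-region gene.  ``lam=None``
    selects the roughness penalty by 5-fold cross-validation.
    """
    df = samples.loc[~samples["excluded"]]
    if stratum == "focal":
        df = df.loc[df["contains_focal"]]
    elif stratum == "non_focal":
        df = df.loc[~df["contains_focal"]]
    elif stratum != "all":
        raise ValueError(f"unknown stratum {stratum!r}")
    if len(df) < min_samples:
        raise DataError(f"need >= {min_samples} unflagged samples in stratum {stratum!r}, have {len(df)}")
    x = df["m_S"].to_numpy(dtype=float)
    y = df[statistic].to_numpy(dtype=float)
    if float(np.ptp(y)) < 1e-12:  # degenerate: constant statistic
        knots = np.array([x.min(), x.max()])
        return ThresholdCurve(tau, statistic, stratum, knots, np.full(2, float(y[0])), 0.0)
    qs = np.linspace(0, 1, min(n_knots, np.unique(x).size))
    knots = np.unique(np.quantile(np.unique(x), qs))
    if knots.size < 2:
        knots = np.array([x.min() - 0.5, x.max() + 0.5])
    if lam is None:
        lam = _cv_lambda(x, y, tau, knots)
    theta = _monotone_quantile_lp(x, y, tau, lam, knots)
    theta = np.maximum.accumulate(theta)  # guard against LP round-off
    return ThresholdCurve(tau, statistic, stratum, knots, theta, float(lam))


def evaluate_criteria(
    lr: float,
    h2: float,
    m_S: int,
    lr_curve: ThresholdCurve,
    h2_curve: ThresholdCurve,
    qc_flags: set[str] | None = None,
) -> tuple[bool | None, bool | None]:
    """Dual significance criteria at the group's size (both inclusive):
    LR >= LR95(m_S) and H2_set >= H2_95(m_S).  QC-failed fits yield
    (None, None)."""
    if qc_flags and qc_flags & FAILURE_FLAGS:
        return None, None
    return bool(lr >= lr_curve(m_S)), bool(h2 >= h2_curve(m_S))


# ---------------------------------------------------------------------------
# chi-square reference and FDR
# ---------------------------------------------------------------------------


@dataclass
class DfSelection:
    """Reference distribution chosen by Kolmogorov-Smirnov distance among
    chi2(1), chi2(2) and an equal-weight mixture of the two."""

    ks: dict[str, float]
    selected: str
    mixture_weight: float = 0.5

    def sf(self, lr: np.ndarray | float) -> np.ndarray | float:
        """Upper-tail probability under the selected reference (LR = 0
        maps to p = 1)."""
        x = np.asarray(lr, dtype=float)
        if self.selected == "chi2_df1":
            p = stats.chi2.sf(x, 1)
        elif self.selected == "chi2_df2":
            p = stats.chi2.sf(x, 2)
        else:
            w = self.mixture_weight
            p = w * stats.chi2.sf(x, 1) + (1 - w) * stats.chi2.sf(x, 2)
        p = np.where(x <= 0, 1.0, p)
        return float(p) if np.isscalar(lr) else p


def select_chi2_df(lr_samples: np.ndarray, mixture_weight: float = 0.5, min_samples: int = 100) -> DfSelection:
    """Pick the chi-square reference closest (in KS distance) to the
    empirical LR distribution; ties break toward the lowest df, then the
    mixture."""
    lrs = np.asarray(lr_samples, dtype=float)
    lrs = lrs[np.isfinite(lrs)]
    if lrs.size < min_samples:
        raise DataError(f"need >= {min_samples} LR values, have {lrs.size}")
    lrs = np.maximum(lrs, 0.0)
    if float(np.ptp(lrs)) < 1e-12 and lrs.max() <= 0:
        raise DataError("degenerate all-zero LR sample")
    w = mixture_weight

    def mix_cdf(x):
        return w * stats.chi2.cdf(x, 1) + (1 - w) * stats.chi2.cdf(x, 2)

    ks = {
        "chi2_df1": float(stats.kstest(lrs, lambda x: stats.chi2.cdf(x, 1)).statistic),
        "chi2_df2": float(stats.kstest(lrs, lambda x: stats.chi2.cdf(x, 2)).statistic),
        "mixture": float(stats.kstest(lrs, mix_cdf).statistic),
    }
    return DfSelection(ks=ks, selected=_best_candidate(ks), mixture_weight=w)


def _best_candidate(ks: dict[str, float], tie_tol: float = 1e-12) -> str:
    """Argmin of the KS statistics; ties (within ``tie_tol``) break toward
    the lowest-df candidate, then the mixture."""
    order = ["chi2_df1", "chi2_df2", "mixture"]
    best = min(ks.values())
    return next(k for k in order if ks[k] <= best + tie_tol)


def pathway_pvalues(
    pathway_lrs: pd.Series | dict[str, float],
    selection: DfSelection,
    fdr_level: float = 0.10,
) -> pd.DataFrame:
    """Chi-square p-values under the selected reference with
    Benjamini-Hochberg adjustment; significant at q <= ``fdr_level``."""
    s = pd.Series(pathway_lrs, dtype=float)
    if (s < 0).any():
        raise ValueError("LR values must be non-negative (truncate first)")
    p = np.asarray(selection.sf(s.to_numpy()), dtype=float).reshape(-1)
    reject, q, _, _ = multipletests(p, alpha=fdr_level, method="fdr_bh")
    return pd.DataFrame(
        {"pathway_id": s.index, "lr": s.to_numpy(), "p_value": p, "q_value": q, "significant": q <= fdr_level}
    ).reset_index(drop=True)
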