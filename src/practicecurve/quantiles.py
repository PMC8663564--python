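"""Short-term learning via linear quantile regression on trials 1-5.

Baseline performance heterogeneity is examined by fitting, per test, a
straight line in repetition number to the pooled scores of the first five
trials at the 5th, 25th, 50th, 75th and 95th percentiles.  The intercept is
anchored at repetition 1, so it estimates baseline performance of that
percentile group, and the slope is the short-term learning rate in metric
units per repetition.

Point estimates minimise the check (pinball) loss exactly via linear
programming with a deterministic lexicographic tie-break.  Inference uses a
cluster bootstrap that resamples analysis units (repeated measures within a
unit are not independent rows); bootstrap replicates are refitted with a
fast vectorised iteratively-reweighted least-squares approximation of the
same loss.  Slope p-values are Bonferroni-adjusted over the five
percentiles, and slope homogeneity is assessed with a Wald (ANOVA-type)
chi-square test on the four successive slope differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.optimize import linprog

from .data_model import Cohort

DEFAULT_TAUS = (0.05, 0.25, 0.50, 0.75, 0.95)


def pinball_loss(t, y, intercept: float, slope: float, tau: float) -> float:
    """Check loss of the line ``intercept + slope * (t - 1)`` at level tau."""
    r = np.asarray(y, float) - (intercept + slope * (np.asarray(t, float) - 1.0))
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1) * r)))


def fit_quantile_line(t, y, tau: float) -> tuple[float, float]:
    """Exact linear quantile regression of ``y`` on repetition number ``t``.

    Minimises the pinball loss of ``y - b0 - b1 (t - 1)`` by linear
    programming, so ``b0`` is the tau-quantile line's value at the first
    repetition.  Among multiple optima the lexicographically smallest
    ``(b0, b1)`` is returned (two further LPs over the optimal face).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 points")
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    x = t - 1.0
    if np.ptp(x) == 0:
        raise ValueError("all repetition numbers identical: slope unidentifiable")
    n = len(y)

    # epigraph LP: y_i = b0 + b1 x_i + u_i - v_i, u, v >= 0
    ones = np.ones(n)
    A_eq = sparse.hstack([
        sparse.csc_matrix(np.column_stack([ones, x])),
        sparse.identity(n, format="csc"),
        -sparse.identity(n, format="csc"),
    ], format="csc")
    cost = np.concatenate([[0.0, 0.0], tau * ones, (1 - tau) * ones])
    bounds = [(None, None), (None, None)] + [(0, None)] * (2 * n)
    res = linprog(cost, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - HiGHS is reliable on feasible LPs
        raise RuntimeError(f"quantile LP failed: {res.message}")
    loss_star = res.fun
    slack = 1e-9 * (1.0 + abs(loss_star))
    loss_row = sparse.csc_matrix(cost)

    # lexicographic refinement: smallest b0, then smallest b1, on the
    # optimal face {loss <= loss*}
    e0 = np.zeros(2 * n + 2)
    e0[0] = 1.0
    res0 = linprog(e0, A_eq=A_eq, b_eq=y, A_ub=loss_row,
                   b_ub=[loss_star + slack], bounds=bounds, method="highs")
    b0 = res0.x[0] if res0.success else res.x[0]
    e1 = np.zeros(2 * n + 2)
    e1[1] = 1.0
    b0_row = sparse.csc_matrix(e0)
    res1 = linprog(e1, A_eq=A_eq, b_eq=y,
                   A_ub=sparse.vstack([loss_row, b0_row]),
                   b_ub=[loss_star + slack, b0 + slack],
                   bounds=bounds, method="highs")
    b1 = res1.x[1] if res1.success else res.x[1]
    return float(b0), float(b1)


def _irls_quantile_batch(x: np.ndarray, y: np.ndarray, weights: np.ndarray,
                         tau: float, init: tuple[float, float],
                         n_iter: int = 60, delta: float = 1e-6,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted quantile-line fits for many weight vectors at once.

    ``weights`` has shape (B, n); row b holds the multiplicity of each point
    in bootstrap replicate b.  Returns (b0, b1, ok) arrays of length B;
    ``ok`` is False where the replicate's design is degenerate.
    """
    B = weights.shape[0]
    b0 = np.full(B, init[0])
    b1 = np.full(B, init[1])
    scale = max(np.std(y), 1.0)
    eps = delta * scale
    wsum = weights.sum(axis=1)
    xbar = weights @ x / wsum
    xvar = weights @ (x ** 2) / wsum - xbar ** 2
    ok = xvar > 1e-12
    for _ in range(n_iter):
        r = y[None, :] - b0[:, None] - b1[:, None] * x[None, :]
        w = weights * np.where(r > 0, tau, 1 - tau) / np.maximum(np.abs(r), eps)
        sw = w.sum(axis=1)
        swx = w @ x
        swxx = w @ (x ** 2)
        swy = (w * y[None, :]).sum(axis=1)
        swxy = (w * y[None, :]) @ x
        det = sw * swxx - swx ** 2
        good = ok & (np.abs(det) > 1e-12)
        nb0 = np.where(good, (swxx * swy - swx * swxy) / np.where(det == 0, 1, det), b0)
        nb1 = np.where(good, (sw * swxy - swx * swy) / np.where(det == 0, 1, det), b1)
        if np.allclose(nb0, b0, atol=1e-10 * scale) and \
           np.allclose(nb1, b1, atol=1e-10 * scale):
            b0, b1 = nb0, nb1
            break
        b0, b1 = nb0, nb1
    return b0, b1, ok


@dataclass
class SlopeEqualityResult:
    statistic: float
    df: int
    p: float

    def as_tuple(self) -> tuple[float, int, float]:
        return (self.statistic, self.df, self.p)


@dataclass
class QuantileFitSet:
    """Per-percentile baseline and learning-rate estimates for one test."""

    taus: tuple[float, ...]
    table: pd.DataFrame  # one row per tau
    slope_cov: np.ndarray  # joint bootstrap covariance of the slopes
    n_points: int
    n_units: int
    n_boot: int
    n_redrawn: int = 0
    slope_equality: SlopeEqualityResult | None = None

    @property
    def slopes(self) -> np.ndarray:
        return self.table["slope"].to_numpy()

    @property
    def intercepts(self) -> np.ndarray:
        return self.table["intercept"].to_numpy()


def quantile_panel(cohort: Cohort, taus=DEFAULT_TAUS, n_boot: int = 1000,
                   seed: int = 0, max_rep: int = 5) -> QuantileFitSet:
    """Fit the five-percentile learning panel on the first ``max_rep`` trials.

    Standard errors and the joint slope covariance come from a cluster
    bootstrap over analysis units (``n_boot`` replicates, derandomised by
    ``seed``); degenerate replicates are redrawn and counted.  Slope
    p-values use the normal approximation and are Bonferroni-adjusted for
    the family of ``len(taus)`` slopes.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; standard errors will be noisy",
                      stacklevel=2)
    taus = tuple(taus)
    units = [u for u in cohort.units if u.n_reps >= 2]
    if not units:
        raise ValueError("no units with at least 2 repetitions")
    t_list, y_list, unit_ix = [], [], []
    for j, u in enumerate(units):
        k = min(u.n_reps, max_rep)
        t_list.append(u.rep_index[:k].astype(float))
        y_list.append(u.values[:k])
        unit_ix.append(np.full(k, j))
    t = np.concatenate(t_list)
    y = np.concatenate(y_list)
    unit_ix = np.concatenate(unit_ix)
    x = t - 1.0
    n_units = len(units)

    fits = {tau: fit_quantile_line(t, y, tau) for tau in taus}

    rng = np.random.default_rng(seed)
    n_redrawn = 0
    boot_slopes = np.empty((len(taus), n_boot))
    boot_intercepts = np.empty((len(taus), n_boot))
    filled = 0
    while filled < n_boot:
        todo = n_boot - filled
        counts = rng.multinomial(n_units, np.full(n_units, 1.0 / n_units),
                                 size=todo)
        weights = counts[:, unit_ix].astype(float)
        ok_all = np.ones(todo, dtype=bool)
        rep_b0 = np.empty((len(taus), todo))
        rep_b1 = np.empty((len(taus), todo))
        for k, tau in enumerate(taus):
            b0, b1, ok = _irls_quantile_batch(x, y, weights, tau, fits[tau])
            rep_b0[k], rep_b1[k] = b0, b1
            ok_all &= ok
        n_good = int(ok_all.sum())
        boot_intercepts[:, filled:filled + n_good] = rep_b0[:, ok_all]
        boot_slopes[:, filled:filled + n_good] = rep_b1[:, ok_all]
        filled += n_good
        n_redrawn += todo - n_good

    slope_cov = np.atleast_2d(np.cov(boot_slopes, ddof=1))
    z975 = stats.norm.ppf(0.975)
    rows = []
    for k, tau in enumerate(taus):
        b0, b1 = fits[tau]
        se0 = float(boot_intercepts[k].std(ddof=1))
        se1 = float(boot_slopes[k].std(ddof=1))
        p_raw = 2 * stats.norm.sf(abs(b1) / se1) if se1 > 0 else (
            1.0 if b1 == 0 else 0.0)
        rows.append({
            "tau": tau, "intercept": b0,
            "intercept_ci_low": b0 - z975 * se0,
            "intercept_ci_high": b0 + z975 * se0,
            "slope": b1, "slope_se": se1,
            "slope_ci_low": b1 - z975 * se1,
            "slope_ci_high": b1 + z975 * se1,
            "p_raw": float(p_raw),
            "p_bonferroni": float(min(1.0, p_raw * len(taus))),
        })
    return QuantileFitSet(
        taus=taus, table=pd.DataFrame(rows), slope_cov=slope_cov,
        n_points=len(y), n_units=n_units, n_boot=n_boot, n_redrawn=n_redrawn)


def slope_equality_test(fitset: QuantileFitSet) -> SlopeEqualityResult:
    """Wald (ANOVA-type) test that all percentile slopes are equal.

    Contrasts the ``k`` slopes with the ``k-1`` successive differences
    ``D``; the statistic ``(D b)' (D V D')^{-1} (D b)`` is chi-square with
    ``k-1`` degrees of freedom under slope equality.
    """
    b = fitset.slopes
    V = fitset.slope_cov
    k = len(b)
    D = np.zeros((k - 1, k))
    for i in range(k - 1):
        D[i, i], D[i, i + 1] = -1.0, 1.0
    db = D @ b
    dvd = D @ V @ D.T
    if np.linalg.cond(dvd) > 1e12:
        raise np.linalg.LinAlgError(
            "contrast covariance is singular; increase n_boot")
    W = float(db @ np.linalg.solve(dvd, db))
    p = float(stats.chi2.sf(W, k - 1))
    result = SlopeEqualityResult(statistic=W, df=k - 1, p=p)
    fitset.slope_equality = result
    return result
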