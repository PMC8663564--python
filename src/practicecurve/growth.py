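"""Learning-curve models and their comparison.

Four models of score as a function of time (repetition number minus one, or
weeks since the first test) are fitted to a selected cohort:

* linear mixed model (random intercept; 4 df),
* quadratic mixed model (adds a fixed squared-time term; 5 df),
* penalized regression spline (generalized additive model; effective df from
  the trace of the influence matrix),
* bounded-growth mixed model (6 df),

      y(t) = boundary + (y0 - boundary) * exp(-c t)

  with unit-level Gaussian random effects on ``y0`` (baseline) and
  ``boundary`` (plateau) and a fixed growth constant ``c``.

For fixed ``c`` the bounded-growth model is *linear* in the two random
effects — the design columns are ``exp(-c t)`` and ``1 - exp(-c t)`` — so
the marginal likelihood is an exact Gaussian likelihood.  Fixed effects and
the residual variance are profiled out in closed form (GLS / Woodbury), and
only ``(log c, log variance ratios)`` are optimized numerically.  No
linearization approximation is involved.

Model fit is compared by the root mean squared conditional residual (unit
random effects included via their BLUPs) and the number of (effective)
degrees of freedom.  From the bounded-growth fit, practice points
``t_p = -ln(1-p)/c`` (time at which a fraction ``p`` of the baseline-to-
boundary gap is closed) and the boundary improvement over baseline are
derived.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .data_model import Cohort
from .synthetic import mean_curve


class FitError(RuntimeError):
    """Model estimation failed to converge."""


class IdentifiabilityError(RuntimeError):
    """The growth constant collapsed to 0 or infinity; the boundary is not
    identified.  A linear model is the appropriate fallback."""


# ---------------------------------------------------------------------------
# pooled data
# ---------------------------------------------------------------------------

def _pooled(cohort: Cohort, time_axis: str):
    units = cohort.units
    if not units:
        raise ValueError("empty cohort")
    t = np.concatenate([u.time(time_axis) for u in units])
    y = np.concatenate([u.values for u in units])
    idx = np.concatenate([np.full(u.n_reps, j) for j, u in enumerate(units)])
    return y, t, idx, [u.unit_id for u in units]


# ---------------------------------------------------------------------------
# linear / quadratic mixed models
# ---------------------------------------------------------------------------

@dataclass
class MixedCurveFit:
    """Random-intercept polynomial fit (linear or quadratic time trend)."""

    name: str
    time_axis: str
    params: dict[str, float]
    var_intercept: float
    sigma2: float
    loglik: float
    rmse: float
    df: int
    n_obs: int
    n_units: int
    fitted: np.ndarray = field(repr=False, default=None)

    def predict_population(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = self.params["intercept"] + self.params["t"] * t
        if "t2" in self.params:
            out = out + self.params["t2"] * t ** 2
        return out


def _fit_polynomial_mixed(cohort: Cohort, time_axis: str,
                          degree: int) -> MixedCurveFit:
    y, t, idx, _ = _pooled(cohort, time_axis)
    cols = {"intercept": np.ones_like(t), "t": t}
    if degree == 2:
        cols["t2"] = t ** 2
    X = np.column_stack(list(cols.values()))
    name = "linear" if degree == 1 else "quadratic"
    df = 2 + degree + 1  # fixed effects + intercept variance + residual

    # degenerate guard: data on one exact population curve
    beta_ols, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_ols = y - X @ beta_ols
    if float(resid_ols @ resid_ols) < 1e-12 * max(1.0, float(y @ y)):
        return MixedCurveFit(
            name=name, time_axis=time_axis,
            params=dict(zip(cols, map(float, beta_ols))),
            var_intercept=0.0, sigma2=0.0, loglik=math.inf, rmse=0.0,
            df=df, n_obs=len(y), n_units=len(cohort.units),
            fitted=X @ beta_ols)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=idx)
        res = model.fit(reml=False, method=["lbfgs", "powell"])
    if not res.converged:
        raise FitError(f"{name} mixed model did not converge: "
                       f"{res.mle_retvals if hasattr(res, 'mle_retvals') else ''}")
    try:
        re = res.random_effects
        blup_int = np.array([float(np.asarray(re[g]).ravel()[0])
                             for g in np.unique(idx)])
    except (ValueError, np.linalg.LinAlgError):
        # intercept variance collapsed to ~0: BLUPs are all zero
        blup_int = np.zeros(len(np.unique(idx)))
    fitted = X @ res.fe_params + blup_int[idx]
    rmse = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return MixedCurveFit(
        name=name, time_axis=time_axis,
        params=dict(zip(cols, map(float, res.fe_params))),
        var_intercept=float(np.asarray(res.cov_re).ravel()[0]),
        sigma2=float(res.scale), loglik=float(res.llf), rmse=rmse,
        df=df, n_obs=len(y), n_units=len(cohort.units), fitted=fitted)


def fit_linear_mixed(cohort: Cohort, time_axis: str = "repetition"
                     ) -> MixedCurveFit:
    """Maximum-likelihood random-intercept model with a linear time trend."""
    return _fit_polynomial_mixed(cohort, time_axis, degree=1)


def fit_quadratic_mixed(cohort: Cohort, time_axis: str = "repetition"
                        ) -> MixedCurveFit:
    """As :func:`fit_linear_mixed` plus a fixed squared-time term."""
    return _fit_polynomial_mixed(cohort, time_axis, degree=2)


# ---------------------------------------------------------------------------
# penalized regression spline (GAM)
# ---------------------------------------------------------------------------

@dataclass
class SplineFit:
    """Penalized cubic regression spline of score on time.

    ``edf`` is the trace of the influence (smoother) matrix.  With
    ``unit_effects`` the additive model includes a ridge-penalized
    per-unit intercept (the random-effect representation of the grouping
    structure); both penalties are chosen by generalized cross-validation.
    """

    name: str
    time_axis: str
    knots: np.ndarray
    coefs: np.ndarray
    lam_spline: float
    lam_units: float | None
    edf: float
    edf_spline: float
    rmse: float
    gcv: float
    n_obs: int
    n_units: int

    @property
    def df(self) -> float:
        return self.edf

    def predict_population(self, t) -> np.ndarray:
        B = _bspline_basis(np.asarray(t, dtype=float), self.knots)
        return B @ self.coefs


def _bspline_basis(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Cubic B-spline design matrix on a fixed open knot vector."""
    from scipy.interpolate import BSpline
    k = 3
    n_basis = len(knots) - k - 1
    t = np.clip(t, knots[k], knots[-k - 1])
    B = np.empty((len(t), n_basis))
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        B[:, j] = BSpline(knots, coef, k)(t)
    return B


def _make_knots(t: np.ndarray, n_basis: int) -> np.ndarray:
    # equally spaced knots (P-spline): the second-difference coefficient
    # penalty then has exactly the straight line as its null space
    lo, hi = float(t.min()), float(t.max())
    step = (hi - lo) / (n_basis - 3)
    return lo + step * np.arange(-3, n_basis + 1)


def fit_spline(cohort: Cohort, time_axis: str = "repetition",
               n_basis: int = 10, unit_effects: bool = True) -> SplineFit:
    """Penalized-spline smoother with GCV-selected smoothing parameters.

    The spline coefficients carry a second-difference penalty whose null
    space is the straight line, so on linear data the effective df
    approaches 2.  With ``unit_effects=True`` (default) a ridge-penalized
    intercept per unit accounts for the grouping of repeated measures.
    """
    y, t, idx, _ = _pooled(cohort, time_axis)
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct time values for a spline")
    n, m = len(y), len(cohort.units)
    knots = _make_knots(t, n_basis)
    B = _bspline_basis(t, knots)
    D = np.diff(np.eye(n_basis), n=2, axis=0)
    S = D.T @ D
    scale = np.trace(B.T @ B) / max(np.trace(S), 1e-12)

    BtB = B.T @ B
    Bty = B.T @ y
    yty = float(y @ y)
    if unit_effects and m >= 2:
        counts = np.bincount(idx, minlength=m).astype(float)
        ZtB = np.zeros((m, n_basis))
        np.add.at(ZtB, idx, B)
        Zty = np.bincount(idx, weights=y, minlength=m)
        lam_u_grid = np.geomspace(1e-6, 1e8, 30) * n / m
    else:
        lam_u_grid = [None]

    best = None
    for lam_s in np.geomspace(1e-7, 1e9, 40) * scale:
        for lam_u in lam_u_grid:
            if lam_u is None:
                A = BtB + lam_s * S
                try:
                    coef = np.linalg.solve(A, Bty)
                except np.linalg.LinAlgError:
                    continue
                fitted = B @ coef
                edf_s = float(np.trace(np.linalg.solve(A, BtB)))
                edf = edf_s
            else:
                # Schur complement on the spline block; the unit-effect
                # block of C'C + penalty is diagonal (counts + lam_u)
                d = counts + lam_u
                Ed = ZtB / d[:, None]  # d^{-1} E with E = Z'B
                P = BtB + lam_s * S - ZtB.T @ Ed
                rhs = Bty - ZtB.T @ (Zty / d)
                try:
                    Pinv = np.linalg.inv(P)
                except np.linalg.LinAlgError:
                    continue
                coef = Pinv @ rhs
                u = (Zty - ZtB @ coef) / d
                fitted = B @ coef + u[idx]
                # edf = tr(G^{-1} C'C), expanded blockwise:
                #   tr(P^{-1} B'B) - 2 tr(P^{-1} E'd^{-1}E)
                #   + tr(P^{-1} E' diag(w/d^2) E) + sum(w/d)
                cross = float(np.einsum("ij,ji->", Pinv, ZtB.T @ Ed))
                edf_s = float(np.trace(Pinv @ BtB)) - cross
                edf = (edf_s - cross
                       + float(np.einsum("ij,ji->", Pinv,
                                         ZtB.T @ (Ed * (counts / d)[:, None])))
                       + float(np.sum(counts / d)))
            rss = float(np.sum((y - fitted) ** 2))
            if rss < 1e-16 * n * max(float(np.var(y)), 1.0):
                rss = 0.0  # interpolation-level residue: numerical zero
            if n - edf <= 0:
                continue
            gcv = n * rss / (n - edf) ** 2
            # ties (e.g. zero-noise data) resolve to the smoothest fit,
            # larger spline penalty first, then larger unit penalty
            key = (lam_s, lam_u if lam_u is not None else math.inf)
            tol = 1e-12 * (1 + abs(best[0])) if best is not None else 0.0
            if best is None or gcv < best[0] - tol \
               or (gcv <= best[0] + tol and key > best[1]):
                best = (gcv, key, lam_s, lam_u, coef, edf, edf_s, rss)
    if best is None:
        raise FitError("spline smoothing-parameter search failed")
    gcv, _, lam_s, lam_u, coef, edf, edf_s, rss = best
    return SplineFit(
        name="spline", time_axis=time_axis, knots=knots, coefs=coef,
        lam_spline=float(lam_s),
        lam_units=None if lam_u is None else float(lam_u),
        edf=float(edf), edf_spline=float(edf_s),
        rmse=float(np.sqrt(rss / n)), gcv=float(gcv), n_obs=n, n_units=m)


# ---------------------------------------------------------------------------
# bounded-growth mixed model
# ---------------------------------------------------------------------------

@dataclass
class BoundedGrowthFit:
    """Exact-ML fit of the bounded-growth mixed model (6 df)."""

    mu_y0: float
    mu_boundary: float
    c: float
    var_y0: float
    var_boundary: float
    sigma2: float
    loglik: float
    rmse: float
    time_axis: str
    n_obs: int
    n_units: int
    blups: pd.DataFrame  # unit_id, y0_i, boundary_i
    ci: dict[str, tuple[float, float]]
    df: int = 6
    grad_norm: float = 0.0
    converged: bool = True

    def predict_population(self, t) -> np.ndarray:
        return mean_curve(self.mu_y0, self.mu_boundary, self.c, t)


class _BGData:
    """Pooled arrays and per-unit sufficient statistics for the fit."""

    def __init__(self, cohort: Cohort, time_axis: str):
        y, t, idx, unit_ids = _pooled(cohort, time_axis)
        self.y, self.t, self.idx = y, t, idx
        self.unit_ids = unit_ids
        self.m = len(unit_ids)
        self.N = len(y)
        self.yy = np.bincount(idx, weights=y * y, minlength=self.m)

    def suff(self, c: float):
        """Per-unit 2x2 Gram blocks of the design [exp(-ct), 1-exp(-ct)]."""
        g = np.exp(-c * self.t)
        h = 1.0 - g
        w = self.idx
        m11 = np.bincount(w, weights=g * g, minlength=self.m)
        m12 = np.bincount(w, weights=g * h, minlength=self.m)
        m22 = np.bincount(w, weights=h * h, minlength=self.m)
        q1 = np.bincount(w, weights=g * self.y, minlength=self.m)
        q2 = np.bincount(w, weights=h * self.y, minlength=self.m)
        return g, m11, m12, m22, q1, q2


def _bg_K(m11, m12, m22, r1, r2):
    """Elementwise ``K = D (I + M D)^{-1}`` for 2x2 blocks (symmetric);
    valid for zero variance ratios.  Returns (K11, K12, K22, log det)."""
    det = (1.0 + m11 * r1) * (1.0 + m22 * r2) - m12 * m12 * r1 * r2
    if np.any(det <= 0):
        return None
    K11 = r1 * (1.0 + m22 * r2) / det
    K12 = -r1 * r2 * m12 / det
    K22 = r2 * (1.0 + m11 * r1) / det
    return K11, K12, K22, np.log(det)


def _bg_profiled(c: float, r1: float, r2: float, data: _BGData):
    """Profiled negative log-likelihood and GLS by-products.

    Uses the Woodbury identity ``(I + U D U')^{-1} = I - U D (I + M D)^{-1} U'``
    with ``M = U'U``, reduced to elementwise 2x2 algebra across units.
    """
    _, m11, m12, m22, q1, q2 = data.suff(c)
    Ks = _bg_K(m11, m12, m22, r1, r2)
    if Ks is None:
        return None
    K11, K12, K22, logdet = Ks
    # T = M K ;  A_i = M - T M ;  rhs_i = q - T q ;  quad_i = yy - q K q
    T11 = m11 * K11 + m12 * K12
    T12 = m11 * K12 + m12 * K22
    T21 = m12 * K11 + m22 * K12
    T22 = m12 * K12 + m22 * K22
    A = np.array([
        [np.sum(m11 - (T11 * m11 + T12 * m12)),
         np.sum(m12 - (T11 * m12 + T12 * m22))],
        [np.sum(m12 - (T21 * m11 + T22 * m12)),
         np.sum(m22 - (T21 * m12 + T22 * m22))],
    ])
    rhs = np.array([np.sum(q1 - (T11 * q1 + T12 * q2)),
                    np.sum(q2 - (T21 * q1 + T22 * q2))])
    quad_yy = float(np.sum(data.yy - (K11 * q1 * q1 + 2 * K12 * q1 * q2
                                      + K22 * q2 * q2)))
    try:
        beta = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        return None
    N = data.N
    rss = quad_yy - 2 * beta @ rhs + beta @ A @ beta
    rss = max(rss, 1e-300)
    sigma2 = rss / N
    nll = 0.5 * (N * math.log(2 * math.pi * sigma2) + float(np.sum(logdet)) + N)
    return nll, beta, sigma2, A


def fit_bounded_growth(cohort: Cohort, time_axis: str = "repetition",
                       zero_variances: bool = False,
                       grad_tol: float = 1e-3) -> BoundedGrowthFit:
    """Exact maximum-likelihood fit of the bounded-growth mixed model.

    Conditional on ``c`` the model is linear in the random baseline and
    boundary, so the marginal likelihood is evaluated exactly; fixed
    effects and the residual variance are profiled out and the optimizer
    works on ``(log c, log var_y0/sigma2, log var_boundary/sigma2)``.  With
    ``zero_variances=True`` both variance ratios are pinned at zero, which
    reduces the fit to pooled nonlinear least squares over ``c``.

    Raises :class:`IdentifiabilityError` when ``c`` runs to its search
    bounds (flat or instantaneous learning leaves the boundary
    unidentified) and :class:`FitError` when the optimizer exits with a
    large likelihood gradient.
    """
    units = cohort.units
    if len(units) < 1:
        raise ValueError("empty cohort")
    data = _BGData(cohort, time_axis)

    t_scale = float(np.median([u.time(time_axis)[-1] if u.n_reps else 1.0
                               for u in units]))
    t_scale = max(t_scale, 1e-9)
    c_lo, c_hi = 1e-3 / t_scale, 1e3 / t_scale

    # initialization: baseline from first scores, boundary from late scores,
    # c from a log-grid profile of the likelihood
    c_grid = np.geomspace(0.05 / t_scale, 30.0 / t_scale, 50)
    r_init = (0.0, 0.0) if zero_variances else (1.0, 1.0)
    grid_nll = []
    for c in c_grid:
        prof = _bg_profiled(c, *r_init, data)
        grid_nll.append(math.inf if prof is None else prof[0])
    c0 = float(c_grid[int(np.argmin(grid_nll))])

    if zero_variances:
        res = optimize.minimize_scalar(
            lambda lc: _bg_profiled(math.exp(lc), 0.0, 0.0, data)[0],
            bracket=(math.log(c0) - 0.7, math.log(c0), math.log(c0) + 0.7)
            if c_grid[0] < c0 < c_grid[-1] else None,
            bounds=(math.log(c_lo), math.log(c_hi)), method="bounded",
            options={"xatol": 1e-12})
        theta = np.array([res.x, -math.inf, -math.inf])
        c_hat, r1, r2 = math.exp(res.x), 0.0, 0.0
        grad_norm = 0.0
        converged = True
    else:
        s_lo, s_hi = -30.0, 12.0

        def nll(theta):
            c = math.exp(theta[0])
            prof = _bg_profiled(c, math.exp(theta[1]), math.exp(theta[2]),
                                data)
            return 1e12 if prof is None else prof[0]

        x0 = np.array([math.log(c0), 0.0, 0.0])
        bounds = [(math.log(c_lo), math.log(c_hi)), (s_lo, s_hi), (s_lo, s_hi)]
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 200, "ftol": 1e-12,
                                         "gtol": 1e-8})
        theta = res.x
        # polish with a derivative-free pass; L-BFGS-B's finite-difference
        # gradient can stall near a variance boundary
        res2 = optimize.minimize(nll, theta, method="Nelder-Mead",
                                 options={"maxiter": 2000, "xatol": 1e-10,
                                          "fatol": 1e-12})
        if res2.fun <= res.fun:
            theta = res2.x
        theta[0] = min(max(theta[0], math.log(c_lo)), math.log(c_hi))
        c_hat = math.exp(theta[0])
        r1, r2 = math.exp(theta[1]), math.exp(theta[2])
        sigma2_hat = _bg_profiled(c_hat, r1, r2, data)[2]
        if sigma2_hat < 1e-10 * (float(np.var(data.y)) + 1.0):
            # perfect interpolation: the likelihood is unbounded along
            # sigma2 -> 0, so a gradient check is meaningless
            grad_norm = 0.0
            converged = True
        else:
            grad = optimize.approx_fprime(theta, nll, 1e-6)
            # ignore gradient components of variance ratios pinned at ~zero
            active = [True, theta[1] > s_lo + 1.0, theta[2] > s_lo + 1.0]
            grad_norm = float(np.max(np.abs(grad[active])))
            converged = grad_norm < grad_tol * max(1.0, abs(nll(theta)))
            if not converged:
                raise FitError(
                    f"bounded-growth optimizer exited with gradient norm "
                    f"{grad_norm:.3g} (theta={theta})")

    nll_opt = _bg_profiled(c_hat, r1, r2, data)[0]
    at_bound = not (c_lo * 1.0001 < c_hat < c_hi * 0.9999)
    edge = min(_bg_profiled(c_lo, r1, r2, data)[0],
               _bg_profiled(c_hi, r1, r2, data)[0])
    if at_bound or edge - nll_opt < 2.0:
        # flat (c ~ 0) or instantaneous (c ~ inf) learning: the likelihood
        # carries no information on c and the boundary is unidentified
        raise IdentifiabilityError(
            f"growth constant is unidentified (c={c_hat:.3g} per "
            f"{time_axis}); fit a linear model instead")

    nll_val, beta, sigma2, A = _bg_profiled(c_hat, r1, r2, data)
    N = data.N
    mu_y0, mu_boundary = float(beta[0]), float(beta[1])
    var_y0, var_boundary = r1 * sigma2, r2 * sigma2

    # BLUPs (b_i = D U'(I + U D U')^{-1} resid_i via Woodbury, i.e.
    # K q_resid with q_resid = q - M beta) and conditional residuals
    g, m11, m12, m22, q1, q2 = data.suff(c_hat)
    K11, K12, K22, _ = _bg_K(m11, m12, m22, r1, r2)
    qr1 = q1 - (m11 * beta[0] + m12 * beta[1])
    qr2 = q2 - (m12 * beta[0] + m22 * beta[1])
    b1 = K11 * qr1 + K12 * qr2
    b2 = K12 * qr1 + K22 * qr2
    blups = pd.DataFrame({
        "unit_id": data.unit_ids,
        "y0_i": mu_y0 + b1,
        "boundary_i": mu_boundary + b2,
    })
    idx = data.idx
    cond = g * (beta[0] + b1[idx]) + (1.0 - g) * (beta[1] + b2[idx])
    rmse = float(np.sqrt(np.mean((data.y - cond) ** 2)))

    # Wald CIs: GLS covariance for the fixed effects; profile-likelihood
    # curvature in log c for the growth constant
    cov_beta = sigma2 * np.linalg.inv(A)
    z = stats.norm.ppf(0.975)
    ci = {
        "mu_y0": (mu_y0 - z * math.sqrt(cov_beta[0, 0]),
                  mu_y0 + z * math.sqrt(cov_beta[0, 0])),
        "mu_boundary": (mu_boundary - z * math.sqrt(cov_beta[1, 1]),
                        mu_boundary + z * math.sqrt(cov_beta[1, 1])),
    }
    h = 1e-4

    def prof_c(lc):
        out = _bg_profiled(math.exp(lc), r1, r2, data)
        return math.inf if out is None else out[0]

    lc = math.log(c_hat)
    d2 = (prof_c(lc + h) - 2 * prof_c(lc) + prof_c(lc - h)) / h ** 2
    if d2 > 0:
        se_lc = 1.0 / math.sqrt(d2)
        ci["c"] = (c_hat * math.exp(-z * se_lc), c_hat * math.exp(z * se_lc))
    else:
        ci["c"] = (float("nan"), float("nan"))

    return BoundedGrowthFit(
        mu_y0=mu_y0, mu_boundary=mu_boundary, c=float(c_hat),
        var_y0=float(var_y0), var_boundary=float(var_boundary),
        sigma2=float(sigma2), loglik=float(-nll_val), rmse=rmse,
        time_axis=time_axis, n_obs=N, n_units=len(units), blups=blups,
        ci=ci, grad_norm=grad_norm, converged=converged)


# ---------------------------------------------------------------------------
# comparison and derived practice metrics
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    table: pd.DataFrame  # name, rmse, df
    best: str

    def rmse_of(self, name: str) -> float:
        return float(self.table.set_index("name").loc[name, "rmse"])


def compare_models(fits: dict) -> ModelComparison:
    """RMSE / (effective) df table over the four models; best = lowest RMSE,
    ties broken by fewest df."""
    expected = {"linear", "quadratic", "spline", "bounded"}
    if set(fits) != expected:
        raise ValueError(f"need exactly the fits {sorted(expected)}, "
                         f"got {sorted(fits)}")
    n_obs = {f.n_obs for f in fits.values()}
    if len(n_obs) != 1:
        raise ValueError("fits come from different cohorts (n_obs differ)")
    rows = [{"name": name, "rmse": float(f.rmse), "df": float(f.df)}
            for name, f in fits.items()]
    table = pd.DataFrame(rows).sort_values(["rmse", "df"]).reset_index(drop=True)
    return ModelComparison(table=table, best=str(table.iloc[0]["name"]))


@dataclass
class PracticeMetrics:
    """Derived summaries of the bounded-growth fit."""

    t50: float
    t90: float
    t50_rounded: int
    t90_rounded: int
    time_axis: str
    pct_improvement: tuple[float, float, float]  # subject-level mean + CI
    pct_improvement_fixed: tuple[float, float, float]  # fixed-effect ratio + CI
    tangent_slope_at: dict[float, float]


def practice_point(c: float, p: float) -> float:
    """Time at which a fraction ``p`` of the baseline-boundary gap is closed."""
    if c <= 0:
        raise ValueError("practice points require a positive growth constant")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    return -math.log(1.0 - p) / c


def tangent_slope(fit: BoundedGrowthFit, t: float) -> float:
    """Instantaneous improvement rate m(t) = c (boundary - y0) exp(-c t)."""
    return fit.c * (fit.mu_boundary - fit.mu_y0) * math.exp(-fit.c * t)


def practice_metrics(fit: BoundedGrowthFit, levels=(0.5, 0.9),
                     tangent_at=(0.0,)) -> PracticeMetrics:
    """Practice points, boundary improvement and tangent slopes.

    The percent improvement over baseline is reported two ways: the mean of
    per-unit BLUP ratios ``100 (boundary_i - y0_i)/y0_i`` with a t-based CI
    (subject-level averaging), and the fixed-effect ratio
    ``100 (mu_boundary - mu_y0)/mu_y0`` with a delta-method CI.
    """
    if fit.c <= 0:
        raise ValueError("practice metrics undefined for c <= 0")
    pts = {p: practice_point(fit.c, p) for p in levels}
    t50 = pts.get(0.5, practice_point(fit.c, 0.5))
    t90 = pts.get(0.9, practice_point(fit.c, 0.9))

    ratios = 100.0 * (fit.blups["boundary_i"] - fit.blups["y0_i"]) \
        / fit.blups["y0_i"]
    ratios = ratios.to_numpy()
    n = len(ratios)
    m = float(ratios.mean())
    if n > 1:
        half = stats.t.ppf(0.975, n - 1) * ratios.std(ddof=1) / math.sqrt(n)
    else:
        half = float("nan")
    subject_ci = (m, m - half, m + half)

    # delta method on the fixed-effect ratio g = 100 (b - a)/a
    a, b = fit.mu_y0, fit.mu_boundary
    ga = float(100.0 * (b - a) / a)
    sa = (fit.ci["mu_y0"][1] - fit.ci["mu_y0"][0]) / (2 * stats.norm.ppf(0.975))
    sb = (fit.ci["mu_boundary"][1] - fit.ci["mu_boundary"][0]) \
        / (2 * stats.norm.ppf(0.975))
    grad = np.array([-100.0 * b / a ** 2, 100.0 / a])
    se_g = math.sqrt(grad[0] ** 2 * sa ** 2 + grad[1] ** 2 * sb ** 2)
    z = stats.norm.ppf(0.975)
    fixed_ci = (ga, ga - z * se_g, ga + z * se_g)

    return PracticeMetrics(
        t50=t50, t90=t90,
        t50_rounded=int(round(t50)), t90_rounded=int(round(t90)),
        time_axis=fit.time_axis,
        pct_improvement=subject_ci,
        pct_improvement_fixed=fixed_ci,
        tangent_slope_at={float(t): tangent_slope(fit, t) for t in tangent_at},
    )
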