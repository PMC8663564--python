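import math
import shutil
import subprocess
from types import SimpleNamespace

import numpy as np
import pytest

import practicecurve as pc
from practicecurve.data_model import Cohort
from practicecurve.growth import IdentifiabilityError, _BGData, _bg_profiled

from conftest import curve_cohort, make_unit


def random_intercept_cohort(n_units=100, beta0=5.0, beta1=0.8, sd_u=2.0,
                            sd_e=1.0, n_reps=8, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(float(n_reps))
    units = []
    for i in range(n_units):
        y = beta0 + beta1 * t + rng.normal(0, sd_u) + rng.normal(0, sd_e, n_reps)
        units.append(make_unit(y, unit_id=f"u{i}", t_weeks=t))
    return Cohort(units)


def lmm_profile_oracle(cohort, n_grid=4001):
    """Brute-force ML for the random-intercept linear model.

    Profiles the fixed effects (GLS) and residual variance in closed form on
    a fine grid of the variance ratio lambda = sd_u^2/sd_e^2, then refines
    around the grid optimum.
    """
    y = np.concatenate([u.values for u in cohort.units])
    t = np.concatenate([u.t_rep for u in cohort.units])
    sizes = [u.n_reps for u in cohort.units]
    N = len(y)

    def profiled_nll(lam):
        # V_i = I + lam J; V_i^{-1} = I - (lam/(1+lam n_i)) J
        A = np.zeros((2, 2))
        rhs = np.zeros(2)
        quad = 0.0
        logdet = 0.0
        pos = 0
        for n_i in sizes:
            s = slice(pos, pos + n_i)
            pos += n_i
            X = np.column_stack([np.ones(n_i), t[s]])
            w = lam / (1 + lam * n_i)
            Xs, ys = X.sum(axis=0), y[s].sum()
            A += X.T @ X - w * np.outer(Xs, Xs)
            rhs += X.T @ y[s] - w * Xs * ys
            quad += y[s] @ y[s] - w * ys ** 2
            logdet += math.log(1 + lam * n_i)
        beta = np.linalg.solve(A, rhs)
        rss = quad - 2 * beta @ rhs + beta @ A @ beta
        s2 = rss / N
        return 0.5 * (N * math.log(2 * math.pi * s2) + logdet + N), beta, s2

    grid = np.concatenate([[0.0], np.geomspace(1e-4, 1e3, n_grid)])
    nlls = [profiled_nll(g)[0] for g in grid]
    k = int(np.argmin(nlls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(lambda g: profiled_nll(g)[0], bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-12})
    lam = res.x
    nll, beta, s2 = profiled_nll(lam)
    return {"beta": beta, "sigma2": s2, "var_u": lam * s2, "loglik": -nll}


class TestLinearQuadraticMixed:
    def test_noiseless_common_line_recovered_exactly(self):
        cohort = curve_cohort(n_units=10, y0=5.0, boundary=5.0, c=0.0)
        # all units on y = 5 (flat line)
        fit = pc.fit_linear_mixed(cohort)
        assert fit.params["intercept"] == pytest.approx(5.0)
        assert fit.params["t"] == pytest.approx(0.0, abs=1e-10)
        assert fit.rmse == 0.0 and fit.var_intercept == 0.0
        assert fit.df == 4

    def test_matches_profile_likelihood_oracle(self):
        cohort = random_intercept_cohort(n_units=100, seed=5)
        fit = pc.fit_linear_mixed(cohort)
        oracle = lmm_profile_oracle(cohort)
        assert fit.params["intercept"] == pytest.approx(oracle["beta"][0],
                                                        abs=1e-4)
        assert fit.params["t"] == pytest.approx(oracle["beta"][1], abs=1e-4)
        assert fit.var_intercept == pytest.approx(oracle["var_u"], rel=1e-3)
        assert fit.sigma2 == pytest.approx(oracle["sigma2"], rel=1e-3)
        assert fit.loglik == pytest.approx(oracle["loglik"], abs=1e-3)

    def test_exact_parabola_recovered(self):
        t = np.arange(6.0)
        units = [make_unit(1.0 + 2.0 * t - 0.25 * t ** 2, unit_id=f"u{i}",
                           t_weeks=t) for i in range(8)]
        fit = pc.fit_quadratic_mixed(Cohort(units))
        assert fit.params["t2"] == pytest.approx(-0.25)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)
        assert fit.df == 5

    def test_quadratic_improves_on_linear_for_bounded_growth_data(
            self, esdmt_selected):
        lin = pc.fit_linear_mixed(esdmt_selected)
        quad = pc.fit_quadratic_mixed(esdmt_selected)
        assert quad.rmse < lin.rmse
        assert quad.loglik >= lin.loglik  # nested ML models


class TestSpline:
    def test_linear_data_uses_about_two_effective_df(self):
        rng = np.random.default_rng(0)
        t = np.arange(10.0)
        units = [make_unit(1.0 + 0.5 * t, unit_id=f"u{i}", t_weeks=t)
                 for i in range(5)]
        for unit_effects in (False, True):
            fit = pc.fit_spline(Cohort(units), unit_effects=unit_effects)
            assert fit.edf == pytest.approx(2.0, abs=0.1)
            pred = fit.predict_population(t)
            assert np.allclose(pred, 1.0 + 0.5 * t, atol=1e-6)

    def test_tracks_exponential_shape_better_than_linear_model(self):
        cohort = curve_cohort(n_units=12, y0=10, boundary=20, c=0.35,
                              n_reps=12)
        spline = pc.fit_spline(cohort)
        linear = pc.fit_linear_mixed(cohort)
        assert spline.rmse < linear.rmse

    def test_needs_four_distinct_times(self):
        t = np.array([0.0, 1.0, 2.0])
        units = [make_unit([1, 2, 3.0], unit_id=f"u{i}", t_weeks=t)
                 for i in range(5)]
        with pytest.raises(ValueError, match="distinct"):
            pc.fit_spline(Cohort(units))


def pooled_nls_grid_oracle(cohort, time_axis="repetition", n_grid=3000):
    """Pooled nonlinear least squares by brute force: fine grid over c with
    the closed-form linear subfit for (y0, boundary)."""
    t = np.concatenate([u.time(time_axis) for u in cohort.units])
    y = np.concatenate([u.values for u in cohort.units])

    def rss_at(c):
        g = np.exp(-c * t)
        X = np.column_stack([g, 1 - g])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), beta

    grid = np.geomspace(1e-3, 10.0, n_grid)
    rss = [rss_at(c)[0] for c in grid]
    k = int(np.argmin(rss))
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(lambda c: rss_at(c)[0],
                          bounds=(grid[max(k - 1, 0)], grid[min(k + 1, n_grid - 1)]),
                          method="bounded", options={"xatol": 1e-14})
    best_rss, beta = rss_at(res.x)
    return {"c": float(res.x), "y0": float(beta[0]), "boundary": float(beta[1]),
            "rss": best_rss}


class TestBoundedGrowth:
    def test_single_noiseless_unit_recovered_exactly(self):
        cohort = curve_cohort(n_units=1, y0=10.0, boundary=20.0, c=math.log(2),
                              n_reps=6)
        fit = pc.fit_bounded_growth(cohort, zero_variances=True)
        assert fit.mu_y0 == pytest.approx(10.0, abs=1e-6)
        assert fit.mu_boundary == pytest.approx(20.0, abs=1e-6)
        assert fit.c == pytest.approx(math.log(2), rel=1e-6)
        assert fit.rmse < 1e-6

    def test_zero_variance_fit_equals_pooled_nls_oracle(self):
        cohort = curve_cohort(n_units=20, y0=10.0, boundary=20.0, c=0.4,
                              n_reps=10, noise_sd=1.0, seed=8)
        fit = pc.fit_bounded_growth(cohort, zero_variances=True)
        oracle = pooled_nls_grid_oracle(cohort)
        assert fit.c == pytest.approx(oracle["c"], rel=1e-6)
        assert fit.mu_y0 == pytest.approx(oracle["y0"], rel=1e-6)
        assert fit.mu_boundary == pytest.approx(oracle["boundary"], rel=1e-6)
        assert fit.var_y0 == 0.0 and fit.var_boundary == 0.0

    def test_noise_free_cohort_recovers_parameters_to_six_digits(self):
        cohort = curve_cohort(n_units=15, y0=41.0, boundary=57.7,
                              c=math.log(2) / 11, n_reps=30)
        fit = pc.fit_bounded_growth(cohort)
        assert fit.mu_y0 == pytest.approx(41.0, rel=1e-6)
        assert fit.mu_boundary == pytest.approx(57.7, rel=1e-6)
        assert fit.c == pytest.approx(math.log(2) / 11, rel=1e-6)

    def test_recovers_simulation_truth(self, esdmt_selected):
        fit = pc.fit_bounded_growth(esdmt_selected)
        assert fit.mu_y0 == pytest.approx(40.0, rel=0.05)
        assert fit.mu_boundary == pytest.approx(58.0, rel=0.05)
        assert fit.c == pytest.approx(0.06, rel=0.15)
        assert fit.df == 6
        assert fit.ci["mu_y0"][0] < fit.mu_y0 < fit.ci["mu_y0"][1]

    def test_blups_shrink_toward_fixed_effects(self, esdmt_selected):
        fit = pc.fit_bounded_growth(esdmt_selected)
        assert abs(fit.blups["y0_i"].mean() - fit.mu_y0) < 1.0
        assert fit.blups["y0_i"].std() < 2.0 * math.sqrt(fit.var_y0) + 1.0

    def test_flat_data_raises_identifiability_error(self):
        rng = np.random.default_rng(3)
        t = np.arange(12.0)
        units = [make_unit(30 + rng.normal(0, 1, 12), unit_id=f"u{i}",
                           t_weeks=t) for i in range(25)]
        with pytest.raises(IdentifiabilityError, match="linear"):
            pc.fit_bounded_growth(Cohort(units), zero_variances=True)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_exact_ml_is_no_worse_than_nlme(self, tmp_path, esdmt_selected):
        """Independent cross-check: R's nlme fits the same model by
        linearization; our exact marginal likelihood at our optimum must be
        at least as high as at nlme's solution, and the estimates must
        agree to a few percent."""
        csv = tmp_path / "bg.csv"
        esdmt_selected.write_csv(csv)
        script = tmp_path / "bg.R"
        script.write_text(f'''
suppressMessages(library(nlme))
d <- read.csv("{csv}")
d$t <- ave(d$repetition_index, d$unit_id, FUN=function(x) x - 1)
fm <- nlme(value ~ b + (a - b) * exp(-c * t), fixed = a + b + c ~ 1,
  random = pdDiag(a + b ~ 1), groups = ~ unit_id,
  start = c(a=40, b=55, c=0.1), data = d, method = "ML",
  control = nlmeControl(maxIter=200, msMaxIter=200))
fe <- fixef(fm); vc <- VarCorr(fm)
cat(fe["a"], fe["b"], fe["c"], as.numeric(vc["a","Variance"]),
    as.numeric(vc["b","Variance"]), fm$sigma^2, "\\n")
''')
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=600)
        assert out.returncode == 0, out.stderr
        a, b, c, va, vb, s2 = map(float, out.stdout.split())
        fit = pc.fit_bounded_growth(esdmt_selected)
        assert fit.mu_y0 == pytest.approx(a, rel=0.03)
        assert fit.mu_boundary == pytest.approx(b, rel=0.05)
        assert fit.c == pytest.approx(c, rel=0.2)
        # exact marginal log-likelihood at our optimum >= at nlme's point
        data = _BGData(esdmt_selected, "repetition")
        nll_at_nlme = _bg_profiled(c, va / s2, vb / s2, data)[0]
        assert -fit.loglik <= nll_at_nlme + 1e-6


class TestCompareModels:
    def test_requires_all_four_fits(self):
        with pytest.raises(ValueError):
            pc.compare_models({"linear": SimpleNamespace(rmse=1, df=4, n_obs=9)})

    def test_mismatched_cohorts_rejected(self):
        fits = {n: SimpleNamespace(rmse=1.0, df=4, n_obs=10)
                for n in ("linear", "quadratic", "spline")}
        fits["bounded"] = SimpleNamespace(rmse=1.0, df=6, n_obs=11)
        with pytest.raises(ValueError, match="different"):
            pc.compare_models(fits)

    def test_ties_break_toward_fewest_df(self):
        fits = {
            "linear": SimpleNamespace(rmse=0.0, df=4, n_obs=10),
            "quadratic": SimpleNamespace(rmse=0.0, df=5, n_obs=10),
            "spline": SimpleNamespace(rmse=0.0, df=2.0, n_obs=10),
            "bounded": SimpleNamespace(rmse=0.0, df=6, n_obs=10),
        }
        assert pc.compare_models(fits).best == "spline"

    def test_bounded_growth_data_reproduces_reported_ordering(
            self, esdmt_selected):
        fits = {
            "linear": pc.fit_linear_mixed(esdmt_selected),
            "quadratic": pc.fit_quadratic_mixed(esdmt_selected),
            "spline": pc.fit_spline(esdmt_selected),
            "bounded": pc.fit_bounded_growth(esdmt_selected),
        }
        comp = pc.compare_models(fits)
        assert comp.best == "bounded"
        assert fits["bounded"].rmse < fits["spline"].rmse
        assert fits["spline"].rmse <= fits["quadratic"].rmse
        assert fits["quadratic"].rmse < fits["linear"].rmse


class TestPracticeMetrics:
    def test_practice_point_identities(self):
        assert pc.practice_point(math.log(2), 0.5) == pytest.approx(1.0)
        for c in (0.01, 0.0630, 1.7):
            t50 = pc.practice_point(c, 0.5)
            t90 = pc.practice_point(c, 0.9)
            assert t90 / t50 == pytest.approx(math.log(10) / math.log(2),
                                              rel=1e-14)
            for p in (0.1, 0.5, 0.9, 0.99):
                assert pc.practice_point(c, p) == pytest.approx(
                    -math.log(1 - p) / c, rel=1e-15)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            pc.practice_point(0.0, 0.5)
        with pytest.raises(ValueError):
            pc.practice_point(1.0, 1.0)

    def test_tangent_slope_positive_and_decreasing_for_growth(
            self, esdmt_selected):
        fit = pc.fit_bounded_growth(esdmt_selected)
        ts = np.linspace(0, 40, 30)
        slopes = [pc.tangent_slope(fit, t) for t in ts]
        assert all(s > 0 for s in slopes)
        assert all(a > b for a, b in zip(slopes, slopes[1:]))
        assert pc.tangent_slope(fit, 0.0) == pytest.approx(
            fit.c * (fit.mu_boundary - fit.mu_y0))

    def test_reported_improvements_from_study_scale_fit(self, esdmt_selected):
        fit = pc.fit_bounded_growth(esdmt_selected)
        metrics = pc.practice_metrics(fit)
        expected_fixed = 100 * (fit.mu_boundary - fit.mu_y0) / fit.mu_y0
        assert metrics.pct_improvement_fixed[0] == pytest.approx(expected_fixed)
        assert metrics.pct_improvement[1] < metrics.pct_improvement[0] \
            < metrics.pct_improvement[2]
        assert metrics.t50_rounded == round(metrics.t50)
        assert metrics.t90 / metrics.t50 == pytest.approx(
            math.log(10) / math.log(2), rel=1e-12)
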