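"""Fit and compare the four learning-curve models.

The bounded-growth mixed model y(t) = boundary + (y0 - boundary) exp(-c t)
treats each unit's baseline y0 and plateau (boundary) as Gaussian random
effects and the growth constant c as fixed.  It is compared against a linear
mixed model, a quadratic mixed model and a penalized spline by the root mean
squared conditional residual and the (effective) degrees of freedom.
"""

import practicecurve as pc

cohort, _ = pc.simulate_cohort(pc.study_config("e-SDMT"), seed=3)
selected, _ = pc.select_units(cohort)

fits = {
    "linear": pc.fit_linear_mixed(selected),
    "quadratic": pc.fit_quadratic_mixed(selected),
    "spline": pc.fit_spline(selected),
    "bounded": pc.fit_bounded_growth(selected),
}
comparison = pc.compare_models(fits)
print(comparison.table.to_string(index=False,
                                 float_format=lambda v: f"{v:.2f}"))
print(f"best model by RMSE: {comparison.best}\n")

bg = fits["bounded"]
print(f"baseline  y0       = {bg.mu_y0:.1f} "
      f"(95% CI {bg.ci['mu_y0'][0]:.1f} to {bg.ci['mu_y0'][1]:.1f})")
print(f"boundary           = {bg.mu_boundary:.1f} "
      f"(95% CI {bg.ci['mu_boundary'][0]:.1f} to {bg.ci['mu_boundary'][1]:.1f})")
print(f"growth constant c  = {bg.c:.4f} per repetition")

metrics = pc.practice_metrics(bg)
print(f"\n50% of the practice effect reached after {metrics.t50:.1f} "
      f"repetitions (~{metrics.t50_rounded}), 90% after {metrics.t90:.1f} "
      f"(~{metrics.t90_rounded})")
m, lo, hi = metrics.pct_improvement
print(f"boundary improvement over baseline: {m:.1f}% "
      f"(95% CI {lo:.1f}% to {hi:.1f}%, mean of per-unit BLUP ratios)")
m, lo, hi = metrics.pct_improvement_fixed
print(f"fixed-effect ratio: {m:.1f}% (95% CI {lo:.1f}% to {hi:.1f}%)")
# The practice points say how many repetitions a trial would need to
# discard before scores stop being dominated by practice gains.
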