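"""First/fifth/last score comparisons, confounder regression, correlations.

Improvements up to the fifth score are attributed to short-term learning
(participants getting acquainted with a test); improvements from the fifth
score onward indicate long-term practice.  Percent changes are computed per
unit and then averaged, with t-based 95% confidence intervals.  The
fifth-to-last difference is additionally regressed on age, first score,
fifth score and the log-transformed number of repetitions: a positive,
significant repetition coefficient is the second indicator of a long-term
practice effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import Cohort
from .registry import Direction


@dataclass(frozen=True)
class ScoreTriple:
    """First, fifth and last score of one unit (needs >= 5 repetitions)."""

    unit_id: str
    first: float
    fifth: float
    last: float
    n_reps: int
    age_years: float | None = None


@dataclass(frozen=True)
class MeanWithCI:
    mean: float
    ci_low: float
    ci_high: float
    n: int

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mean, self.ci_low, self.ci_high)


@dataclass(frozen=True)
class ImprovementSummary:
    """Mean per-unit percent changes between first, fifth and last scores.

    Signs are kept as observed: for a lower-is-better metric a negative
    percent change is an improvement.  ``mean_abs_1_to_last`` is the mean
    raw difference in metric units.
    """

    mean_pct_1_to_5: MeanWithCI
    mean_pct_5_to_last: MeanWithCI
    mean_pct_1_to_last: MeanWithCI
    mean_abs_1_to_last: MeanWithCI
    mean_abs_5_to_last: MeanWithCI
    direction: Direction
    n_units: int
    n_excluded_zero_base: int
    #: ratio-of-means variant (pct change of the mean scores), for reference
    pct_of_means_1_to_last: float = float("nan")


def score_triples(cohort: Cohort) -> list[ScoreTriple]:
    """Extract (first, fifth, last) per unit with at least 5 repetitions."""
    triples = []
    for u in cohort.units:
        if u.n_reps < 5:
            continue
        triples.append(ScoreTriple(
            unit_id=u.unit_id, first=float(u.values[0]),
            fifth=float(u.values[4]), last=float(u.values[-1]),
            n_reps=u.n_reps, age_years=cohort.age_of(u)))
    return triples


def mean_with_ci(x: np.ndarray, level: float = 0.95) -> MeanWithCI:
    """Mean with two-sided t interval on n-1 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    m = float(x.mean())
    if n < 2:
        return MeanWithCI(m, float("nan"), float("nan"), n)
    se = float(x.std(ddof=1)) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2, df=n - 1)
    return MeanWithCI(m, m - tcrit * se, m + tcrit * se, n)


def pct_change(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed percent change 100 * (b - a) / a."""
    return 100.0 * (np.asarray(b) - np.asarray(a)) / np.asarray(a)


def improvement_summary(triples: list[ScoreTriple],
                        direction: Direction = Direction.HIGHER_BETTER,
                        ) -> ImprovementSummary:
    """Cohort-level improvement summary from per-unit score triples.

    Units whose first or fifth score is zero are excluded from the percent
    computations (a ratio to zero is undefined) but kept for the absolute
    difference.
    """
    if len(triples) < 2:
        raise ValueError("need at least 2 score triples")
    first = np.array([t.first for t in triples])
    fifth = np.array([t.fifth for t in triples])
    last = np.array([t.last for t in triples])
    usable = (first != 0) & (fifth != 0)
    n_excluded = int((~usable).sum())
    if not usable.any():
        raise ValueError("all units excluded: zero first or fifth scores")
    f, m, l = first[usable], fifth[usable], last[usable]
    return ImprovementSummary(
        mean_pct_1_to_5=mean_with_ci(pct_change(f, m)),
        mean_pct_5_to_last=mean_with_ci(pct_change(m, l)),
        mean_pct_1_to_last=mean_with_ci(pct_change(f, l)),
        mean_abs_1_to_last=mean_with_ci(last - first),
        mean_abs_5_to_last=mean_with_ci(last - fifth),
        direction=direction,
        n_units=len(triples),
        n_excluded_zero_base=n_excluded,
        pct_of_means_1_to_last=float(100.0 * (l.mean() - f.mean()) / f.mean()),
    )


def fifth_to_last_regression(triples: list[ScoreTriple]) -> pd.DataFrame:
    """OLS of (last - fifth) on age, first score, fifth score, ln(repetitions).

    Repetition counts are log-transformed because of their strong
    right-skew.  Units without a recorded age are dropped.  Returns a table
    with one row per term (coef, se, t, p) and the fit size/quality in the
    attrs ``n`` and ``r_squared``.
    """
    rows = [(t.age_years, t.first, t.fifth, np.log(t.n_reps),
             t.last - t.fifth)
            for t in triples if t.age_years is not None]
    if len(rows) < 6:
        raise ValueError("need >= 6 units with age for the confounder model")
    arr = np.asarray(rows, dtype=float)
    X = pd.DataFrame(arr[:, :4],
                     columns=["age", "first_score", "fifth_score", "log_n_reps"])
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            "rank-deficient design; check for constant or collinear "
            f"columns among {list(X.columns)}")
    fit = sm.OLS(arr[:, 4], X).fit()
    table = pd.DataFrame({
        "coef": fit.params, "se": fit.bse,
        "t": fit.tvalues, "p": fit.pvalues,
    })
    table.attrs["n"] = int(fit.nobs)
    r2 = float(fit.rsquared)
    table.attrs["r_squared"] = r2 if np.isfinite(r2) else 0.0  # constant response
    return table


def correlation_panel(pairs: dict[str, tuple[np.ndarray, np.ndarray]]
                      ) -> dict[str, dict[str, float]]:
    """Pearson R (t test) and Spearman rho for each named pair of vectors."""
    out = {}
    for name, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            raise ValueError(f"pair {name!r}: need >= 3 complete observations")
        pearson = stats.pearsonr(x[ok], y[ok])
        spearman = stats.spearmanr(x[ok], y[ok])
        out[name] = {
            "pearson_r": float(pearson.statistic),
            "pearson_p": float(pearson.pvalue),
            "spearman_rho": float(spearman.statistic),
            "spearman_p": float(spearman.pvalue),
            "n": int(ok.sum()),
        }
    return out
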