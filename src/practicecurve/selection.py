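"""Inclusion filters and cohort characteristics.

Units enter the analysis only with enough repetitions and enough follow-up:
the main criteria are at least 5 repetitions and at least 5 weeks between
the first and last repetition (stricter 10/10 criteria are used in
sensitivity analyses).  Five weeks is interpreted as 35 x 24 h of elapsed
time.  The characteristics table summarises, per test, the adherence and
schedule irregularity of the selected units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Cohort, ConfigurationError

DAYS_PER_WEEK = 7.0


@dataclass
class SelectionReport:
    """Counts of units and tests before/after the inclusion filter."""

    min_reps: int
    min_weeks: float
    n_units_total: int
    n_units_selected: int
    n_tests_total: int
    n_tests_selected: int
    per_test: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def pct_units_selected(self) -> float:
        return 100.0 * self.n_units_selected / self.n_units_total

    @property
    def pct_tests_selected(self) -> float:
        return 100.0 * self.n_tests_selected / self.n_tests_total

    def to_dict(self) -> dict:
        return {
            "min_reps": self.min_reps, "min_weeks": self.min_weeks,
            "n_units_total": self.n_units_total,
            "n_units_selected": self.n_units_selected,
            "n_tests_total": self.n_tests_total,
            "n_tests_selected": self.n_tests_selected,
            "pct_units_selected": self.pct_units_selected,
            "pct_tests_selected": self.pct_tests_selected,
            "per_test": self.per_test,
        }


def select_units(cohort: Cohort, min_reps: int = 5,
                 min_weeks: float = 5.0) -> tuple[Cohort, SelectionReport]:
    """Keep units with >= ``min_reps`` repetitions spanning >= ``min_weeks``.

    The span criterion is elapsed time from first to last repetition of at
    least ``7 * min_weeks`` days (24-hour days, not calendar days).
    """
    if min_reps < 2:
        raise ConfigurationError("min_reps must be at least 2")
    selected = [
        u for u in cohort.units
        if u.n_reps >= min_reps and u.span_weeks >= min_weeks
    ]
    per_test: dict[str, dict[str, int]] = {}
    for u in cohort.units:
        d = per_test.setdefault(u.test, {
            "n_units_total": 0, "n_units_selected": 0,
            "n_tests_total": 0, "n_tests_selected": 0})
        keep = u.n_reps >= min_reps and u.span_weeks >= min_weeks
        d["n_units_total"] += 1
        d["n_tests_total"] += u.n_reps
        if keep:
            d["n_units_selected"] += 1
            d["n_tests_selected"] += u.n_reps
    report = SelectionReport(
        min_reps=min_reps, min_weeks=min_weeks,
        n_units_total=len(cohort.units), n_units_selected=len(selected),
        n_tests_total=sum(u.n_reps for u in cohort.units),
        n_tests_selected=sum(u.n_reps for u in selected),
        per_test=per_test)
    provenance = (cohort.provenance +
                  f"; selected >= {min_reps} reps and >= {min_weeks} weeks "
                  f"(span as elapsed time, 1 week = 7x24 h)")
    out = Cohort(selected, dict(cohort.participants), provenance,
                 dict(cohort.meta))
    return out, report


def _median_iqr_range(x: np.ndarray) -> dict[str, float]:
    """median (IQR; range) with the linear-interpolation quantile rule."""
    x = np.asarray(x, dtype=float)
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return {"median": float(q50), "q25": float(q25), "q75": float(q75),
            "min": float(x.min()), "max": float(x.max())}


def cohort_characteristics(cohort: Cohort) -> pd.DataFrame:
    """Adherence/schedule summary per test, one row per statistic.

    Per unit: repetition count, the median and IQR of its consecutive
    intertest intervals (days), and the weeks from first to last test.
    Reported is the cohort-level median (IQR; range) of each per-unit
    statistic, plus the age distribution of the participants involved.
    Units with fewer than two records have no intervals and are omitted
    from the interval statistics.
    """
    rows = []
    for test in cohort.tests:
        sub = cohort.for_test(test)
        n_reps = np.array([u.n_reps for u in sub.units], dtype=float)
        med_int, iqr_int, spans = [], [], []
        for u in sub.units:
            spans.append(u.span_weeks)
            if u.n_reps >= 2:
                gaps = u.interval_days()
                q25, q50, q75 = np.percentile(gaps, [25, 50, 75])
                med_int.append(q50)
                iqr_int.append(q75 - q25)
        pids = sorted({u.participant_id for u in sub.units})
        ages = np.array([sub.participants[p] for p in pids
                         if sub.participants.get(p) is not None], dtype=float)
        stats = {
            "n_units": {"median": float(len(sub.units))},
            "n_repetitions": _median_iqr_range(n_reps),
            "median_intertest_interval_days": _median_iqr_range(np.array(med_int))
                if med_int else {},
            "iqr_intertest_interval_days": _median_iqr_range(np.array(iqr_int))
                if iqr_int else {},
            "weeks_first_to_last": _median_iqr_range(np.array(spans)),
            "age_years": _median_iqr_range(ages) if ages.size else {},
        }
        for stat, vals in stats.items():
            rows.append({"test": test, "statistic": stat, **vals})
    return pd.DataFrame(rows)
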