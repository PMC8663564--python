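"""End-to-end analysis per test and the sensitivity grid.

For every test the pipeline runs: inclusion filtering, cohort
characteristics, first/fifth/last summary effects with the confounder
regression and correlation panel, and the five-percentile short-term
learning panel with the slope-equality test.  The four-model learning-curve
analysis (and the derived practice metrics) runs only for tests flagged
with a long-term practice effect: the mean fifth-to-last improvement must
be significant (95% CI excluding zero) *and* the log-repetitions
coefficient of the confounder regression must support the association
(p < .05).

The sensitivity grid crosses the two selection criteria with the two time
axes: main = (5 reps, 5 weeks, repetition axis), S1 = (5, 5, weeks),
S2 = (10, 10, repetition), S3 = (10, 10, weeks).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import Cohort
from .growth import (compare_models, fit_bounded_growth, fit_linear_mixed,
                     fit_quadratic_mixed, fit_spline, practice_metrics)
from .quantiles import quantile_panel, slope_equality_test
from .registry import get_test_spec
from .selection import cohort_characteristics, select_units
from .summary import (correlation_panel, fifth_to_last_regression,
                      improvement_summary, score_triples)

logger = logging.getLogger(__name__)

#: the four analysis cells: name -> (min_reps, min_weeks, time_axis)
SENSITIVITY_GRID: dict[str, tuple[int, float, str]] = {
    "main": (5, 5.0, "repetition"),
    "S1": (5, 5.0, "weeks"),
    "S2": (10, 10.0, "repetition"),
    "S3": (10, 10.0, "weeks"),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    tests: list[str] | None = None  # default: every test present
    min_reps: int = 5
    min_weeks: float = 5.0
    time_axis: str = "repetition"
    n_boot: int = 1000
    seed: int = 0
    alpha: float = 0.05
    out_dir: str | None = None


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return repr(obj)
    return obj


def analyze_test(cohort: Cohort, test: str, config: RunConfig) -> dict:
    """Full analysis of one test; returns a JSON-ready result block."""
    spec = get_test_spec(test)
    sub = cohort.for_test(test)
    selected, report = select_units(sub, config.min_reps, config.min_weeks)
    block: dict = {
        "test": test,
        "selection": report.to_dict(),
        "n_selected_units": len(selected.units),
    }
    if len(selected.units) < 3:
        block["errors"] = {"selection": "fewer than 3 units selected"}
        return block
    errors: dict[str, str] = {}

    block["characteristics"] = _jsonable(cohort_characteristics(selected))

    triples = score_triples(selected)
    summary = improvement_summary(triples, spec.direction)
    block["summary_effects"] = _jsonable(summary)

    regression = None
    try:
        regression = fifth_to_last_regression(triples)
        block["fifth_to_last_regression"] = {
            "n": regression.attrs["n"],
            "r_squared": regression.attrs["r_squared"],
            "terms": _jsonable(regression.reset_index(names="term")),
        }
    except ValueError as exc:
        errors["fifth_to_last_regression"] = str(exc)

    try:
        ages = np.array([t.age_years if t.age_years is not None else np.nan
                         for t in triples])
        reps = np.array([t.n_reps for t in triples], dtype=float)
        first = np.array([t.first for t in triples])
        block["correlations"] = correlation_panel({
            "age_vs_n_reps": (ages, reps),
            "first_score_vs_n_reps": (first, reps),
        })
    except ValueError as exc:
        errors["correlations"] = str(exc)

    try:
        panel = quantile_panel(selected, n_boot=config.n_boot,
                               seed=config.seed)
        equality = slope_equality_test(panel)
        block["quantile_panel"] = {
            "table": _jsonable(panel.table),
            "n_points": panel.n_points, "n_units": panel.n_units,
            "n_boot": panel.n_boot, "n_redrawn": panel.n_redrawn,
            "slope_equality": _jsonable(equality),
        }
    except (ValueError, np.linalg.LinAlgError) as exc:
        errors["quantile_panel"] = str(exc)

    # long-term practice gate: significant 5th-to-last improvement and a
    # supporting log-repetitions association
    ci = summary.mean_pct_5_to_last
    significant_gain = ci.ci_low > 0 or ci.ci_high < 0
    reps_assoc = False
    if regression is not None:
        p_reps = float(regression.loc["log_n_reps", "p"])
        coef_reps = float(regression.loc["log_n_reps", "coef"])
        improving = coef_reps > 0 if ci.mean >= 0 else coef_reps < 0
        reps_assoc = p_reps < config.alpha and improving
    long_term = bool(significant_gain and reps_assoc)
    block["long_term_practice"] = {
        "flagged": long_term,
        "significant_fifth_to_last": bool(significant_gain),
        "log_reps_association": bool(reps_assoc),
    }

    if long_term:
        try:
            fits = {
                "linear": fit_linear_mixed(selected, config.time_axis),
                "quadratic": fit_quadratic_mixed(selected, config.time_axis),
                "spline": fit_spline(selected, config.time_axis),
                "bounded": fit_bounded_growth(selected, config.time_axis),
            }
            comparison = compare_models(fits)
            bg = fits["bounded"]
            metrics = practice_metrics(bg)
            block["learning_curves"] = {
                "time_axis": config.time_axis,
                "model_comparison": _jsonable(comparison.table),
                "best_model": comparison.best,
                "bounded_growth": {
                    "mu_y0": bg.mu_y0, "mu_boundary": bg.mu_boundary,
                    "c": bg.c, "var_y0": bg.var_y0,
                    "var_boundary": bg.var_boundary, "sigma2": bg.sigma2,
                    "rmse": bg.rmse, "df": bg.df, "loglik": bg.loglik,
                    "ci": _jsonable(bg.ci),
                },
                "practice_metrics": _jsonable(metrics),
            }
        except Exception as exc:  # noqa: BLE001 - stage errors must not abort
            errors["learning_curves"] = f"{type(exc).__name__}: {exc}"
    if errors:
        block["errors"] = errors
    return block


def run_analysis(cohort: Cohort, config: RunConfig | None = None) -> dict:
    """Run the per-test pipeline on every configured test of ``cohort``."""
    config = config or RunConfig()
    tests = config.tests or cohort.tests
    bundle = {
        "software": {"package": "practicecurve", "version": __version__},
        "config": _jsonable(config),
        "provenance": cohort.provenance,
        "results": {},
    }
    for test in tests:
        try:
            bundle["results"][test] = analyze_test(cohort, test, config)
        except Exception as exc:  # noqa: BLE001 - isolate per-test failures
            logger.exception("analysis of %s failed", test)
            bundle["results"][test] = {
                "test": test, "errors": {"fatal": f"{type(exc).__name__}: {exc}"}}
    if config.out_dir:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def run_sensitivity(cohort: Cohort, config: RunConfig | None = None) -> dict:
    """Run all four analysis cells and tabulate them side by side."""
    config = config or RunConfig()
    cells = {}
    for name, (min_reps, min_weeks, axis) in SENSITIVITY_GRID.items():
        cell_cfg = RunConfig(
            tests=config.tests, min_reps=min_reps, min_weeks=min_weeks,
            time_axis=axis, n_boot=config.n_boot, seed=config.seed,
            alpha=config.alpha, out_dir=None)
        cells[name] = run_analysis(cohort, cell_cfg)

    comparison_rows = []
    for test in (config.tests or cohort.tests):
        row: dict = {"test": test}
        for name, cell in cells.items():
            block = cell["results"].get(test, {})
            eff = block.get("summary_effects")
            row[f"{name}_n_units"] = block.get("n_selected_units")
            if eff:
                row[f"{name}_pct_5_to_last"] = \
                    eff["mean_pct_5_to_last"]["mean"]
            curves = block.get("learning_curves")
            if curves:
                row[f"{name}_boundary_improvement_pct"] = \
                    curves["practice_metrics"]["pct_improvement"][0]
        comparison_rows.append(row)
    out = {
        "software": {"package": "practicecurve", "version": __version__},
        "config": _jsonable(config),
        "cells": cells,
        "comparison": comparison_rows,
    }
    if config.out_dir:
        path = Path(config.out_dir)
        path.mkdir(parents=True, exist_ok=True)
        (path / "sensitivity.json").write_text(
            json.dumps(_jsonable(out), indent=2, sort_keys=True))
        pd.DataFrame(comparison_rows).to_csv(
            path / "sensitivity_comparison.tsv", sep="\t", index=False)
    return out


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(_jsonable(bundle), indent=2, sort_keys=True))
    for test, block in bundle["results"].items():
        safe = test.replace("/", "_")
        if "characteristics" in block:
            pd.DataFrame(block["characteristics"]).to_csv(
                out_dir / f"{safe}_characteristics.tsv", sep="\t", index=False)
        if "quantile_panel" in block:
            pd.DataFrame(block["quantile_panel"]["table"]).to_csv(
                out_dir / f"{safe}_quantiles.tsv", sep="\t", index=False)
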