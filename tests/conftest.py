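import numpy as np
import pytest

import practicecurve as pc
from practicecurve.data_model import AnalysisUnit, Cohort


def make_unit(values, unit_id="u0", test="e-SDMT", t_weeks=None, hand="none",
              participant_id=None):
    values = np.asarray(values, dtype=float)
    if t_weeks is None:
        t_weeks = np.arange(len(values), dtype=float)  # weekly schedule
    return AnalysisUnit(
        unit_id=unit_id, test=test,
        participant_id=participant_id or unit_id.split("/")[0], hand=hand,
        values=values, t_weeks=np.asarray(t_weeks, dtype=float))


def curve_cohort(n_units=20, y0=10.0, boundary=20.0, c=np.log(2), n_reps=8,
                 test="e-SDMT", noise_sd=0.0, seed=0):
    """Cohort of units on (possibly noisy copies of) one bounded-growth curve."""
    rng = np.random.default_rng(seed)
    t = np.arange(float(n_reps))
    units = []
    for i in range(n_units):
        y = pc.mean_curve(y0, boundary, c, t) + noise_sd * rng.standard_normal(n_reps)
        units.append(make_unit(y, unit_id=f"u{i}", test=test, t_weeks=t))
    return Cohort(units)


def equal_slope_cohort(seed, n_units=200, slope=2.0, intercept_sd=8.0,
                       noise_sd=3.0, n_reps=5):
    """Linear series with a common slope and unit-specific intercepts."""
    rng = np.random.default_rng(seed)
    units = []
    t = np.arange(float(n_reps))
    for i in range(n_units):
        a = rng.normal(40.0, intercept_sd)
        y = a + slope * t + rng.normal(0.0, noise_sd, n_reps)
        units.append(make_unit(y, unit_id=f"u{i}", t_weeks=t))
    return Cohort(units)


@pytest.fixture(scope="session")
def esdmt_sim():
    """Mid-size study-calibrated e-SDMT cohort with ground truth."""
    cfg = pc.study_config("e-SDMT", n_units=150, mu_y0=40.0, mu_boundary=58.0,
                          c=0.06, sd_y0=5.0, sd_boundary=5.0, sigma_resid=3.0)
    cohort, truth = pc.simulate_cohort(cfg, seed=11)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def esdmt_selected(esdmt_sim):
    cohort, truth, cfg = esdmt_sim
    selected, _ = pc.select_units(cohort)
    return selected
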