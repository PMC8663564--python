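"""Synthetic cohorts with known ground truth.

Emulates the structure of self-scheduled high-frequency smartphone testing:
per-unit bounded-growth trajectories

    y(t) = boundary_i + (y0_i - boundary_i) * exp(-c * t),   t = repetition - 1

with Gaussian random baseline ``y0_i`` and plateau ``boundary_i``, additive
Gaussian residual noise, a right-skewed repetition-count law, irregular
lognormal intertest intervals floored at the app-enforced minimum, optional
left/right hand interleaving, and an age covariate weakly correlated with
adherence (number of repetitions) through a Gaussian copula.

Every unit draws from its own child stream of the root seed, so adding
units to a configuration leaves the existing units' data unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import AnalysisUnit, Cohort, ConfigurationError, make_unit_id
from .registry import Direction, get_test_spec

_Z75 = 0.6744897501960817  # standard normal 75% quantile


@dataclass(frozen=True)
class RepsLaw:
    """Right-skewed repetition-count targets: median, (q25, q75), maximum."""

    median: float
    iqr: tuple[float, float]
    max: float

    def lognormal_params(self) -> tuple[float, float]:
        """Least-squares (mu, sigma) of a lognormal matching the three
        log-quantile targets."""
        if self.median < 1:
            raise ConfigurationError("repetition-count median must be >= 1")
        q25, q75 = self.iqr
        if q75 < q25 or q25 <= 0:
            raise ConfigurationError("invalid repetition-count IQR")
        logs = np.log([q25, self.median, q75])
        mu = logs.mean()
        sigma = (logs[2] - logs[0]) / (2 * _Z75)
        return float(mu), float(sigma)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters for one test's cohort."""

    test: str = "e-SDMT"
    n_units: int = 100
    mu_y0: float = 41.0
    sd_y0: float = 10.0
    mu_boundary: float = 57.7
    sd_boundary: float = 10.0
    c: float = math.log(2) / 11  # half the practice effect after 11 reps
    sigma_resid: float = 3.3
    reps_dist: RepsLaw = field(default_factory=lambda: RepsLaw(11, (7, 18), 119))
    interval_log_mean: float = math.log(7.9)
    interval_log_sd: float = 0.75
    age_mean: float = 50.0
    age_sd: float = 12.0
    age_reps_corr: float = 0.19
    seed: int = 0

    def validate(self) -> None:
        spec = get_test_spec(self.test)
        if self.n_units < 1:
            raise ConfigurationError("n_units must be positive")
        if min(self.sd_y0, self.sd_boundary, self.sigma_resid) < 0:
            raise ConfigurationError("standard deviations must be nonnegative")
        if self.c < 0:
            raise ConfigurationError("growth constant c must be nonnegative")
        if not -1 < self.age_reps_corr < 1:
            raise ConfigurationError("age_reps_corr must lie in (-1, 1)")
        if (spec.direction is Direction.HIGHER_BETTER and self.c > 0
                and self.mu_boundary < self.mu_y0):
            raise ConfigurationError(
                "higher-is-better test needs mu_boundary >= mu_y0")
        self.reps_dist.lognormal_params()


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated unit (recovery-test oracle)."""

    unit_id: str
    y0_i: float
    boundary_i: float
    n_reps_i: int
    age_i: float


def mean_curve(y0: float, boundary: float, c: float, t) -> np.ndarray | float:
    """Expected score ``boundary + (y0 - boundary) * exp(-c t)``.

    Approaches ``boundary`` monotonically as ``t`` grows; at ``t = 0`` it
    equals ``y0``.
    """
    t = np.asarray(t, dtype=float)
    out = boundary + (y0 - boundary) * np.exp(-c * t)
    return float(out) if out.ndim == 0 else out


def simulate_cohort(config: SimConfig,
                    seed: int | None = None) -> tuple[Cohort, list[TruthRecord]]:
    """Generate one cohort plus its per-unit ground truth.

    ``seed`` overrides ``config.seed``.  Hand-grouped tests emit two
    interleaved units (left/right schedules offset by one day) per
    participant; ``n_units`` then counts units, i.e. hands.
    """
    config.validate()
    spec = get_test_spec(config.test)
    root = config.seed if seed is None else seed
    mu_log, sd_log = config.reps_dist.lognormal_params()

    n_participants = (config.n_units + 1) // 2 if spec.hand_grouped \
        else config.n_units
    units: list[AnalysisUnit] = []
    truths: list[TruthRecord] = []
    participants: dict[str, float | None] = {}
    rho = config.age_reps_corr

    for i in range(n_participants):
        pid = f"sim{i:05d}"
        prng = np.random.default_rng(np.random.SeedSequence(root, spawn_key=(i,)))
        z_age = prng.standard_normal()
        age = config.age_mean + config.age_sd * z_age
        participants[pid] = float(age)
        hands = ["left", "right"] if spec.hand_grouped else ["none"]
        for h, hand in enumerate(hands):
            if spec.hand_grouped and len(units) >= config.n_units:
                break
            rng = np.random.default_rng(
                np.random.SeedSequence(root, spawn_key=(i, h)))
            # adherence correlated with age via a Gaussian copula
            z_reps = rho * z_age + math.sqrt(1 - rho ** 2) * rng.standard_normal()
            n_reps = int(min(config.reps_dist.max,
                             max(1, math.ceil(math.exp(mu_log + sd_log * z_reps)))))
            y0_i = config.mu_y0 + config.sd_y0 * rng.standard_normal()
            boundary_i = config.mu_boundary + config.sd_boundary * rng.standard_normal()
            gaps = np.exp(config.interval_log_mean
                          + config.interval_log_sd * rng.standard_normal(n_reps - 1))
            gaps = np.maximum(gaps, spec.min_interval_days)
            t_days = np.concatenate([[0.0], np.cumsum(gaps)])
            t_rep = np.arange(n_reps, dtype=float)
            values = mean_curve(y0_i, boundary_i, config.c, t_rep) \
                + config.sigma_resid * rng.standard_normal(n_reps)
            unit_id = make_unit_id(pid, hand)
            units.append(AnalysisUnit(
                unit_id=unit_id, test=config.test, participant_id=pid,
                hand=hand, values=np.atleast_1d(values),
                t_weeks=t_days / 7.0))
            truths.append(TruthRecord(unit_id, float(y0_i), float(boundary_i),
                                      n_reps, float(age)))

    cohort = Cohort(units, participants,
                    provenance=f"simulated {config.test} cohort, seed={root}")
    cohort.meta["sim_config"] = config
    return cohort, truths


# ---------------------------------------------------------------------------
# Study-calibrated presets
# ---------------------------------------------------------------------------

#: Per-test generator presets.  Trajectory parameters follow the reported
#: bounded-growth estimates (baseline/boundary fixed effects, half-practice
#: repetition number, residual RMSE); schedule and adherence laws follow the
#: reported cohort characteristics (median/IQR/maximum repetitions, median
#: intertest intervals, age distribution and age-adherence correlation).
#: Mobility tests, which showed no long-term practice effect, are emulated as
#: flat (Two Minute Walk) or fast-saturating (U-Turn, Static Balance) curves.
STUDY_PRESETS: dict[str, SimConfig] = {
    "e-SDMT": SimConfig(
        test="e-SDMT", n_units=262, mu_y0=41.0, sd_y0=10.0, mu_boundary=57.7,
        sd_boundary=10.0, c=math.log(2) / 11, sigma_resid=3.3,
        reps_dist=RepsLaw(11, (7, 18), 119),
        interval_log_mean=math.log(7.9), interval_log_sd=0.75,
        age_mean=50.0, age_sd=12.0, age_reps_corr=0.19),
    "FingerPinching": SimConfig(
        test="FingerPinching", n_units=499, mu_y0=31.4, sd_y0=14.0,
        mu_boundary=58.4, sd_boundary=14.0, c=math.log(2) / 28,
        sigma_resid=6.8, reps_dist=RepsLaw(17, (9, 41.5), 416),
        interval_log_mean=math.log(3.1), interval_log_sd=0.75,
        age_mean=50.0, age_sd=12.0, age_reps_corr=0.21),
    "DrawAShape": SimConfig(
        test="DrawAShape", n_units=484, mu_y0=3.2, sd_y0=1.5,
        mu_boundary=3.94, sd_boundary=1.5, c=math.log(2) / 17,
        sigma_resid=1.02, reps_dist=RepsLaw(17, (9, 41), 414),
        interval_log_mean=math.log(3.3), interval_log_sd=0.75,
        age_mean=50.0, age_sd=12.0, age_reps_corr=0.22),
    "TwoMinuteWalk": SimConfig(
        test="TwoMinuteWalk", n_units=171, mu_y0=210.0, sd_y0=50.0,
        mu_boundary=210.0, sd_boundary=0.0, c=0.0, sigma_resid=20.0,
        reps_dist=RepsLaw(30, (15, 83.5), 827),
        interval_log_mean=math.log(1.4), interval_log_sd=0.75,
        age_mean=50.0, age_sd=12.0, age_reps_corr=0.15),
    "UTurn": SimConfig(
        test="UTurn", n_units=217, mu_y0=1.17, sd_y0=0.45, mu_boundary=1.29,
        sd_boundary=0.45, c=0.5, sigma_resid=0.15,
        reps_dist=RepsLaw(24, (11, 69), 829),
        interval_log_mean=math.log(1.8), interval_log_sd=0.75,
        age_mean=50.0, age_sd=12.0, age_reps_corr=0.15),
    "StaticBalance": SimConfig(
        test="StaticBalance", n_units=257, mu_y0=60.0, sd_y0=40.0,
        mu_boundary=44.0, sd_boundary=30.0, c=0.5, sigma_resid=15.0,
        reps_dist=RepsLaw(24, (12, 67), 828),
        interval_log_mean=math.log(1.7), interval_log_sd=0.75,
        age_mean=50.0, age_sd=12.0, age_reps_corr=0.15),
}


def study_config(test: str, **overrides) -> SimConfig:
    """Study-calibrated :class:`SimConfig` for ``test``, with overrides."""
    preset = STUDY_PRESETS.get(test)
    if preset is None:
        raise ConfigurationError(f"no preset for test {test!r}")
    return replace(preset, **overrides) if overrides else preset
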