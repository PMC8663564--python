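"""Domain containers and readers for long-format test-record tables.

The raw input is a long-format delimited file with one row per performed
test and metric: participant id, test name, hand, timestamp, metric name and
metric value.  Rows are filtered to each test's primary metric, grouped into
:class:`AnalysisUnit` series (per participant, or per participant x hand for
dexterity tests), chronologically indexed, and wrapped in a :class:`Cohort`.

The module also implements the e-SDMT dexterity correction: the app's
second "baseline" step (15 s of digit tapping without the symbol
association) provides a denominator that removes motor speed from the
cognitive score via the quotient main / baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .registry import TEST_SPECS, Grouping, TestSpec, get_test_spec

logger = logging.getLogger(__name__)

SECONDS_PER_WEEK = 7 * 24 * 3600.0


class ConfigurationError(ValueError):
    """Invalid configuration (missing columns, bad parameter values)."""


class InputDataError(ValueError):
    """Input file yields no usable records."""


class UsageError(RuntimeError):
    """Operation applied to an object it does not apply to."""


#: Column names of the public long-format export; every entry can be
#: overridden through ``column_map``.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "participant_id": "floodlightOpenId",
    "test": "testName",
    "hand": "handUsed",
    "timestamp": "testStartedAt",
    "metric": "testMetricName",
    "value": "testResultMetricValue",
    "age": "age",
}

#: Primary metric per test and the e-SDMT baseline-step metric.
DEFAULT_METRIC_MAP: dict[str, str] = {
    "e-SDMT": "correctResponses",
    "FingerPinching": "successfulPinches",
    "DrawAShape": "shapesDrawnCorrectly",
    "TwoMinuteWalk": "steps",
    "UTurn": "turnSpeedAverage",
    "StaticBalance": "swayPath",
}

DEFAULT_SDMT_BASELINE_METRIC = "baselineCorrectResponses"


@dataclass(frozen=True)
class TestRecord:
    """One administration of one test (already reduced to its primary metric)."""

    participant_id: str
    test: str
    hand: str  # "left" | "right" | "none"
    timestamp: pd.Timestamp
    value: float
    sdmt_baseline_correct: float | None = None
    age_years: float | None = None


@dataclass
class AnalysisUnit:
    """Chronologically indexed series of one unit (participant or hand).

    ``rep_index`` is the gap-free 1-based repetition number, ``t_rep`` the
    model time ``rep_index - 1`` and ``t_weeks`` the elapsed weeks since the
    unit's first test.
    """

    unit_id: str
    test: str
    participant_id: str
    hand: str
    values: np.ndarray
    t_weeks: np.ndarray
    timestamps: pd.DatetimeIndex | None = None
    baseline_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.t_weeks = np.asarray(self.t_weeks, dtype=float)
        if self.values.shape != self.t_weeks.shape:
            raise ValueError("values and t_weeks must have equal length")
        if self.n_reps and self.t_weeks[0] != 0.0:
            raise ValueError("t_weeks must start at 0")
        if np.any(np.diff(self.t_weeks) < 0):
            raise ValueError("t_weeks must be nondecreasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n_reps(self) -> int:
        return len(self.values)

    @property
    def rep_index(self) -> np.ndarray:
        return np.arange(1, self.n_reps + 1)

    @property
    def t_rep(self) -> np.ndarray:
        """Model time on the repetition axis: repetition number minus one."""
        return np.arange(self.n_reps, dtype=float)

    def time(self, axis: str) -> np.ndarray:
        """Model time on the requested axis ("repetition" or "weeks")."""
        if axis == "repetition":
            return self.t_rep
        if axis == "weeks":
            return self.t_weeks
        raise ValueError(f"unknown time axis {axis!r}")

    @property
    def span_weeks(self) -> float:
        return float(self.t_weeks[-1]) if self.n_reps else 0.0

    def interval_days(self) -> np.ndarray:
        """Consecutive intertest intervals in days."""
        return np.diff(self.t_weeks) * 7.0

    @property
    def spec(self) -> TestSpec:
        return get_test_spec(self.test)


@dataclass
class Cohort:
    """Collection of analysis units for one or more tests."""

    units: list[AnalysisUnit]
    participants: dict[str, float | None] = field(default_factory=dict)
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u in self.units:
            self.participants.setdefault(u.participant_id, None)

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    @property
    def tests(self) -> list[str]:
        return sorted({u.test for u in self.units})

    def for_test(self, test: str) -> "Cohort":
        """Sub-cohort containing only the units of ``test``."""
        units = [u for u in self.units if u.test == test]
        return Cohort(units, dict(self.participants), self.provenance,
                      dict(self.meta))

    def age_of(self, unit: AnalysisUnit) -> float | None:
        return self.participants.get(unit.participant_id)

    def n_records(self) -> int:
        return sum(u.n_reps for u in self.units)

    # -- normalized long format ------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per record: unit_id, test, repetition_index, t_weeks, value."""
        rows = []
        for u in sorted(self.units, key=lambda x: (x.test, x.unit_id)):
            rows.append(pd.DataFrame({
                "unit_id": u.unit_id,
                "test": u.test,
                "repetition_index": u.rep_index,
                "t_weeks": u.t_weeks,
                "value": u.values,
            }))
        if not rows:
            return pd.DataFrame(columns=["unit_id", "test", "repetition_index",
                                         "t_weeks", "value"])
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, path) -> None:
        # %.17g round-trips IEEE doubles exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   participants: dict | None = None,
                   provenance: str = "") -> "Cohort":
        units = []
        for (unit_id, test), grp in frame.groupby(["unit_id", "test"],
                                                  sort=True):
            grp = grp.sort_values("repetition_index")
            pid, hand = _split_unit_id(str(unit_id))
            units.append(AnalysisUnit(
                unit_id=str(unit_id), test=str(test), participant_id=pid,
                hand=hand,
                values=grp["value"].to_numpy(float),
                t_weeks=grp["t_weeks"].to_numpy(float),
            ))
        return cls(units, dict(participants or {}), provenance)

    @classmethod
    def read_csv(cls, path, provenance: str | None = None) -> "Cohort":
        frame = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(frame, provenance=provenance or str(path))


def _split_unit_id(unit_id: str) -> tuple[str, str]:
    for hand in ("left", "right"):
        suffix = f"/{hand}"
        if unit_id.endswith(suffix):
            return unit_id[: -len(suffix)], hand
    return unit_id, "none"


def make_unit_id(participant_id: str, hand: str) -> str:
    return participant_id if hand == "none" else f"{participant_id}/{hand}"


# ---------------------------------------------------------------------------
# Loading the raw long-format export
# ---------------------------------------------------------------------------

def build_units(records: list[TestRecord]) -> list[AnalysisUnit]:
    """Group records into chronologically indexed units.

    Within a unit, records are ordered by timestamp with ties broken by the
    original input order (the order of ``records``), so indexing is
    deterministic for same-day repetitions.
    """
    groups: dict[tuple[str, str], list[TestRecord]] = {}
    for rec in records:
        key = (make_unit_id(rec.participant_id, rec.hand), rec.test)
        groups.setdefault(key, []).append(rec)
    units = []
    for (unit_id, test), recs in sorted(groups.items()):
        recs = sorted(recs, key=lambda r: r.timestamp)  # stable for ties
        ts = pd.DatetimeIndex([r.timestamp for r in recs])
        t_weeks = (ts - ts[0]).total_seconds() / SECONDS_PER_WEEK
        baseline = None
        if any(r.sdmt_baseline_correct is not None for r in recs):
            baseline = np.array([
                np.nan if r.sdmt_baseline_correct is None
                else float(r.sdmt_baseline_correct) for r in recs])
        units.append(AnalysisUnit(
            unit_id=unit_id, test=test, participant_id=recs[0].participant_id,
            hand=recs[0].hand, values=np.array([r.value for r in recs]),
            t_weeks=np.asarray(t_weeks, dtype=float), timestamps=ts,
            baseline_values=baseline,
        ))
    return units


def cohort_from_records(records: list[TestRecord],
                        provenance: str = "") -> Cohort:
    units = build_units(records)
    participants: dict[str, float | None] = {}
    for rec in records:
        if rec.age_years is not None and np.isfinite(rec.age_years):
            participants[rec.participant_id] = float(rec.age_years)
        else:
            participants.setdefault(rec.participant_id, None)
    return Cohort(units, participants, provenance)


def load_cohort(path, column_map: dict[str, str] | None = None,
                cutoff_date=None,
                metric_map: dict[str, str] | None = None,
                test_name_map: dict[str, str] | None = None,
                sdmt_baseline_metric: str = DEFAULT_SDMT_BASELINE_METRIC,
                ) -> Cohort:
    """Read a raw long-format export into a :class:`Cohort`.

    Parameters
    ----------
    path
        Delimited long-format text file (RFC-4180 CSV).
    column_map
        Overrides for :data:`DEFAULT_COLUMN_MAP` entries.
    cutoff_date
        Keep only rows whose timestamp date is on or before this date.
    metric_map
        Per-test primary metric name overrides.
    test_name_map
        Mapping from export test labels to canonical test names, if they
        differ.
    """
    cols = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cols.update(column_map)
    metrics = dict(DEFAULT_METRIC_MAP)
    if metric_map:
        metrics.update(metric_map)

    raw = pd.read_csv(path, dtype=str)
    mandatory = ["participant_id", "test", "timestamp", "metric", "value"]
    missing = [cols[k] for k in mandatory if cols[k] not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"input file lacks mandatory column(s) {missing}; "
            f"adjust column_map (have: {list(raw.columns)})")

    name_map = dict(test_name_map or {})
    metric_to_test = {m: t for t, m in metrics.items()}

    n_dropped = 0
    records: list[TestRecord] = []
    sdmt_baseline: dict[tuple[str, pd.Timestamp], float] = {}
    for row in raw.itertuples(index=False):
        row = row._asdict()
        test_label = row.get(cols["test"])
        test = name_map.get(test_label, test_label)
        if test not in TEST_SPECS:
            n_dropped += 1
            continue
        spec = TEST_SPECS[test]
        metric = row.get(cols["metric"])
        is_baseline = test == "e-SDMT" and metric == sdmt_baseline_metric
        if metric != metrics[test] and not is_baseline:
            n_dropped += 1
            continue
        ts = _parse_timestamp(row.get(cols["timestamp"]))
        value = _parse_float(row.get(cols["value"]))
        pid = row.get(cols["participant_id"])
        if ts is None or value is None or not pid:
            n_dropped += 1
            continue
        if cutoff_date is not None and ts.date() > pd.Timestamp(cutoff_date).date():
            continue
        if is_baseline:
            sdmt_baseline[(pid, ts)] = value
            continue
        hand = _normalize_hand(row.get(cols["hand"], None), spec)
        if hand is None:
            n_dropped += 1
            continue
        age = _parse_float(row.get(cols["age"])) if cols["age"] in raw.columns else None
        records.append(TestRecord(pid, test, hand, ts, value, None, age))

    if n_dropped:
        logger.warning("dropped %d unusable rows while loading %s",
                       n_dropped, path)
    if not records:
        raise InputDataError(f"no parseable test records in {path}")

    records = [
        replace(rec, sdmt_baseline_correct=sdmt_baseline.get(
            (rec.participant_id, rec.timestamp)))
        if rec.test == "e-SDMT" else rec
        for rec in records
    ]
    cohort = cohort_from_records(
        records, provenance=f"loaded from {path}; cutoff={cutoff_date}; "
                            f"{n_dropped} rows dropped")
    cohort.meta["n_rows_dropped"] = n_dropped
    return cohort


def _parse_timestamp(raw) -> pd.Timestamp | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text:
        return None
    try:
        ts = pd.Timestamp(text)
    except (ValueError, TypeError):
        return None
    # date-only stamps sit at midnight; move them to noon so that week
    # arithmetic is stable against timezone/boundary quirks
    if ":" not in text:
        ts = ts + pd.Timedelta(hours=12)
    return ts


def _parse_float(raw) -> float | None:
    if raw is None:
        return None
    try:
        value = float(raw)
    except (TypeError, ValueError):
        return None
    return value if np.isfinite(value) else None


def _normalize_hand(raw, spec: TestSpec) -> str | None:
    """Return "left"/"right"/"none", or None for an unusable label."""
    if spec.grouping is Grouping.PARTICIPANT:
        return "none"
    if raw is None:
        return None
    hand = str(raw).strip().lower()
    if hand in ("left", "right"):
        return hand
    logger.warning("unrecognized hand label %r on %s record; dropping",
                   raw, spec.name)
    return None


# ---------------------------------------------------------------------------
# e-SDMT dexterity correction
# ---------------------------------------------------------------------------

def correct_sdmt(cohort: Cohort) -> Cohort:
    """Divide e-SDMT scores by the baseline digit-tapping step.

    Records with a missing or zero baseline are dropped (counted in
    ``meta["sdmt_records_dropped"]``); the unit's repetition index and week
    clock are rebuilt from the surviving records.  The corrected score is a
    dimensionless ratio, so a second application is refused.
    """
    if cohort.meta.get("sdmt_corrected"):
        raise UsageError("cohort e-SDMT scores are already baseline-corrected")
    if "e-SDMT" not in cohort.tests:
        raise UsageError("correct_sdmt applies only to cohorts with e-SDMT units")
    new_units: list[AnalysisUnit] = []
    n_dropped = 0
    for u in cohort.units:
        if u.test != "e-SDMT":
            new_units.append(u)
            continue
        if u.baseline_values is None:
            raise UsageError(
                f"unit {u.unit_id}: e-SDMT records carry no baseline step")
        baseline = np.asarray(u.baseline_values, dtype=float)
        keep = np.isfinite(baseline) & (baseline != 0)
        n_dropped += int((~keep).sum())
        if not keep.any():
            continue
        values = u.values[keep] / baseline[keep]
        ts = u.timestamps[keep] if u.timestamps is not None else None
        t_weeks = (u.t_weeks[keep] - u.t_weeks[keep][0])
        new_units.append(AnalysisUnit(
            unit_id=u.unit_id, test=u.test, participant_id=u.participant_id,
            hand=u.hand, values=values, t_weeks=t_weeks, timestamps=ts))
    if n_dropped:
        logger.warning("correct_sdmt dropped %d records lacking a usable "
                       "baseline", n_dropped)
    out = Cohort(new_units, dict(cohort.participants),
                 cohort.provenance + "; e-SDMT baseline-corrected",
                 dict(cohort.meta))
    out.meta["sdmt_corrected"] = True
    out.meta["sdmt_records_dropped"] = n_dropped
    return out
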