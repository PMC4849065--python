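"""Trial data model: long-format I/O, dropout-cause taxonomy, scenario
reclassification, survival-format conversion and descriptive summaries.

A trial is a collection of patients, each with a treatment arm, a monotone
sequence of scheduled outcome measurements, and a single terminating event:
either completion of the full schedule or dropout.  Dropout causes follow a
four-way taxonomy motivated by paediatric acute-asthma trials:

``good``
    withdrawn because of improving condition (e.g. discharged early) —
    informative, depends on the unobserved outcome trajectory;
``poor``
    withdrawn because of worsening condition (e.g. escalation of care) —
    informative;
``unknown``
    reason not recorded or unclear — a mixture of mechanisms, reclassified
    to good/poor by sensitivity scenarios before model fitting;
``unrelated``
    reason judged unrelated to concurrent health status (protocol deviation,
    assessor unavailable) — treated as independent censoring.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class Cause(str, Enum):
    """Terminal status of a patient: completion or one of four dropout causes."""

    COMPLETED = "completed"
    GOOD = "good"
    POOR = "poor"
    UNKNOWN = "unknown"
    UNRELATED = "unrelated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Dropout causes (everything except completion).
DROPOUT_CAUSES = (Cause.GOOD, Cause.POOR, Cause.UNKNOWN, Cause.UNRELATED)

#: Causes treated as informative under the all-cause (K=1) coding.
INFORMATIVE_CAUSES = (Cause.GOOD, Cause.POOR, Cause.UNKNOWN)


class TrialDataError(ValueError):
    """Raised for invalid trial datasets or malformed input tables."""


@dataclass(frozen=True)
class Measurement:
    """One outcome assessment: ``value`` observed at ``time`` minutes."""

    patient_id: str
    time: float
    value: float


@dataclass
class PatientRecord:
    """One patient: arm, ordered measurements, and the terminating event."""

    patient_id: str
    arm: int
    measurements: list[Measurement]
    event_time: float
    cause: Cause

    def validate(self) -> None:
        if self.arm not in (0, 1):
            raise TrialDataError(
                f"patient {self.patient_id!r}: arm must be 0 or 1, got {self.arm!r}"
            )
        if not self.measurements:
            raise TrialDataError(
                f"patient {self.patient_id!r}: at least the baseline measurement is required"
            )
        times = [m.time for m in self.measurements]
        if any(t < 0 for t in times):
            raise TrialDataError(f"patient {self.patient_id!r}: negative measurement time")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise TrialDataError(
                f"patient {self.patient_id!r}: measurement times must be strictly increasing"
            )
        if times[-1] > self.event_time:
            raise TrialDataError(
                f"patient {self.patient_id!r}: measurement at t={times[-1]:g} "
                f"after event_time={self.event_time:g}"
            )

    @property
    def times(self) -> np.ndarray:
        return np.array([m.time for m in self.measurements], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([m.value for m in self.measurements], dtype=float)


@dataclass(frozen=True)
class SurvivalRecord:
    """Event-format view of one patient: time and integer status code.

    ``status`` is 0 for censoring and ``l`` in ``1..K`` for dropout from
    cause ``l``.
    """

    patient_id: str
    arm: int
    time: float
    status: int


@dataclass
class TrialDataset:
    """A validated trial: unique patients, shared schedule, admin censoring."""

    records: list[PatientRecord]
    schedule: list[float] = field(default_factory=lambda: list(DEFAULT_SCHEDULE))
    admin_censor_time: float = 240.0

    def __post_init__(self) -> None:
        self.schedule = sorted(float(t) for t in self.schedule)
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.patient_id in seen:
                raise TrialDataError(f"duplicate patient id {rec.patient_id!r}")
            seen.add(rec.patient_id)
            rec.validate()
            if rec.cause is Cause.COMPLETED and rec.event_time != self.schedule[-1]:
                raise TrialDataError(
                    f"patient {rec.patient_id!r}: completer must have "
                    f"event_time == final scheduled visit ({self.schedule[-1]:g})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialDataset):
            return NotImplemented
        return (
            self.schedule == other.schedule
            and self.admin_censor_time == other.admin_censor_time
            and self.records == other.records
        )

    def copy(self) -> "TrialDataset":
        return copy.deepcopy(self)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def subset(self, patient_ids: Iterable[str]) -> "TrialDataset":
        wanted = set(patient_ids)
        return TrialDataset(
            [copy.deepcopy(r) for r in self.records if r.patient_id in wanted],
            schedule=list(self.schedule),
            admin_censor_time=self.admin_censor_time,
        )

    def measurements_frame(self) -> pd.DataFrame:
        rows = [
            (r.patient_id, r.arm, m.time, m.value)
            for r in self.records
            for m in r.measurements
        ]
        return pd.DataFrame(rows, columns=["patient_id", "arm", "time_min", "score"])

    def events_frame(self) -> pd.DataFrame:
        rows = [(r.patient_id, r.event_time, r.cause.value) for r in self.records]
        return pd.DataFrame(rows, columns=["patient_id", "event_time_min", "cause"])


DEFAULT_SCHEDULE = (0.0, 20.0, 40.0, 60.0, 120.0, 180.0, 240.0)

_CAUSE_VOCAB = {c.value: c for c in Cause}


def _parse_cause(raw: object, patient_id: str) -> Cause:
    key = str(raw).strip().lower()
    if key not in _CAUSE_VOCAB:
        raise TrialDataError(
            f"patient {patient_id!r}: unknown cause {raw!r}; "
            f"allowed: {sorted(_CAUSE_VOCAB)}"
        )
    return _CAUSE_VOCAB[key]


def read_trial_long(
    measurements_source,
    events_source,
    schedule: Sequence[float] | None = None,
    admin_censor_time: float | None = None,
) -> TrialDataset:
    """Read a trial from two CSV tables (long measurements + one-row-per-patient events).

    ``measurements_source`` needs columns ``patient_id, arm, time_min, score``;
    ``events_source`` needs ``patient_id, event_time_min, cause``.  Sources may
    be paths or open file objects.  The schedule defaults to the distinct
    measurement times; administrative censoring defaults to the final visit.
    """
    meas = pd.read_csv(measurements_source, float_precision="round_trip")
    events = pd.read_csv(events_source, float_precision="round_trip")
    for col in ("patient_id", "arm", "time_min", "score"):
        if col not in meas.columns:
            raise TrialDataError(f"measurement table lacks column {col!r}")
    for col in ("patient_id", "event_time_min", "cause"):
        if col not in events.columns:
            raise TrialDataError(f"event table lacks column {col!r}")

    if events["patient_id"].duplicated().any():
        dups = events.loc[events["patient_id"].duplicated(), "patient_id"].tolist()
        raise TrialDataError(f"duplicate event rows for patients {dups}")
    dup_meas = meas.duplicated(subset=["patient_id", "time_min"])
    if dup_meas.any():
        dups = meas.loc[dup_meas, "patient_id"].unique().tolist()
        raise TrialDataError(f"duplicate (patient, time) measurement rows for patients {dups}")

    event_ids = set(events["patient_id"].astype(str))
    meas_ids = set(meas["patient_id"].astype(str))
    if meas_ids - event_ids:
        raise TrialDataError(
            f"measurements without an event row for patients {sorted(meas_ids - event_ids)}"
        )
    if event_ids - meas_ids:
        raise TrialDataError(
            f"event rows without measurements for patients {sorted(event_ids - meas_ids)}"
        )

    records = []
    events = events.assign(patient_id=events["patient_id"].astype(str))
    meas = meas.assign(patient_id=meas["patient_id"].astype(str))
    grouped = meas.sort_values(["patient_id", "time_min"]).groupby("patient_id", sort=False)
    by_pid = {pid: g for pid, g in grouped}
    for row in events.itertuples(index=False):
        pid = row.patient_id
        g = by_pid[pid]
        arms = g["arm"].unique()
        if len(arms) != 1:
            raise TrialDataError(f"patient {pid!r}: inconsistent arm labels {arms.tolist()}")
        cause = _parse_cause(row.cause, pid)
        rec = PatientRecord(
            patient_id=pid,
            arm=int(arms[0]),
            measurements=[
                Measurement(pid, float(t), float(v))
                for t, v in zip(g["time_min"], g["score"])
            ],
            event_time=float(row.event_time_min),
            cause=cause,
        )
        records.append(rec)
    # keep the event-table order for reproducibility
    if schedule is None:
        schedule = sorted({float(t) for t in meas["time_min"]}) or [0.0]
    if admin_censor_time is None:
        admin_censor_time = max(
            float(events["event_time_min"].max()) if len(events) else 0.0,
            schedule[-1] if schedule else 0.0,
        )
    return TrialDataset(records, schedule=list(schedule), admin_censor_time=admin_censor_time)


def write_trial_long(dataset: TrialDataset, destination) -> tuple[str, str]:
    """Write the two CSV tables that :func:`read_trial_long` accepts.

    ``destination`` is either a directory (files ``measurements.csv`` and
    ``events.csv`` are created inside it) or a pair of path-like targets.
    Returns the pair of paths written.  Values are written at full precision.
    """
    if isinstance(destination, (tuple, list)):
        meas_path, events_path = destination
    else:
        os.makedirs(destination, exist_ok=True)
        meas_path = os.path.join(destination, "measurements.csv")
        events_path = os.path.join(destination, "events.csv")
    # %.17g guarantees binary round-trip of double-precision scores
    dataset.measurements_frame().to_csv(meas_path, index=False, float_format="%.17g")
    dataset.events_frame().to_csv(events_path, index=False, float_format="%.17g")
    return str(meas_path), str(events_path)


# ---------------------------------------------------------------------------
# Descriptive summaries


@dataclass
class DropoutSummary:
    """Counts and percentages of completion/dropout by arm, Table-1 style.

    Percentage conventions: the baseline row shows each arm's share of the
    total sample; completed and overall-dropout rows are percentages of the
    arm's baseline-assessed count; cause rows are percentages of the arm's
    total dropouts.
    """

    counts: pd.DataFrame  # index: status rows; columns: active, control, total
    percents: pd.DataFrame

    _ROWS = (
        "baseline",
        "completed",
        "dropout",
        "case1_good",
        "case2_poor",
        "case3_unknown",
        "case4_unrelated",
    )

    def table(self) -> pd.DataFrame:
        """Tidy display table with counts and 1-decimal percentages."""
        out = self.counts.copy().astype(object)
        for col in out.columns:
            pct = self.percents[col]
            out[col] = [
                f"{int(n)}" if not np.isfinite(p) else f"{int(n)} ({p:.1f})"
                for n, p in zip(self.counts[col], pct)
            ]
        return out


_CAUSE_ROW = {
    Cause.GOOD: "case1_good",
    Cause.POOR: "case2_poor",
    Cause.UNKNOWN: "case3_unknown",
    Cause.UNRELATED: "case4_unrelated",
}


def summarize_dropout(dataset: TrialDataset) -> DropoutSummary:
    """Summarise completion and dropout-cause counts by treatment arm."""
    rows = DropoutSummary._ROWS
    counts = pd.DataFrame(0, index=list(rows), columns=["active", "control", "total"])
    for rec in dataset.records:
        col = "active" if rec.arm == 1 else "control"
        counts.loc["baseline", col] += 1
        if rec.cause is Cause.COMPLETED:
            counts.loc["completed", col] += 1
        else:
            counts.loc["dropout", col] += 1
            counts.loc[_CAUSE_ROW[rec.cause], col] += 1
    counts["total"] = counts["active"] + counts["control"]

    def pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    percents = pd.DataFrame(np.nan, index=list(rows), columns=counts.columns)
    total_baseline = counts.loc["baseline", "total"]
    total_dropout = counts.loc["dropout", "total"]
    for col in ("active", "control"):
        base = counts.loc["baseline", col]
        drop = counts.loc["dropout", col]
        percents.loc["baseline", col] = pct(counts.loc["baseline", col], total_baseline)
        percents.loc["completed", col] = pct(counts.loc["completed", col], base)
        percents.loc["dropout", col] = pct(drop, base)
        for row in rows[3:]:
            percents.loc[row, col] = pct(counts.loc[row, col], drop)
    percents.loc["completed", "total"] = pct(counts.loc["completed", "total"], total_baseline)
    percents.loc["dropout", "total"] = pct(total_dropout, total_baseline)
    for row in rows[3:]:
        percents.loc[row, "total"] = pct(counts.loc[row, "total"], total_dropout)
    return DropoutSummary(counts=counts, percents=percents)


# ---------------------------------------------------------------------------
# Scenario reclassification


def apply_scenario(
    dataset: TrialDataset,
    scenario: int,
    seed: int | None = None,
    explicit_allocation: Mapping[str, Cause | str] | None = None,
) -> TrialDataset:
    """Reclassify unknown-cause dropouts to good/poor prognosis.

    Scenario 1 (conservative) splits each arm's unknown dropouts as evenly as
    possible between good and poor prognosis, the split chosen at random; an
    odd remainder is assigned by a seeded uniform draw.  ``explicit_allocation``
    (patient_id -> good/poor) overrides the random split but must still be an
    even-as-possible split within each arm.  Scenario 2 (worst case) relabels
    every unknown dropout to poor prognosis.  Completers and unrelated
    dropouts are never touched.
    """
    if scenario not in (1, 2):
        raise ValueError(f"scenario must be 1 or 2, got {scenario!r}")
    out = dataset.copy()
    unknown = [r for r in out.records if r.cause is Cause.UNKNOWN]
    if scenario == 2:
        for rec in unknown:
            rec.cause = Cause.POOR
        return out

    unknown_ids = {r.patient_id for r in unknown}
    if explicit_allocation is not None:
        alloc: dict[str, Cause] = {}
        for pid, raw in explicit_allocation.items():
            cause = Cause(raw) if not isinstance(raw, Cause) else raw
            if cause not in (Cause.GOOD, Cause.POOR):
                raise TrialDataError(
                    f"allocation for {pid!r} must be good or poor, got {raw!r}"
                )
            if pid not in unknown_ids:
                raise TrialDataError(
                    f"allocation references patient {pid!r} whose cause is not unknown"
                )
            alloc[pid] = cause
        missing = unknown_ids - set(alloc)
        if missing:
            raise TrialDataError(f"allocation missing unknown patients {sorted(missing)}")
        for arm in (0, 1):
            ids = [r.patient_id for r in unknown if r.arm == arm]
            n_good = sum(1 for pid in ids if alloc[pid] is Cause.GOOD)
            n_poor = len(ids) - n_good
            if abs(n_good - n_poor) > 1:
                raise TrialDataError(
                    f"arm {arm}: allocation {n_good} good / {n_poor} poor is not an "
                    "even-as-possible split"
                )
        for rec in unknown:
            rec.cause = alloc[rec.patient_id]
        return out

    if seed is None:
        raise ValueError("scenario 1 requires a seed or an explicit allocation")
    rng = np.random.default_rng(seed)
    for arm in (0, 1):
        arm_unknown = [r for r in unknown if r.arm == arm]
        n = len(arm_unknown)
        if n == 0:
            continue
        n_good = n // 2 + (int(rng.integers(2)) if n % 2 else 0)
        order = rng.permutation(n)
        for rank, idx in enumerate(order):
            arm_unknown[idx].cause = Cause.GOOD if rank < n_good else Cause.POOR
    return out


# ---------------------------------------------------------------------------
# Survival-format conversion


def to_survival_records(
    dataset: TrialDataset,
    K: int,
    informative_unrelated: bool | None = None,
) -> list[SurvivalRecord]:
    """Convert the dataset to event format with ``K`` competing causes.

    K=2: good prognosis -> status 1, poor prognosis -> status 2, unrelated
    dropouts and completers -> censored (status 0); unknown causes must have
    been reclassified first.  K=1 codes all-cause informative dropout as
    status 1; by default this includes unrelated dropouts (the single-process
    coding under which every dropout is one event), pass
    ``informative_unrelated=False`` to censor them instead.
    """
    if K not in (1, 2):
        raise ValueError(f"K must be 1 or 2, got {K!r}")
    if informative_unrelated is None:
        informative_unrelated = K == 1
    out: list[SurvivalRecord] = []
    for rec in dataset.records:
        if rec.event_time <= 0:
            raise TrialDataError(
                f"patient {rec.patient_id!r}: event_time must be positive for survival coding"
            )
        if rec.cause is Cause.COMPLETED:
            status = 0
        elif rec.cause is Cause.UNRELATED:
            status = (1 if K == 1 else 0) if informative_unrelated else 0
        elif K == 1:
            status = 1
        else:
            if rec.cause is Cause.UNKNOWN:
                raise TrialDataError(
                    f"patient {rec.patient_id!r}: unknown cause present with K=2; "
                    "apply_scenario must run first"
                )
            status = 1 if rec.cause is Cause.GOOD else 2
        out.append(SurvivalRecord(rec.patient_id, rec.arm, float(rec.event_time), status))
    return out


# ---------------------------------------------------------------------------
# Mean profiles (the data behind completion/cause profile figures)


def mean_profiles(
    dataset: TrialDataset,
    grouping: str = "completion",
    by_arm: bool = False,
) -> pd.DataFrame:
    """Observed mean outcome at each scheduled time within patient groups.

    ``grouping="completion"`` contrasts completers with dropouts (plus an
    all-dropouts group); ``grouping="cause"`` groups by terminal status.  With
    ``by_arm`` the groups are additionally split by treatment arm.  Cells with
    no observations are reported with count 0 and NaN mean.
    """
    if grouping not in ("completion", "cause"):
        raise ValueError(f"grouping must be 'completion' or 'cause', got {grouping!r}")

    def groups_of(rec: PatientRecord) -> list[str]:
        if grouping == "completion":
            if rec.cause is Cause.COMPLETED:
                return ["completed"]
            return ["dropout"]
        return [rec.cause.value]

    rows = []
    obs: dict[tuple, list[float]] = {}
    group_names: set = set()
    for rec in dataset.records:
        for g in groups_of(rec):
            key_base = (g, rec.arm) if by_arm else (g,)
            group_names.add(key_base)
            for m in rec.measurements:
                if m.time in dataset.schedule:
                    obs.setdefault(key_base + (m.time,), []).append(m.value)
    for key_base in sorted(group_names):
        for t in dataset.schedule:
            vals = obs.get(key_base + (t,), [])
            row = {"group": key_base[0]}
            if by_arm:
                row["arm"] = key_base[1]
            row["time_min"] = t
            row["count"] = len(vals)
            row["mean"] = float(np.mean(vals)) if vals else float("nan")
            rows.append(row)
    cols = ["group"] + (["arm"] if by_arm else []) + ["time_min", "count", "mean"]
    return pd.DataFrame(rows, columns=cols)
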