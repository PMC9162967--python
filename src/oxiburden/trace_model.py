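"""Data model and I/O for intraoperative tissue-oximetry traces and patient records.

A cohort lives on disk as one directory::

    cohort_dir/
      cohort.csv            # one row per patient: events, arm, covariates, creatinine
      traces/<patient>.csv  # long format: time_min, channel, value

Times are decimal minutes from induction of anaesthesia; saturations are
percentages in [0, 100].  Missing samples are gaps in the time grid, never
sentinel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CHANNELS = ("renal_left", "renal_right", "renal_mean", "cerebral", "peripheral")
RENAL_CHANNELS = ("renal_left", "renal_right", "renal_mean")
ARMS = ("on_pump", "off_pump")

#: creatinine columns in cohort.csv are crea_day_1 .. crea_day_7 plus extras
_MAX_STORED_DAY = 14


class TraceValidationError(ValueError):
    """A trace or record violates a structural invariant."""


@dataclass(frozen=True)
class OximetryTrace:
    """One channel's saturation time series with surgical event markers.

    Parameters
    ----------
    channel
        One of :data:`CHANNELS`.
    times
        Strictly increasing sample times, decimal minutes from induction.
    values
        Saturation in %, same length as ``times``, each in [0, 100].
    incision_time, end_time
        Surgical incision and end of surgery, minutes.  The analysis window
        for every burden is ``[incision_time, end_time]``.
    """

    channel: str
    times: np.ndarray
    values: np.ndarray
    incision_time: float
    end_time: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.channel not in CHANNELS:
            raise TraceValidationError(f"unknown channel {self.channel!r}")
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise TraceValidationError(
                f"{self.channel}: times and values must be 1-d and equal length"
            )
        if t.size == 0:
            raise TraceValidationError(f"{self.channel}: empty trace")
        if not np.all(np.diff(t) > 0):
            raise TraceValidationError(f"{self.channel}: times must be strictly increasing")
        if not (np.isfinite(v).all() and (v >= 0).all() and (v <= 100).all()):
            raise TraceValidationError(
                f"{self.channel}: saturation values must be finite and within [0, 100]"
            )
        if not np.isfinite(self.incision_time) or not np.isfinite(self.end_time):
            raise TraceValidationError(f"{self.channel}: non-finite event time")
        if not self.incision_time < self.end_time:
            raise TraceValidationError(
                f"{self.channel}: incision_time must precede end_time"
            )

    @property
    def duration(self) -> float:
        """Length of the analysis window in minutes."""
        return self.end_time - self.incision_time

    def covers_window(self, tol: float = 0.0) -> bool:
        """Whether samples span [incision_time, end_time] (± ``tol`` minutes)."""
        return (
            self.times[0] <= self.incision_time + tol
            and self.times[-1] >= self.end_time - tol
        )


@dataclass(frozen=True)
class CreatinineSeries:
    """Serum creatinine: one preoperative baseline plus postoperative days.

    ``postop`` maps postoperative day (integer ≥ 1) to concentration in
    µmol·l⁻¹.  Days beyond the default 7-day labelling window may be stored;
    the outcome rule ignores them.
    """

    baseline_value: float
    postop: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "postop",
            tuple(sorted((int(d), float(v)) for d, v in self.postop)),
        )
        if not (np.isfinite(self.baseline_value) and self.baseline_value > 0):
            raise TraceValidationError("baseline creatinine must be positive")
        days = [d for d, _ in self.postop]
        if len(set(days)) != len(days):
            raise TraceValidationError("duplicate postoperative day")
        for d, v in self.postop:
            if d < 1 or d > _MAX_STORED_DAY:
                raise TraceValidationError(f"postoperative day {d} out of range")
            if not (np.isfinite(v) and v > 0):
                raise TraceValidationError(f"non-positive creatinine on day {d}")


@dataclass(frozen=True)
class PatientRecord:
    """Everything the pipeline needs for one subject."""

    patient_id: str
    traces: Mapping[str, OximetryTrace]
    creatinine: CreatinineSeries
    arm: str
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "traces", dict(self.traces))
        object.__setattr__(self, "covariates", dict(self.covariates))
        if self.arm not in ARMS:
            raise TraceValidationError(f"{self.patient_id}: unknown arm {self.arm!r}")
        for ch, tr in self.traces.items():
            if ch not in CHANNELS:
                raise TraceValidationError(f"{self.patient_id}: unknown channel {ch!r}")
            if tr.channel != ch:
                raise TraceValidationError(
                    f"{self.patient_id}: trace keyed {ch!r} carries channel {tr.channel!r}"
                )

    @property
    def renal_channels(self) -> list[str]:
        return [c for c in RENAL_CHANNELS if c in self.traces]

    @property
    def incision_time(self) -> float:
        return next(iter(self.traces.values())).incision_time

    @property
    def end_time(self) -> float:
        return next(iter(self.traces.values())).end_time


@dataclass(frozen=True)
class RejectedRecord:
    patient_id: str
    reason: str


# ---------------------------------------------------------------------------
# cohort I/O


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> Path:
    """Write a cohort to ``path`` in the documented two-file CSV layout."""
    path = Path(path)
    (path / "traces").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "patient_id": rec.patient_id,
            "arm": rec.arm,
            "incision_time_min": rec.incision_time,
            "end_time_min": rec.end_time,
            "creatinine_baseline": rec.creatinine.baseline_value,
        }
        for d, v in rec.creatinine.postop:
            row[f"crea_day_{d}"] = v
        row.update(rec.covariates)
        rows.append(row)

        tdf = pd.concat(
            [
                pd.DataFrame(
                    {"time_min": tr.times, "channel": ch, "value": tr.values}
                )
                for ch, tr in sorted(rec.traces.items())
            ],
            ignore_index=True,
        )
        tdf.to_csv(path / "traces" / f"{rec.patient_id}.csv", index=False)
    pd.DataFrame(rows).to_csv(path / "cohort.csv", index=False)
    return path


@dataclass
class CohortReadResult:
    records: list[PatientRecord]
    rejected: list[RejectedRecord]


_FIXED_COLS = {
    "patient_id",
    "arm",
    "incision_time_min",
    "end_time_min",
    "creatinine_baseline",
}


def read_cohort(path: str | Path) -> CohortReadResult:
    """Read a cohort directory; invalid records are rejected, never dropped.

    Returns validated :class:`PatientRecord` objects plus a list of
    :class:`RejectedRecord` naming each patient that failed validation and
    why.  An unreadable path is a fatal :class:`FileNotFoundError`.
    """
    path = Path(path)
    cohort_csv = path / "cohort.csv"
    if not cohort_csv.exists():
        raise FileNotFoundError(f"no cohort.csv under {path}")
    # round_trip parsing keeps written values bit-identical on re-read
    meta = pd.read_csv(cohort_csv, float_precision="round_trip")
    records: list[PatientRecord] = []
    rejected: list[RejectedRecord] = []
    crea_cols = [c for c in meta.columns if c.startswith("crea_day_")]
    extra_cols = [c for c in meta.columns if c not in _FIXED_COLS and c not in crea_cols]

    for _, row in meta.iterrows():
        pid = str(row["patient_id"])
        try:
            trace_file = path / "traces" / f"{pid}.csv"
            if not trace_file.exists():
                raise TraceValidationError("no trace file")
            tdf = pd.read_csv(trace_file, float_precision="round_trip")
            if not {"time_min", "channel", "value"} <= set(tdf.columns):
                raise TraceValidationError("trace file missing required columns")
            traces = {}
            for ch, grp in tdf.groupby("channel", sort=True):
                grp = grp.sort_values("time_min")
                traces[str(ch)] = OximetryTrace(
                    channel=str(ch),
                    times=grp["time_min"].to_numpy(dtype=float),
                    values=grp["value"].to_numpy(dtype=float),
                    incision_time=float(row["incision_time_min"]),
                    end_time=float(row["end_time_min"]),
                )
            postop = tuple(
                (int(c.removeprefix("crea_day_")), float(row[c]))
                for c in crea_cols
                if pd.notna(row[c])
            )
            crea = CreatinineSeries(
                baseline_value=float(row["creatinine_baseline"]), postop=postop
            )
            covs = {
                c: float(row[c]) for c in extra_cols if pd.notna(row[c])
            }
            records.append(
                PatientRecord(
                    patient_id=pid,
                    traces=traces,
                    creatinine=crea,
                    arm=str(row["arm"]),
                    covariates=covs,
                )
            )
        except (TraceValidationError, ValueError, KeyError) as exc:
            rejected.append(RejectedRecord(patient_id=pid, reason=str(exc)))
    return CohortReadResult(records=records, rejected=rejected)


# ---------------------------------------------------------------------------
# exclusions


def apply_exclusions(
    records: Iterable[PatientRecord], coverage_tol: float = 0.0
) -> tuple[list[PatientRecord], list[tuple[PatientRecord, str]]]:
    """Partition records into analysable vs excluded-with-reason.

    A record is excluded iff it lacks every renal channel, lacks the
    peripheral channel, or a required trace does not cover the analysis
    window ``[incision_time, end_time]``.  Renal coverage is satisfied when
    at least one renal channel spans the window (unilateral measurements are
    retained).
    """
    analysable: list[PatientRecord] = []
    excluded: list[tuple[PatientRecord, str]] = []
    for rec in records:
        renal = rec.renal_channels
        if not renal:
            excluded.append((rec, "no renal data"))
            continue
        if "peripheral" not in rec.traces:
            excluded.append((rec, "no peripheral data"))
            continue
        if not any(rec.traces[c].covers_window(coverage_tol) for c in renal):
            excluded.append((rec, "insufficient renal data"))
            continue
        if not rec.traces["peripheral"].covers_window(coverage_tol):
            excluded.append((rec, "insufficient peripheral data"))
            continue
        analysable.append(rec)
    return analysable, excluded
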