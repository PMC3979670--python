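"""Timed behavioral event logs: reading, validation, and summaries.

A session is one recorded encounter (60 min for paired males; the
single-male control sessions drop the first and last 5 min, leaving a
50-min window).  Each subject's records are ordered, non-overlapping
bouts; contiguous records of the same behavior are merged into one bout
at read time.  Uncoded gaps are permitted: they count toward total
observation time but toward no behavior, and they do not break
transition chains (nor does resuming the same behavior after a gap
count as a change).
"""

from __future__ import annotations

import csv
import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .ethogram import Ethogram, EthogramError, collapse_low_intensity

#: video frame period; time resolution of scored events
FRAME_S = 1.0 / 30.0

EVENT_COLUMNS = ["session_id", "cohort_age_days", "subject_id", "behavior", "onset_s", "offset_s"]


class EventLogError(ValueError):
    pass


@dataclass(frozen=True)
class EventRecord:
    session_id: str
    cohort_age_days: int
    subject_id: str
    behavior: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset_s <= self.offset_s):
            raise EventLogError(
                f"invalid interval [{self.onset_s}, {self.offset_s}] "
                f"for {self.subject_id}/{self.behavior}"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class EventLog:
    """Validated per-session event records."""

    records: list[EventRecord]
    session_duration_s: float
    session_id: str = ""
    cohort_age_days: int | None = None

    @property
    def subjects(self) -> set[str]:
        return {r.subject_id for r in self.records}

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _merge_and_validate(
    records: Sequence[EventRecord], session_duration_s: float
) -> list[EventRecord]:
    """Sort per subject, check overlaps, merge adjacent same-behavior records."""
    out: list[EventRecord] = []
    by_subject: dict[str, list[EventRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    for subject in sorted(by_subject):
        recs = sorted(by_subject[subject], key=lambda r: (r.onset_s, r.offset_s))
        merged: list[EventRecord] = []
        for r in recs:
            if r.offset_s > session_duration_s + 1e-9:
                raise EventLogError(
                    f"{subject}: offset {r.offset_s} exceeds session duration "
                    f"{session_duration_s}"
                )
            if merged and r.onset_s < merged[-1].offset_s - 1e-9:
                prev = merged[-1]
                raise EventLogError(
                    f"{subject}: overlapping events "
                    f"[{prev.onset_s}, {prev.offset_s}] ({prev.behavior}) and "
                    f"[{r.onset_s}, {r.offset_s}] ({r.behavior})"
                )
            if (
                merged
                and merged[-1].behavior == r.behavior
                and r.onset_s <= merged[-1].offset_s + FRAME_S / 2
            ):
                # contiguous same-behavior records are one bout split at
                # scoring; same behavior after an uncoded gap is a new bout
                merged[-1] = replace(merged[-1], offset_s=max(r.offset_s, merged[-1].offset_s))
            else:
                merged.append(r)
        out.extend(merged)
    return out


def make_event_log(
    records: Iterable[EventRecord],
    session_duration_s: float,
    ethogram: Ethogram | None = None,
    session_id: str = "",
    cohort_age_days: int | None = None,
) -> EventLog:
    """Build a validated :class:`EventLog` from raw records."""
    recs = []
    for r in records:
        code = collapse_low_intensity(r.behavior)
        if ethogram is not None and code not in ethogram:
            raise EthogramError(f"unknown behavior code: {r.behavior!r}")
        recs.append(replace(r, behavior=code) if code != r.behavior else r)
    merged = _merge_and_validate(recs, session_duration_s)
    return EventLog(
        records=merged,
        session_duration_s=session_duration_s,
        session_id=session_id,
        cohort_age_days=cohort_age_days,
    )


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, newline="", encoding="utf-8")


def read_event_log(
    path: Union[str, Path],
    ethogram: Ethogram,
    session_duration_s: float = 3600.0,
    single_male: bool = False,
    trim_s: float = 300.0,
) -> list[EventLog]:
    """Read an event-log CSV (one or more sessions) into validated logs.

    Raw low-intensity scoring names are collapsed to ``Lo``.  With
    ``single_male=True`` the first and last ``trim_s`` seconds are
    discarded (records clipped, times shifted), emulating the 50-min
    effective window of the single-male control sessions.
    """
    path = Path(path)
    rows: dict[str, list[EventRecord]] = {}
    ages: dict[str, int] = {}
    with _open_maybe_gzip(path) as fh:
        reader = csv.DictReader(fh)
        missing = set(EVENT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise EventLogError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            rec = EventRecord(
                session_id=row["session_id"],
                cohort_age_days=int(row["cohort_age_days"]),
                subject_id=row["subject_id"],
                behavior=row["behavior"],
                onset_s=float(row["onset_s"]),
                offset_s=float(row["offset_s"]),
            )
            rows.setdefault(rec.session_id, []).append(rec)
            ages[rec.session_id] = rec.cohort_age_days
    logs = []
    for session_id in sorted(rows):
        recs = rows[session_id]
        duration = session_duration_s
        if single_male:
            lo, hi = trim_s, session_duration_s - trim_s
            clipped = []
            for r in recs:
                if r.offset_s <= lo or r.onset_s >= hi:
                    continue
                clipped.append(
                    replace(
                        r,
                        onset_s=max(r.onset_s, lo) - lo,
                        offset_s=min(r.offset_s, hi) - lo,
                    )
                )
            recs = clipped
            duration = session_duration_s - 2 * trim_s
        logs.append(
            make_event_log(
                recs,
                session_duration_s=duration,
                ethogram=ethogram,
                session_id=session_id,
                cohort_age_days=ages[session_id],
            )
        )
    return logs


def write_event_log(logs: Iterable[EventLog], path: Union[str, Path]) -> None:
    """Write logs in the event-log CSV dialect (gzip if path ends in .gz)."""
    path = Path(path)
    with _open_maybe_gzip(path, "wt") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for log in logs:
            for r in log.records:
                writer.writerow(
                    [
                        r.session_id or log.session_id,
                        r.cohort_age_days,
                        r.subject_id,
                        r.behavior,
                        f"{r.onset_s:.6g}",
                        f"{r.offset_s:.6g}",
                    ]
                )


@dataclass
class TimeBudget:
    """Pooled fraction of observation time occupied per behavior."""

    proportions: dict[str, float]
    total_time_s: float

    def __getitem__(self, code: str) -> float:
        return self.proportions.get(code, 0.0)


def time_budget(logs: Sequence[EventLog], behaviors: Iterable[str]) -> TimeBudget:
    """Pooled time budget across all subjects and sessions of a cohort.

    The denominator is the full observation time (subjects x session
    duration); uncoded time dilutes all proportions, matching the use of
    total arena time as the reference.
    """
    logs = list(logs)
    if not logs:
        raise EventLogError("empty log collection")
    behaviors = list(behaviors)
    total = sum(log.session_duration_s * max(log.n_subjects, 1) for log in logs)
    occupied = {b: 0.0 for b in behaviors}
    for log in logs:
        for r in log.records:
            if r.behavior in occupied:
                occupied[r.behavior] += r.duration_s
    return TimeBudget(
        proportions={b: occupied[b] / total for b in behaviors}, total_time_s=total
    )


def bout_durations(logs: Union[EventLog, Sequence[EventLog]], behavior: str) -> list[float]:
    """Durations (s) of every bout of ``behavior``, in encounter order."""
    if isinstance(logs, EventLog):
        logs = [logs]
    out: list[float] = []
    for log in logs:
        for r in sorted(log.records, key=lambda r: (r.subject_id, r.onset_s)):
            if r.behavior == behavior:
                out.append(r.duration_s)
    return out


@dataclass
class OccurrenceRates:
    """Per-individual occurrence rates (bouts / hour / individual)."""

    values: np.ndarray  # one entry per individual
    mean: float
    sem: float


def occurrence_rate(logs: Sequence[EventLog], behavior: str) -> OccurrenceRates:
    """Bout count per hour for each individual, with mean and s.e.m."""
    rates: list[float] = []
    for log in logs:
        if log.session_duration_s <= 0:
            raise EventLogError(f"session {log.session_id!r} has zero duration")
        counts: dict[str, int] = {s: 0 for s in log.subjects}
        for r in log.records:
            if r.behavior == behavior:
                counts[r.subject_id] += 1
        hours = log.session_duration_s / 3600.0
        for s in sorted(counts):
            rates.append(counts[s] / hours)
    values = np.asarray(rates, dtype=float)
    if values.size == 0:
        raise EventLogError("no individuals in log collection")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / math.sqrt(values.size)) if values.size > 1 else 0.0
    return OccurrenceRates(values=values, mean=mean, sem=sem)


def interval_counts(
    log: EventLog,
    behaviors: Iterable[str],
    interval_s: float = 600.0,
    trim_s: float = 300.0,
) -> np.ndarray:
    """Per-interval bout counts for the pair, onset-based, half-open bins.

    The first and last ``trim_s`` seconds are excluded; the remaining
    window is divided into consecutive intervals of ``interval_s``
    (5 ten-minute intervals for a one-hour session at defaults).  A bout
    is assigned to the interval containing its onset.
    """
    duration = log.session_duration_s
    if duration < 2 * trim_s + interval_s:
        raise EventLogError(
            f"session of {duration}s too short for trim {trim_s}s + interval {interval_s}s"
        )
    n_intervals = int((duration - 2 * trim_s) // interval_s)
    behaviors = set(behaviors)
    counts = np.zeros(n_intervals, dtype=np.int64)
    lo = trim_s
    for r in log.records:
        if r.behavior not in behaviors:
            continue
        idx = int((r.onset_s - lo) // interval_s)
        if 0 <= idx < n_intervals and r.onset_s >= lo:
            counts[idx] += 1
    return counts
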