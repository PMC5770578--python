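"""Minute-level step-stream ingestion and day-level validity filtering.

A consumer activity tracker reports, for each minute in which at least one
step was taken, a timestamped step count.  This module parses those
streams, lays them onto a 90-day observation window that starts on the
first Monday strictly after device activation, applies the "full day" rule
(at least 8 h between the first and last recorded steps of a calendar
day), and partitions the cohort into analyzable and excluded participants
by the >=60-full-days adherence rule.

The day boundary is local civil midnight; daylight-saving transitions do
not move records between calendar days.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import FULL_DAY_SPAN_MIN, MINUTES_PER_DAY, MIN_COMPLETE_DAYS, WINDOW_DAYS


class StreamFormatError(ValueError):
    """Raised when a minute-stream file violates the expected format."""


@dataclass
class MinuteStepStream:
    """Validated per-participant sequence of (minute timestamp, steps).

    Timestamps are strictly increasing at minute resolution; step counts
    are non-negative integers.
    """

    participant_id: str
    timestamps: pd.DatetimeIndex
    steps: np.ndarray

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=np.int64)
        self.timestamps = pd.DatetimeIndex(self.timestamps).as_unit("ns")
        self.timestamps.name = None
        if len(self.timestamps) != len(self.steps):
            raise ValueError("timestamps and steps differ in length")
        if np.any(self.steps < 0):
            raise ValueError("step counts must be non-negative")
        if len(self.timestamps) > 1:
            diffs = np.diff(self.timestamps.asi8)
            if np.any(diffs <= 0):
                pos = int(np.argmax(diffs <= 0))
                raise ValueError(
                    f"timestamps must be strictly increasing; violation at "
                    f"record {pos + 1} ({self.timestamps[pos + 1]})"
                )

    def __len__(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class ObservationWindow:
    """90 consecutive calendar days starting the first Monday after activation."""

    activation_date: dt.date
    start_date: dt.date

    @property
    def end_date(self) -> dt.date:
        return self.start_date + dt.timedelta(days=WINDOW_DAYS - 1)

    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(WINDOW_DAYS)]

    def day_index(self, date: dt.date) -> int | None:
        """1-based day index of *date* within the window, or None if outside."""
        i = (date - self.start_date).days
        return i + 1 if 0 <= i < WINDOW_DAYS else None


@dataclass
class DayProfile:
    """One calendar day's 1440-slot step vector plus validity markers."""

    date: dt.date
    steps_by_minute: np.ndarray  # shape (1440,), non-negative ints
    any_record: bool
    first_step_minute: int | None
    last_step_minute: int | None

    @property
    def span_minutes(self) -> int | None:
        if self.first_step_minute is None:
            return None
        return self.last_step_minute - self.first_step_minute

    @property
    def total_steps(self) -> int:
        return int(self.steps_by_minute.sum())


@dataclass
class ParticipantDays:
    """A participant's 90-day grid of step minutes with full-day flags."""

    participant_id: str
    window: ObservationWindow
    steps: np.ndarray          # shape (90, 1440)
    any_record: np.ndarray     # shape (90,), bool
    first_minute: np.ndarray   # shape (90,), int, -1 where no steps
    last_minute: np.ndarray    # shape (90,), int, -1 where no steps
    full_day: np.ndarray       # shape (90,), bool
    n_records_discarded: int = 0

    @property
    def n_complete_days(self) -> int:
        return int(self.full_day.sum())

    @property
    def n_days_worn(self) -> int:
        return int(self.any_record.sum())

    def day_profile(self, day_index: int) -> DayProfile:
        """Return the DayProfile for a 1-based window day index."""
        i = day_index - 1
        if not 0 <= i < WINDOW_DAYS:
            raise IndexError(f"day index {day_index} outside 1..{WINDOW_DAYS}")
        first = int(self.first_minute[i])
        last = int(self.last_minute[i])
        return DayProfile(
            date=self.window.start_date + dt.timedelta(days=i),
            steps_by_minute=self.steps[i],
            any_record=bool(self.any_record[i]),
            first_step_minute=first if first >= 0 else None,
            last_step_minute=last if last >= 0 else None,
        )


def read_stream(path: str | Path, participant_id: str | None = None) -> MinuteStepStream:
    """Parse a ``timestamp,steps`` CSV into a validated MinuteStepStream.

    The file must have a header row; timestamps are ISO-8601 at minute
    resolution.  Rows that fail to parse, negative counts and duplicate
    minutes are reported with their line number (header = line 1).
    """
    path = Path(path)
    if participant_id is None:
        participant_id = path.stem
    df = pd.read_csv(path, dtype={"steps": "Int64"})
    required = {"timestamp", "steps"}
    if not required.issubset(df.columns):
        raise StreamFormatError(
            f"{path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    if len(df) == 0:
        return MinuteStepStream(participant_id, pd.DatetimeIndex([]), np.empty(0, dtype=np.int64))
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = ts.isna()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise StreamFormatError(f"{path}: unparseable timestamp at line {line}")
    if df["steps"].isna().any():
        line = int(np.flatnonzero(df["steps"].isna())[0]) + 2
        raise StreamFormatError(f"{path}: missing or non-integer steps at line {line}")
    steps = df["steps"].astype(np.int64).to_numpy()
    if (steps < 0).any():
        line = int(np.flatnonzero(steps < 0)[0]) + 2
        raise StreamFormatError(f"{path}: negative step count at line {line}")
    ts = pd.DatetimeIndex(ts).floor("min")
    order = np.argsort(ts.asi8, kind="stable")
    ts, steps = ts[order], steps[order]
    dup = pd.Index(ts).duplicated()
    if dup.any():
        minute = ts[np.flatnonzero(dup)[0]]
        raise StreamFormatError(f"{path}: duplicate record for minute {minute}")
    return MinuteStepStream(participant_id, ts, steps)


def build_window(activation_date: dt.date) -> ObservationWindow:
    """Observation window starting the first Monday strictly after activation.

    An activation that itself falls on a Monday starts the *next* Monday.
    """
    if isinstance(activation_date, dt.datetime):
        activation_date = activation_date.date()
    days_ahead = 7 - activation_date.weekday()  # Monday -> 7 (strictly after)
    start = activation_date + dt.timedelta(days=days_ahead)
    return ObservationWindow(activation_date=activation_date, start_date=start)


def is_full_day(day: DayProfile) -> bool:
    """True iff >=8 h elapsed between the day's first and last steps."""
    span = day.span_minutes
    return span is not None and span >= FULL_DAY_SPAN_MIN


def assemble_participant(stream: MinuteStepStream, window: ObservationWindow) -> ParticipantDays:
    """Place a stream's records into the 90 x 1440 window grid.

    Records outside the window are discarded and counted.  A day is marked
    worn if it has any record at all, and full if its first-to-last-step
    span reaches 8 h.
    """
    steps = np.zeros((WINDOW_DAYS, MINUTES_PER_DAY), dtype=np.int64)
    any_record = np.zeros(WINDOW_DAYS, dtype=bool)
    start = np.datetime64(window.start_date)
    n_discard = 0
    if len(stream) > 0:
        ts64 = stream.timestamps.values
        day_idx = (ts64.astype("datetime64[D]") - start).astype(np.int64)
        minute = (ts64.astype("datetime64[m]")
                  - ts64.astype("datetime64[D]").astype("datetime64[m]")).astype(np.int64)
        in_win = (day_idx >= 0) & (day_idx < WINDOW_DAYS)
        n_discard = int((~in_win).sum())
        d, m, s = day_idx[in_win], minute[in_win], stream.steps[in_win]
        steps[d, m] = s
        any_record[d] = True

    has_steps = steps > 0
    any_steps = has_steps.any(axis=1)
    first = np.where(any_steps, has_steps.argmax(axis=1), -1)
    rev = has_steps[:, ::-1].argmax(axis=1)
    last = np.where(any_steps, MINUTES_PER_DAY - 1 - rev, -1)
    full = any_steps & ((last - first) >= FULL_DAY_SPAN_MIN)
    return ParticipantDays(
        participant_id=stream.participant_id,
        window=window,
        steps=steps,
        any_record=any_record,
        first_minute=first.astype(np.int64),
        last_minute=last.astype(np.int64),
        full_day=full,
        n_records_discarded=n_discard,
    )


def filter_adherent(
    cohort: Iterable[ParticipantDays], min_days: int = MIN_COMPLETE_DAYS
) -> tuple[list[ParticipantDays], list[ParticipantDays]]:
    """Split a cohort into (analyzable, excluded) by complete-day count.

    The threshold is inclusive: exactly ``min_days`` full days qualifies.
    The excluded set is returned, not dropped, because adherence reporting
    covers every included participant.
    """
    analyzable: list[ParticipantDays] = []
    excluded: list[ParticipantDays] = []
    for p in cohort:
        (analyzable if p.n_complete_days >= min_days else excluded).append(p)
    return analyzable, excluded
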