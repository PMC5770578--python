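"""Daily and weekly activity patterns, guideline scoring, imputation, adherence.

Each full day yields: total steps, the morning-step proportion (steps
before noon over total steps, a proxy for morning stiffness), total
activity duration (minutes at >=20 steps/min), MVPA duration (minutes at
>=100 steps/min), vigorous duration (>=130 steps/min) and MVPA steps.
Participant summaries average over full days only; weekly MVPA defaults
to the daily mean times seven.

Missing days of the participants-by-days trajectory matrix are imputed by
the participant's mean of the same weekday over days with data, the
standard same-weekday imputation for actigraphy.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .config import (CadenceThresholds, DEFAULT_CUTOFFS, DEFAULT_THRESHOLDS,
                     GuidelineCutoffs, MINUTES_PER_DAY, MORNING_MINUTES, WINDOW_DAYS)
from .ingest import DayProfile, ParticipantDays, is_full_day

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "steps_total", "morning_fraction", "active_minutes",
    "mvpa_minutes", "vigorous_minutes", "mvpa_steps",
]


@dataclass(frozen=True)
class DailyFeatures:
    """Derived activity patterns for one full day."""

    steps_total: int
    morning_fraction: float  # NaN when the day has zero steps
    active_minutes: int
    mvpa_minutes: int
    vigorous_minutes: int
    mvpa_steps: int


@dataclass(frozen=True)
class RecommendationStatus:
    """Fulfilment of weekly-MVPA and daily-step recommendations."""

    who_mvpa_met: bool
    who_vigorous_met: bool
    steps10k_met: bool
    steps7k_met: bool

    @property
    def who_met(self) -> bool:
        """WHO guideline: moderate *or* vigorous weekly target reached."""
        return self.who_mvpa_met or self.who_vigorous_met


def daily_features(
    day: DayProfile, thresholds: CadenceThresholds = DEFAULT_THRESHOLDS
) -> DailyFeatures:
    """Compute one full day's activity patterns.

    Raises ValueError when called on a day failing the full-day rule; the
    study design analyses full days only.  The morning fraction of a
    zero-step day would be 0/0 and is recorded as NaN (such a day cannot
    be full anyway).
    """
    if not is_full_day(day):
        raise ValueError(
            f"daily_features requires a full day; {day.date} has span "
            f"{day.span_minutes} min"
        )
    v = day.steps_by_minute
    total = int(v.sum())
    morning = float(v[:MORNING_MINUTES].sum() / total) if total > 0 else float("nan")
    return DailyFeatures(
        steps_total=total,
        morning_fraction=morning,
        active_minutes=int((v >= thresholds.rest).sum()),
        mvpa_minutes=int((v >= thresholds.mvpa).sum()),
        vigorous_minutes=int((v >= thresholds.vigorous).sum()),
        mvpa_steps=int(v[v >= thresholds.mvpa].sum()),
    )


def features_table(
    participants: Iterable[ParticipantDays],
    thresholds: CadenceThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Tidy table of daily features over all *full* days of the cohort.

    One row per participant-day, columns ``participant_id, day, date,
    weekday`` plus FEATURE_COLUMNS.  ``day`` is the 1-based window index;
    windows start on a Monday so ``weekday = (day - 1) % 7`` (0 = Monday).
    """
    frames = []
    for p in participants:
        full = np.flatnonzero(p.full_day)
        if len(full) == 0:
            continue
        v = p.steps[full]  # (n_full, 1440)
        totals = v.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            morning = np.where(totals > 0, v[:, :MORNING_MINUTES].sum(axis=1) / totals, np.nan)
        frames.append(pd.DataFrame({
            "participant_id": p.participant_id,
            "day": full + 1,
            "date": [p.window.start_date + dt.timedelta(days=int(i)) for i in full],
            "weekday": full % 7,
            "steps_total": totals,
            "morning_fraction": morning,
            "active_minutes": (v >= thresholds.rest).sum(axis=1),
            "mvpa_minutes": (v >= thresholds.mvpa).sum(axis=1),
            "vigorous_minutes": (v >= thresholds.vigorous).sum(axis=1),
            "mvpa_steps": np.where(v >= thresholds.mvpa, v, 0).sum(axis=1),
        }))
    if not frames:
        return pd.DataFrame(columns=["participant_id", "day", "date", "weekday", *FEATURE_COLUMNS])
    return pd.concat(frames, ignore_index=True)


def participant_summary(
    features: pd.DataFrame,
    weekly_mode: Literal["daily-mean", "week-sum"] = "daily-mean",
) -> pd.DataFrame:
    """Per-participant means of the daily features over their full days.

    Returns one row per participant with the daily means, the number of
    full days, and weekly MVPA/vigorous durations.  ``weekly_mode``
    selects the weekly aggregation: ``"daily-mean"`` multiplies the daily
    mean by 7 (the default); ``"week-sum"`` averages per-calendar-week
    sums rescaled to 7 days when a week is partially observed.  The two
    differ only through week-level missingness structure.
    """
    if len(features) == 0:
        raise ValueError("participant_summary requires at least one full day")
    g = features.groupby("participant_id", sort=True)
    out = g[FEATURE_COLUMNS].mean()
    out["n_complete_days"] = g.size()
    if weekly_mode == "daily-mean":
        out["mvpa_min_per_week"] = out["mvpa_minutes"] * 7.0
        out["vigorous_min_per_week"] = out["vigorous_minutes"] * 7.0
    elif weekly_mode == "week-sum":
        f = features.assign(week=(features["day"] - 1) // 7)
        wk = f.groupby(["participant_id", "week"]).agg(
            mvpa=("mvpa_minutes", "sum"), vig=("vigorous_minutes", "sum"),
            n=("day", "size"))
        wk["mvpa"] *= 7.0 / wk["n"]
        wk["vig"] *= 7.0 / wk["n"]
        w = wk.groupby("participant_id")[["mvpa", "vig"]].mean()
        out["mvpa_min_per_week"] = w["mvpa"]
        out["vigorous_min_per_week"] = w["vig"]
    else:
        raise ValueError(f"unknown weekly_mode {weekly_mode!r}")
    return out.reset_index()


def who_status(
    summary_row: pd.Series | pd.DataFrame,
    cutoffs: GuidelineCutoffs = DEFAULT_CUTOFFS,
) -> RecommendationStatus | pd.DataFrame:
    """Score recommendation fulfilment from a participant summary.

    All comparisons are inclusive.  Accepts a single summary row (returns
    a RecommendationStatus) or the whole summary table (returns a boolean
    DataFrame indexed like the input, with a combined ``who_met`` column).
    """
    if isinstance(summary_row, pd.Series):
        return RecommendationStatus(
            who_mvpa_met=bool(summary_row["mvpa_min_per_week"] >= cutoffs.mvpa_min_per_week),
            who_vigorous_met=bool(summary_row["vigorous_min_per_week"] >= cutoffs.vigorous_min_per_week),
            steps10k_met=bool(summary_row["steps_total"] >= cutoffs.steps_per_day_high),
            steps7k_met=bool(summary_row["steps_total"] >= cutoffs.steps_per_day_low),
        )
    df = summary_row
    out = pd.DataFrame({
        "participant_id": df["participant_id"],
        "who_mvpa_met": df["mvpa_min_per_week"] >= cutoffs.mvpa_min_per_week,
        "who_vigorous_met": df["vigorous_min_per_week"] >= cutoffs.vigorous_min_per_week,
        "steps10k_met": df["steps_total"] >= cutoffs.steps_per_day_high,
        "steps7k_met": df["steps_total"] >= cutoffs.steps_per_day_low,
    })
    out["who_met"] = out["who_mvpa_met"] | out["who_vigorous_met"]
    return out


def trajectory_matrix(features: pd.DataFrame, feature: str = "mvpa_minutes") -> pd.DataFrame:
    """Participants x 90-day matrix of one daily feature; NaN = non-full day."""
    if feature not in FEATURE_COLUMNS:
        raise ValueError(f"unknown feature {feature!r}; choose from {FEATURE_COLUMNS}")
    mat = features.pivot(index="participant_id", columns="day", values=feature)
    mat = mat.reindex(columns=range(1, WINDOW_DAYS + 1))
    mat.columns.name = "day"
    return mat.sort_index()


def impute_missing_days(matrix: pd.DataFrame) -> pd.DataFrame:
    """Fill each missing day with the participant's same-weekday mean.

    Observed cells are left bit-identical.  A participant with no observed
    instance of some weekday falls back to their overall mean across
    observed days (logged); a participant with no observed days at all
    cannot be imputed and raises.
    """
    if matrix.isna().all(axis=1).any():
        bad = matrix.index[matrix.isna().all(axis=1)][0]
        raise ValueError(f"participant {bad!r} has no observed days to impute from")
    weekday = (np.asarray(matrix.columns, dtype=int) - 1) % 7
    values = matrix.to_numpy(dtype=float)
    out = values.copy()
    for wd in range(7):
        cols = weekday == wd
        block = values[:, cols]
        cnt = (~np.isnan(block)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            wd_mean = np.where(cnt > 0, np.nansum(block, axis=1) / np.maximum(cnt, 1),
                               np.nan)
        missing_wd = np.isnan(wd_mean)
        if missing_wd.any():
            overall = np.nanmean(values, axis=1)
            for i in np.flatnonzero(missing_wd):
                logger.info(
                    "participant %s: no observed weekday %d; imputing with overall mean",
                    matrix.index[i], wd,
                )
            wd_mean = np.where(missing_wd, overall, wd_mean)
        block_out = out[:, cols]
        fill = np.broadcast_to(wd_mean[:, None], block_out.shape)
        out[:, cols] = np.where(np.isnan(block_out), fill, block_out)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass(frozen=True)
class AdherenceSummary:
    """Cohort wearing behaviour over the 90-day window (all included participants)."""

    n_participants: int
    mean_days_worn: float
    sd_days_worn: float
    mean_pct_days_worn: float
    sd_pct_days_worn: float
    fraction_ge_80_days: float
    fraction_wearing_at_end: float


def adherence_summary(participants: Sequence[ParticipantDays]) -> AdherenceSummary:
    """Adherence over *all* included participants, analyzable or not.

    A day counts as worn if it has any record, full or not; "wearing at
    the end" means any record during the last 7 window days.
    """
    if len(participants) == 0:
        raise ValueError("adherence_summary requires at least one participant")
    worn = np.array([p.n_days_worn for p in participants], dtype=float)
    at_end = np.array([bool(p.any_record[-7:].any()) for p in participants])
    pct = 100.0 * worn / WINDOW_DAYS
    return AdherenceSummary(
        n_participants=len(participants),
        mean_days_worn=float(worn.mean()),
        sd_days_worn=float(worn.std(ddof=1)) if len(worn) > 1 else 0.0,
        mean_pct_days_worn=float(pct.mean()),
        sd_pct_days_worn=float(pct.std(ddof=1)) if len(pct) > 1 else 0.0,
        fraction_ge_80_days=float((worn >= 80).mean()),
        fraction_wearing_at_end=float(at_end.mean()),
    )
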