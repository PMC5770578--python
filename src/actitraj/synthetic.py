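"""Synthetic tracker cohort with known ground-truth activity classes.

Generates minute-level step streams and a covariate table for a simulated
inflammatory-arthritis cohort (RA and axSpA) followed for 90 days from
the first Monday after device activation.  The cohort mixes three latent
MVPA classes (low / moderate / high) whose means are constant over time,
with weekly periodicity (quieter Sundays), day-to-day noise, whole
missing days, partial wear days, and participant drop-out.  Body-mass
index acts on activity twice: it shifts the latent class propensity
(heavier participants are likelier to fall in the low-activity class) and
multiplicatively depresses activity within class.

Generation is layered so that downstream consumers can stop at the level
they need:

``sample_participants``  -> covariates + latent per-participant means
``sample_daily``         -> day-level targets (steps, MVPA minutes, status)
``generate_cohort``      -> full minute-level streams (renders each day)

Simulation studies of the day-level statistics use the first two layers
directly; the minute renderer realises the same day targets as sparse
cadence records.
"""
from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .config import MINUTES_PER_DAY, WINDOW_DAYS
from .ingest import MinuteStepStream, build_window

DAY_STATUS = {"missing": 0, "partial": 1, "full": 2}

#: Relative propensity of activity per hour of day (00..23).  Chosen to
#: place roughly a third of steps before noon, nothing at night, and a
#: broad afternoon/early-evening plateau; the tracker literature gives no
#: canonical within-day shape, so this is a plausible default, not a
#: validated diurnal model.
HOUR_WEIGHTS = np.array([
    0.0, 0.0, 0.0, 0.0, 0.0, 0.1,
    0.6, 2.2, 3.0, 2.9, 2.9, 2.9,
    3.2, 3.2, 3.1, 3.1, 3.3, 3.6,
    3.8, 3.3, 2.4, 1.4, 0.7, 0.2,
])


@dataclass
class CovariateModel:
    """Distributions of baseline covariates and their effects on activity.

    Defaults mirror a typical established-arthritis outpatient cohort:
    mean age ~46, mean BMI ~25, ~64% female, three quarters employed,
    about half on biologics, well-controlled disease (PtGA ~3/10).

    ``bmi_class_effect`` is the probit shift of the latent activity-class
    propensity per SD of BMI (higher BMI -> likelier low class); with the
    default 0.4 the odds of low-class membership roughly double per
    5 kg/m^2.  ``bmi_activity_decrement`` is the within-class fractional
    loss of mean activity per kg/m^2 above the cohort mean.
    """

    ra_prob: float = 0.53
    female_prob: float = 0.637
    age_mean: float = 45.8
    age_sd: float = 12.5
    bmi_mean: float = 25.1
    bmi_sd: float = 4.5
    duration_mean: float = 10.5
    duration_sd: float = 8.9
    biologic_prob: float = 0.56
    employed_prob: float = 0.764
    ptga_mean: float = 3.3
    ptga_sd: float = 2.4
    bmi_class_effect: float = 0.4
    bmi_activity_decrement: float = 0.02

    def validate(self) -> None:
        for name in ("ra_prob", "female_prob", "biologic_prob", "employed_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"CovariateModel.{name} must be in [0, 1], got {p}")
        for name in ("age_sd", "bmi_sd", "duration_sd", "ptga_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"CovariateModel.{name} must be non-negative")


@dataclass
class CohortSpec:
    """Parameters of the simulated cohort.

    Class structure defaults to the three observed MVPA levels (7.2, 23.8
    and 49.4 min/day at proportions 54.1 / 42.7 / 3.2%).  Class step
    means are set so that the realised cohort mean, Sunday dip included,
    lands near 7100 steps/day.  Missingness defaults reproduce wearing
    ~88% of days (SD of days worn ~17) with ~11% of participants failing
    the 60-full-days rule: each participant's daily missing probability
    is Beta-distributed with mean ``missing_day_prob`` (8%) and
    concentration ``missing_day_concentration`` (adherence differs across
    people), worn days are partial with probability 5%, and 15% of
    participants abandon the tracker at a uniformly drawn day between
    day 30 and day 90.
    """

    n_participants: int = 178
    class_proportions: tuple[float, float, float] = (0.541, 0.427, 0.032)
    class_mvpa_means: tuple[float, float, float] = (7.2, 23.8, 49.4)
    class_daily_steps_means: tuple[float, float, float] = (5950.0, 8750.0, 11400.0)
    sunday_multiplier: float = 0.8
    missing_day_prob: float = 0.08
    missing_day_concentration: float = 37.5
    partial_day_prob: float = 0.05
    dropout_prob: float = 0.15
    dropout_day_min: int = 30
    participant_log_sd: float = 0.2
    mvpa_log_sd: float = 0.2
    daily_log_sd: float = 0.25
    mvpa_daily_log_sd: float = 0.35
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    base_activation_date: dt.date = dt.date(2016, 1, 6)
    activation_spread_days: int = 42
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError("CohortSpec.n_participants must be non-negative")
        if len(self.class_proportions) != 3:
            raise ValueError("CohortSpec.class_proportions must have 3 entries")
        if any(p < 0 for p in self.class_proportions):
            raise ValueError("CohortSpec.class_proportions must be non-negative")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("CohortSpec.class_proportions must sum to 1")
        for name in ("class_mvpa_means", "class_daily_steps_means"):
            if any(m < 0 for m in getattr(self, name)):
                raise ValueError(f"CohortSpec.{name} must be non-negative")
        if not 0.0 < self.sunday_multiplier <= 1.0:
            raise ValueError("CohortSpec.sunday_multiplier must be in (0, 1]")
        for name in ("missing_day_prob", "partial_day_prob", "dropout_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"CohortSpec.{name} must be in [0, 1], got {p}")
        if self.missing_day_prob + self.partial_day_prob > 1.0:
            raise ValueError(
                "CohortSpec.missing_day_prob + partial_day_prob must not exceed 1")
        if self.missing_day_concentration <= 0:
            raise ValueError("CohortSpec.missing_day_concentration must be positive")
        for name in ("participant_log_sd", "mvpa_log_sd", "daily_log_sd",
                     "mvpa_daily_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"CohortSpec.{name} must be non-negative")
        if not 1 <= self.dropout_day_min <= WINDOW_DAYS:
            raise ValueError("CohortSpec.dropout_day_min must be in 1..90")
        self.covariate_model.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["base_activation_date"] = self.base_activation_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "covariate_model" in d and isinstance(d["covariate_model"], dict):
            d["covariate_model"] = CovariateModel(**d["covariate_model"])
        if isinstance(d.get("base_activation_date"), str):
            d["base_activation_date"] = dt.date.fromisoformat(d["base_activation_date"])
        for key in ("class_proportions", "class_mvpa_means", "class_daily_steps_means"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class GroundTruth:
    """Latent generating quantities, kept apart from the covariate table."""

    labels: pd.Series          # participant_id -> class index 0/1/2
    mean_steps: pd.Series      # participant-level mean daily steps (pre-Sunday)
    mean_mvpa: pd.Series       # participant-level mean MVPA min/day (pre-Sunday)
    covariates: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": {k: int(v) for k, v in self.labels.items()},
            "mean_steps": {k: float(v) for k, v in self.mean_steps.items()},
            "mean_mvpa": {k: float(v) for k, v in self.mean_mvpa.items()},
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


@dataclass
class Cohort:
    """A generated cohort: streams, covariates, and withheld ground truth."""

    spec: CohortSpec
    streams: list[MinuteStepStream]
    covariates: pd.DataFrame
    ground_truth: GroundTruth


def _class_thresholds(proportions: tuple[float, float, float], gamma: float) -> tuple[float, float]:
    """Probit cutpoints keeping marginal class proportions exact.

    The latent index is eps - gamma * z_bmi with eps ~ N(0,1), so its
    marginal SD is sqrt(1 + gamma^2); cutting that marginal at the target
    quantiles preserves the proportions for any gamma.
    """
    s = float(np.sqrt(1.0 + gamma * gamma))
    p_low, p_mod, _ = proportions
    lo = norm.ppf(min(max(p_low, 0.0), 1.0)) * s if p_low > 0 else -np.inf
    hi = norm.ppf(min(max(p_low + p_mod, 0.0), 1.0)) * s if p_low + p_mod < 1 else np.inf
    return lo, hi


def sample_participants(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw covariates, latent classes and per-participant activity means.

    Returns one row per participant with covariates, ``activation_date``,
    latent ``class_label`` and the participant-level mean daily steps and
    MVPA minutes (before the Sunday multiplier and day noise).
    """
    spec.validate()
    n = spec.n_participants
    cm = spec.covariate_model
    width = int(np.ceil(np.log10(max(n, 1) + 1)))
    pid = [f"P{i + 1:0{width}d}" for i in range(n)]

    group = np.where(rng.random(n) < cm.ra_prob, "RA", "axSpA")
    female = rng.random(n) < cm.female_prob
    age = np.clip(rng.normal(cm.age_mean, cm.age_sd, n), 18.0, 90.0)
    bmi = np.clip(rng.normal(cm.bmi_mean, cm.bmi_sd, n), 16.0, 45.0)
    duration = np.clip(rng.normal(cm.duration_mean, cm.duration_sd, n), 0.1, None)
    biologic = rng.random(n) < cm.biologic_prob
    employed = rng.random(n) < cm.employed_prob
    ptga = np.clip(rng.normal(cm.ptga_mean, cm.ptga_sd, n), 0.0, 10.0)

    z_bmi = (bmi - cm.bmi_mean) / cm.bmi_sd
    latent = rng.standard_normal(n) - cm.bmi_class_effect * z_bmi
    lo, hi = _class_thresholds(spec.class_proportions, cm.bmi_class_effect)
    label = np.where(latent < lo, 0, np.where(latent < hi, 1, 2))

    u = rng.standard_normal(n)  # shared participant frailty for steps & MVPA
    bmi_mult = np.exp(-cm.bmi_activity_decrement * (bmi - cm.bmi_mean))
    s_sd, m_sd = spec.participant_log_sd, spec.mvpa_log_sd
    steps_means = np.asarray(spec.class_daily_steps_means)[label]
    mvpa_means = np.asarray(spec.class_mvpa_means)[label]
    mean_steps = steps_means * np.exp(s_sd * u - 0.5 * s_sd**2) * bmi_mult
    mean_mvpa = mvpa_means * np.exp(m_sd * u - 0.5 * m_sd**2) * bmi_mult

    # adherence varies across people: per-participant daily missing rate
    if spec.missing_day_prob in (0.0, 1.0):
        p_missing = np.full(n, spec.missing_day_prob)
    else:
        kappa = spec.missing_day_concentration
        p_missing = rng.beta(spec.missing_day_prob * kappa,
                             (1.0 - spec.missing_day_prob) * kappa, n)
        p_missing = np.clip(p_missing, 0.0, 1.0 - spec.partial_day_prob)
    dropout = np.full(n, WINDOW_DAYS + 1)
    dropping = rng.random(n) < spec.dropout_prob
    dropout[dropping] = rng.integers(spec.dropout_day_min, WINDOW_DAYS + 1,
                                     dropping.sum())
    activation = [
        spec.base_activation_date + dt.timedelta(days=int(o))
        for o in rng.integers(0, max(spec.activation_spread_days, 1), n)
    ]
    return pd.DataFrame({
        "participant_id": pid, "group": group,
        "sex": np.where(female, "F", "M"),
        "age": np.round(age, 1), "bmi": np.round(bmi, 1),
        "disease_duration": np.round(duration, 1),
        "biologic": biologic, "employed": employed,
        "ptga": np.round(ptga, 1),
        "activation_date": activation,
        "class_label": label,
        "mean_steps": mean_steps, "mean_mvpa": mean_mvpa,
        "p_missing": p_missing,
        "dropout_day": dropout,
    })


def sample_daily(
    spec: CohortSpec, participants: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw day-level wear status and activity targets for each participant-day.

    Returns a long table (participant_id, day 1..90, weekday, status,
    steps, mvpa_minutes).  Day 1 is a Monday; weekday 6 is Sunday, whose
    mean activity is scaled by ``sunday_multiplier``.  Missing days carry
    zero targets; partial days carry a wear fraction < 1 that the minute
    renderer turns into a short wear window.
    """
    n = len(participants)
    days = np.arange(1, WINDOW_DAYS + 1)
    weekday = (days - 1) % 7
    sun = np.where(weekday == 6, spec.sunday_multiplier, 1.0)

    u = rng.random((n, WINDOW_DAYS))
    status = np.full((n, WINDOW_DAYS), DAY_STATUS["full"], dtype=np.int8)
    pm = participants["p_missing"].to_numpy()[:, None]
    status[u < pm + spec.partial_day_prob] = DAY_STATUS["partial"]
    status[u < pm] = DAY_STATUS["missing"]
    dropout = participants["dropout_day"].to_numpy()[:, None]
    status[days[None, :] >= dropout] = DAY_STATUS["missing"]

    s_sd, m_sd = spec.daily_log_sd, spec.mvpa_daily_log_sd
    step_noise = np.exp(rng.normal(-0.5 * s_sd**2, s_sd, (n, WINDOW_DAYS)))
    mvpa_noise = np.exp(rng.normal(-0.5 * m_sd**2, m_sd, (n, WINDOW_DAYS)))
    steps = participants["mean_steps"].to_numpy()[:, None] * sun[None, :] * step_noise
    lam = participants["mean_mvpa"].to_numpy()[:, None] * sun[None, :] * mvpa_noise
    mvpa = rng.poisson(lam)

    wear_frac = np.ones((n, WINDOW_DAYS))
    partial = status == DAY_STATUS["partial"]
    wear_frac[partial] = rng.uniform(0.15, 0.5, int(partial.sum()))
    steps = np.rint(steps * wear_frac).astype(np.int64)
    mvpa = np.rint(mvpa * wear_frac).astype(np.int64)
    missing = status == DAY_STATUS["missing"]
    steps[missing] = 0
    mvpa[missing] = 0

    return pd.DataFrame({
        "participant_id": np.repeat(participants["participant_id"].to_numpy(), WINDOW_DAYS),
        "day": np.tile(days, n),
        "weekday": np.tile(weekday, n),
        "status": np.array(["missing", "partial", "full"])[status.ravel()],
        "steps": steps.ravel(),
        "mvpa_minutes": mvpa.ravel(),
        "wear_fraction": wear_frac.ravel(),
    })


def simulate_daily_features(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Day-level cohort draw without minute rendering.

    Returns ``(day_table, participants)`` where ``day_table`` holds one
    row per *full* participant-day with ``steps_total`` and
    ``mvpa_minutes`` plus the participant's covariates — the same
    day-level joint distribution the minute renderer realises, minus
    sub-day structure.  This is the generator layer that simulation
    studies of the day-level statistics (mixed models, cluster
    regressions) sample from; replicate-level work would gain nothing
    from rendering and re-aggregating 1440 minutes per day.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    participants = sample_participants(spec, rng)
    daily = sample_daily(spec, participants, rng)
    full = daily[daily["status"] == "full"].rename(columns={"steps": "steps_total"})
    cov_cols = ["participant_id", "group", "sex", "age", "bmi",
                "disease_duration", "biologic", "employed", "ptga"]
    day_table = full.merge(participants[cov_cols], on="participant_id")
    return day_table.reset_index(drop=True), participants


def _render_day(
    steps_target: int,
    mvpa_minutes: int,
    partial: bool,
    minute_logp: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Realise one day's targets as (minute indices, cadences).

    MVPA minutes get cadences ~N(112, 8) clipped to [100, 180]; the
    remaining steps are split 85/15 between light minutes (cadence
    ~N(48, 14) clipped to [20, 99]) and incidental sub-rest minutes
    (cadence 1..19).  A full day receives two sentinel low-cadence
    minutes near 07:30 and 21:00, guaranteeing the 8-h wear span the
    full-day rule requires; a partial day is confined to a wear window
    shorter than 8 h starting between 08:00 and 14:00.
    """
    m = int(mvpa_minutes)
    mvpa_cad = np.clip(np.rint(rng.normal(112.0, 8.0, m)), 100, 180).astype(np.int64)
    rest_steps = max(int(steps_target) - int(mvpa_cad.sum()), 0)
    n_light = int(round(0.85 * rest_steps / 48.0))
    light_cad = np.clip(np.rint(rng.normal(48.0, 14.0, n_light)), 20, 99).astype(np.int64)
    n_low = int(round(0.15 * rest_steps / 10.0))
    low_cad = rng.integers(1, 20, n_low)
    cad = np.concatenate([mvpa_cad, light_cad, low_cad])

    if partial:
        start = int(rng.integers(8 * 60, 14 * 60))
        span = int(rng.integers(120, 479))
        window = np.arange(start, min(start + span, MINUTES_PER_DAY))
        logp = minute_logp[window]
        if len(cad) == 0:
            cad = np.array([int(rng.integers(5, 20))], dtype=np.int64)
        k = min(len(cad), len(window))
        cad = cad[:k]
        keys = logp + rng.gumbel(size=len(window))
        slots = window[np.argpartition(-keys, k - 1)[:k]]
        return slots, cad

    k = min(len(cad), MINUTES_PER_DAY - 2)
    cad = cad[:k]
    keys = minute_logp + rng.gumbel(size=MINUTES_PER_DAY)
    keys[:6 * 60] -= 1e6  # keep the night clear for the sentinel span
    slots = np.argpartition(-keys, k - 1)[:k] if k > 0 else np.empty(0, dtype=int)
    sentinels = np.array([7 * 60 + int(rng.integers(0, 45)),
                          21 * 60 + int(rng.integers(0, 45))])
    sent_cad = rng.integers(3, 16, 2)
    keep = ~np.isin(slots, sentinels)
    return (np.concatenate([slots[keep], sentinels]),
            np.concatenate([cad[keep], sent_cad]))


def _minute_log_weights() -> np.ndarray:
    w = np.repeat(HOUR_WEIGHTS, 60).astype(float)
    with np.errstate(divide="ignore"):
        return np.where(w > 0, np.log(np.maximum(w, 1e-300)), -1e6)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full minute-level cohort for *spec*.

    Deterministic for a fixed ``spec.seed``.  Returns the streams, the
    covariate table (ground-truth labels withheld) and the GroundTruth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    participants = sample_participants(spec, rng)
    daily = sample_daily(spec, participants, rng)
    logp = _minute_log_weights()

    streams: list[MinuteStepStream] = []
    by_pid = daily.groupby("participant_id", sort=False)
    for _, row in participants.iterrows():
        pid = row["participant_id"]
        window = build_window(row["activation_date"])
        start = np.datetime64(window.start_date, "m")
        pdaily = by_pid.get_group(pid)
        all_ts: list[np.ndarray] = []
        all_steps: list[np.ndarray] = []
        for day, status, steps_t, mvpa_t in zip(
            pdaily["day"], pdaily["status"], pdaily["steps"], pdaily["mvpa_minutes"]
        ):
            if status == "missing":
                continue
            slots, cad = _render_day(steps_t, mvpa_t, status == "partial", logp, rng)
            order = np.argsort(slots)
            all_ts.append(start + (int(day) - 1) * MINUTES_PER_DAY + slots[order])
            all_steps.append(cad[order])
        if all_ts:
            ts = pd.DatetimeIndex(np.concatenate(all_ts))
            steps = np.concatenate(all_steps)
        else:
            ts, steps = pd.DatetimeIndex([]), np.empty(0, dtype=np.int64)
        streams.append(MinuteStepStream(pid, ts, steps))

    cov_cols = ["participant_id", "group", "sex", "age", "bmi", "disease_duration",
                "biologic", "employed", "ptga", "activation_date"]
    covariates = participants[cov_cols].copy()
    gt = GroundTruth(
        labels=participants.set_index("participant_id")["class_label"],
        mean_steps=participants.set_index("participant_id")["mean_steps"],
        mean_mvpa=participants.set_index("participant_id")["mean_mvpa"],
        covariates=covariates,
    )
    return Cohort(spec=spec, streams=streams, covariates=covariates, ground_truth=gt)


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort to disk in the ingestible layout.

    ``streams/<pid>.csv`` (timestamp,steps; minute ISO-8601),
    ``covariates.csv``, ``ground_truth.json`` and ``spec.yaml``.  Returns
    the paths written.
    """
    directory = Path(directory)
    stream_dir = directory / "streams"
    stream_dir.mkdir(parents=True, exist_ok=True)
    for s in cohort.streams:
        df = pd.DataFrame({
            "timestamp": s.timestamps.strftime("%Y-%m-%dT%H:%M"),
            "steps": s.steps,
        })
        df.to_csv(stream_dir / f"{s.participant_id}.csv", index=False)
    cov_path = directory / "covariates.csv"
    cohort.covariates.to_csv(cov_path, index=False)
    gt_path = directory / "ground_truth.json"
    cohort.ground_truth.to_json(gt_path)
    spec_path = directory / "spec.yaml"
    spec_path.write_text(yaml.safe_dump(cohort.spec.to_dict(), sort_keys=True))
    return {"streams": stream_dir, "covariates": cov_path,
            "ground_truth": gt_path, "spec": spec_path}
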