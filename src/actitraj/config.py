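"""Shared configuration objects: cadence thresholds and guideline cutoffs.

Cadence (steps per minute) is the tracker's native intensity measure.  A
minute at >=100 steps/min is conventionally taken as moderate-to-vigorous
physical activity (MVPA), >=130 as vigorous, and <20 as rest.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CadenceThresholds:
    """Cadence cutpoints (steps/min) classifying each minute's intensity.

    All comparisons downstream are inclusive (``>=``).
    """

    rest: int = 20
    mvpa: int = 100
    vigorous: int = 130

    def __post_init__(self) -> None:
        if not (0 < self.rest < self.mvpa < self.vigorous):
            raise ValueError(
                "cadence thresholds must satisfy 0 < rest < mvpa < vigorous, "
                f"got rest={self.rest}, mvpa={self.mvpa}, vigorous={self.vigorous}"
            )


@dataclass(frozen=True)
class GuidelineCutoffs:
    """Weekly/daily activity levels used to score guideline fulfilment.

    WHO guidelines ask for >=150 min/week of moderate or >=75 min/week of
    vigorous activity; 10,000 steps/day is the usual healthy-adult step
    target and 7,000 steps/day a commonly cited lower bound.
    """

    mvpa_min_per_week: float = 150.0
    vigorous_min_per_week: float = 75.0
    steps_per_day_high: float = 10_000.0
    steps_per_day_low: float = 7_000.0

    def __post_init__(self) -> None:
        for name in ("mvpa_min_per_week", "vigorous_min_per_week",
                     "steps_per_day_high", "steps_per_day_low"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.steps_per_day_low > self.steps_per_day_high:
            raise ValueError("steps_per_day_low must not exceed steps_per_day_high")


DEFAULT_THRESHOLDS = CadenceThresholds()
DEFAULT_CUTOFFS = GuidelineCutoffs()

#: Minutes per day (fixed tracker resolution).
MINUTES_PER_DAY = 1440
#: Minutes in the morning half of the day (00:00-11:59).
MORNING_MINUTES = 720
#: Minimum first-to-last-step span (minutes) for a "full" day.
FULL_DAY_SPAN_MIN = 480
#: Length of the observation window in calendar days.
WINDOW_DAYS = 90
#: Minimum number of full days for a participant to be analyzable.
MIN_COMPLETE_DAYS = 60
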