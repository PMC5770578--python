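import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from actitraj.ingest import (DayProfile, assemble_participant, build_window,
                             filter_adherent)
from actitraj.synthetic import CohortSpec, generate_cohort


def make_day(minute_steps: dict[int, int], date=dt.date(2016, 1, 11)) -> DayProfile:
    """Build a DayProfile from a {minute: steps} mapping."""
    v = np.zeros(1440, dtype=np.int64)
    for m, s in minute_steps.items():
        v[m] = s
    idx = np.flatnonzero(v > 0)
    return DayProfile(
        date=date,
        steps_by_minute=v,
        any_record=len(minute_steps) > 0,
        first_step_minute=int(idx[0]) if len(idx) else None,
        last_step_minute=int(idx[-1]) if len(idx) else None,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-participant minute-level cohort shared across tests."""
    spec = CohortSpec(n_participants=40, seed=20160111)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_assembled(small_cohort):
    act = dict(zip(small_cohort.covariates["participant_id"],
                   small_cohort.covariates["activation_date"]))
    return [assemble_participant(s, build_window(act[s.participant_id]))
            for s in small_cohort.streams]


@pytest.fixture(scope="session")
def small_analyzable(small_assembled):
    analyzable, _ = filter_adherent(small_assembled)
    return analyzable
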