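import datetime as dt

import numpy as np
import pytest

from mdpa.minutes import (
    MINUTES_PER_DAY,
    WakingWindow,
    build_day_profile,
    validate_week,
)
from mdpa.synthetic import ArmWeekParams, Channel, SimulationConfig, default_config

START = dt.date(2021, 3, 1)
WINDOW = WakingWindow()


def make_day(mets, rmr=1600.0, steps=None, wear=None, date=START):
    """Build a DayProfile from a 1440-long MET vector (kcal consistent)."""
    mets = np.asarray(mets, dtype=float)
    assert len(mets) == MINUTES_PER_DAY
    kcal = mets * rmr / MINUTES_PER_DAY
    steps = np.zeros(MINUTES_PER_DAY) if steps is None else np.asarray(steps)
    wear = np.ones(MINUTES_PER_DAY, dtype=bool) if wear is None else np.asarray(wear)
    return build_day_profile(date, mets, kcal, steps, wear, rmr, WINDOW)


def make_week(day_mets, rmr=1600.0, steps=None, pid="P001", label="baseline"):
    """Build a ParticipantWeek from seven 1440-long MET vectors."""
    days = [
        make_day(
            m,
            rmr=rmr,
            steps=None if steps is None else steps[i],
            date=START + dt.timedelta(days=i),
        )
        for i, m in enumerate(day_mets)
    ]
    return validate_week(days, rmr, pid, label)


def constant_week(met_value, rmr=1600.0, steps_per_min=0):
    mets = np.full(MINUTES_PER_DAY, float(met_value))
    steps = np.full(MINUTES_PER_DAY, steps_per_min)
    return make_week([mets] * 7, rmr=rmr, steps=[steps] * 7)


def zero_sd_params(pal=1.5, sed=60.0, mod=120.0, vig=0.0, mvpa=300.0, steps=7000.0):
    c = lambda m: Channel(m, 0.0)
    return ArmWeekParams(
        pal=c(pal),
        sedentary_pct=c(sed),
        moderate_min_day=c(mod),
        vigorous_bout_min_week=c(vig),
        mvpa_bout_min_week=c(mvpa),
        steps_day=c(steps),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210302)


@pytest.fixture(scope="session")
def small_trial_config():
    """Down-scaled cohort for fast end-to-end tests."""
    cfg = default_config(seed=5)
    return SimulationConfig(
        **{**cfg.__dict__, "n_intervention": 8, "n_control": 6}
    )


@pytest.fixture(scope="session")
def noise_free_config():
    """Deterministic generator: zero SDs, no gaps, no day-to-day noise."""
    cfg = default_config(seed=0)
    params = {
        key: zero_sd_params() for key in cfg.params
    }
    return SimulationConfig(
        **{
            **cfg.__dict__,
            "params": params,
            "gaps_per_day": 0.0,
            "within_day_sd_frac": 0.0,
        }
    )
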