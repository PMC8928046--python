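"""Minute-epoch processing of wearable energy-expenditure records.

The measurement unit throughout the package is the 1-minute epoch.  A day
is exactly 1440 epochs; a participant-week is 7 consecutive days.  This
module turns raw, possibly incomplete device output into complete,
validity-checked 24-hour days:

* MET-based intensity classification (sedentary < 1.8, light [1.8, 3.0),
  moderate [3.0, 6.0), vigorous >= 6.0 METs),
* non-wear imputation at resting metabolic rate (every missing or
  non-wear minute is assigned kcal = RMR/1440, 1.0 MET, 0 steps),
* the valid-day rule (wear covering >= 80% of an assumed 16-hour waking
  day) and the valid-week rule (>= 6 valid days out of 7).

Energy bookkeeping is exact: 1 MET equals the participant's resting
metabolic rate, so a minute at m METs costs m * RMR / 1440 kcal.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MINUTES_PER_DAY",
    "IntensityClass",
    "MET_CUTPOINTS",
    "VALID_DAY_WEAR_FRACTION",
    "MIN_VALID_DAYS",
    "WakingWindow",
    "DayProfile",
    "ParticipantWeek",
    "classify_intensity",
    "intensity_codes",
    "impute_nonwear",
    "build_day_profile",
    "validate_week",
    "week_from_frame",
    "week_to_frame",
]

MINUTES_PER_DAY = 1440

#: Half-open MET cut-points between sedentary/light, light/moderate and
#: moderate/vigorous intensity.
MET_CUTPOINTS = (1.8, 3.0, 6.0)

#: A day is valid when worn minutes cover at least this fraction of the
#: waking window.
VALID_DAY_WEAR_FRACTION = 0.80

#: A week is valid when at least this many of its 7 days are valid.
MIN_VALID_DAYS = 6


class IntensityClass(enum.IntEnum):
    """Activity intensity classes; the values order them by MET level."""

    SEDENTARY = 0
    LIGHT = 1
    MODERATE = 2
    VIGOROUS = 3


def classify_intensity(mets: float) -> IntensityClass:
    """Classify a MET value into its intensity class.

    The classes partition [0, inf) with half-open bounds: sedentary
    [0, 1.8), light [1.8, 3.0), moderate [3.0, 6.0), vigorous [6.0, inf).
    Boundary values therefore belong to the class they open: 1.8 is
    light, 3.0 is moderate, 6.0 is vigorous.
    """
    if mets < 0:
        raise ValueError(f"MET value must be non-negative, got {mets}")
    return IntensityClass(int(np.searchsorted(MET_CUTPOINTS, mets, side="right")))


def intensity_codes(mets: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_intensity`; returns integer class codes."""
    mets = np.asarray(mets)
    if np.any(mets < 0):
        raise ValueError("MET values must be non-negative")
    return np.searchsorted(MET_CUTPOINTS, mets, side="right")


@dataclass(frozen=True)
class WakingWindow:
    """Clock window treated as the waking day (default 07:00-23:00, 16 h).

    Sedentary percentage and the 80% valid-day wear criterion are both
    evaluated against this window only; wear outside it does not count.
    """

    start_minute: int = 7 * 60
    end_minute: int = 23 * 60

    def __post_init__(self) -> None:
        if not (0 <= self.start_minute < self.end_minute <= MINUTES_PER_DAY):
            raise ValueError(
                f"waking window [{self.start_minute}, {self.end_minute}) "
                f"must lie within a 1440-minute day"
            )

    @property
    def length(self) -> int:
        return self.end_minute - self.start_minute

    @property
    def slice(self) -> slice:
        return slice(self.start_minute, self.end_minute)


DEFAULT_WAKING_WINDOW = WakingWindow()


@dataclass
class DayProfile:
    """One complete, imputed 24-hour day (exactly 1440 minute epochs)."""

    date: dt.date
    mets: np.ndarray
    kcal: np.ndarray
    steps: np.ndarray
    imputed: np.ndarray
    window: WakingWindow = field(default_factory=WakingWindow)
    wear_fraction_waking: float = float("nan")
    valid: bool = False

    def __post_init__(self) -> None:
        for name in ("mets", "kcal", "steps", "imputed"):
            arr = getattr(self, name)
            if len(arr) != MINUTES_PER_DAY:
                raise ValueError(f"{name} must have exactly {MINUTES_PER_DAY} entries")

    @property
    def tee_kcal(self) -> float:
        """Total daily energy expenditure (kcal)."""
        return float(self.kcal.sum())

    @property
    def total_steps(self) -> int:
        return int(self.steps.sum())

    def waking(self, name: str) -> np.ndarray:
        """Return the waking-window slice of a minute array."""
        return getattr(self, name)[self.window.slice]


@dataclass
class ParticipantWeek:
    """Seven consecutive imputed days for one participant at one assessment."""

    participant_id: str
    label: str
    days: list[DayProfile]
    rmr_kcal_day: float
    n_valid_days: int = 0
    valid: bool = False

    def mets_matrix(self) -> np.ndarray:
        return np.vstack([d.mets for d in self.days])

    def kcal_matrix(self) -> np.ndarray:
        return np.vstack([d.kcal for d in self.days])

    def steps_matrix(self) -> np.ndarray:
        return np.vstack([d.steps for d in self.days])


def _finalize_day(
    date: dt.date,
    mets: np.ndarray,
    kcal: np.ndarray,
    steps: np.ndarray,
    imputed: np.ndarray,
    window: WakingWindow,
) -> DayProfile:
    worn_waking = int((~imputed[window.slice]).sum())
    frac = worn_waking / window.length
    return DayProfile(
        date=date,
        mets=mets,
        kcal=kcal,
        steps=steps,
        imputed=imputed,
        window=window,
        wear_fraction_waking=frac,
        valid=frac >= VALID_DAY_WEAR_FRACTION - 1e-12,
    )


def build_day_profile(
    date: dt.date,
    mets: np.ndarray,
    kcal: np.ndarray,
    steps: np.ndarray,
    wear: np.ndarray,
    rmr_kcal_day: float,
    window: WakingWindow = DEFAULT_WAKING_WINDOW,
) -> DayProfile:
    """Impute a day given full-length minute arrays and a wear mask.

    Fast-path equivalent of :func:`impute_nonwear` for callers that
    already hold 1440-long arrays (the synthetic generator, bulk
    pipelines).  Non-wear minutes are overwritten with the resting
    assignment; worn minutes are passed through untouched.
    """
    if rmr_kcal_day <= 0:
        raise ValueError("resting metabolic rate must be positive")
    wear = np.asarray(wear, dtype=bool)
    if len(wear) != MINUTES_PER_DAY:
        raise ValueError("wear mask must cover all 1440 minutes")
    imputed = ~wear
    mets = np.where(wear, mets, 1.0).astype(float)
    kcal = np.where(wear, kcal, rmr_kcal_day / MINUTES_PER_DAY).astype(float)
    steps = np.where(wear, steps, 0).astype(np.int64)
    return _finalize_day(date, mets, kcal, steps, imputed, window)


def impute_nonwear(
    records: pd.DataFrame,
    rmr_kcal_day: float,
    *,
    date: dt.date | None = None,
    window: WakingWindow = DEFAULT_WAKING_WINDOW,
) -> DayProfile:
    """Complete one calendar day of raw minute records to 24 hours.

    ``records`` columns: ``timestamp`` (minute-resolution, one calendar
    day), ``mets``, ``kcal``, ``steps`` and optionally ``wear`` (0/1;
    rows missing from the frame are treated as non-wear, as are rows
    with ``wear == 0``).  Every non-wear minute receives the resting
    assignment kcal = RMR/1440, 1.0 MET, 0 steps, ``imputed = True``.

    Raises on duplicate timestamps, sub-minute timestamps, timestamps
    spanning more than one day, negative measurements, or RMR <= 0.
    """
    if rmr_kcal_day <= 0:
        raise ValueError("resting metabolic rate must be positive")

    if len(records) == 0:
        if date is None:
            raise ValueError("empty day requires an explicit date")
        wear = np.zeros(MINUTES_PER_DAY, dtype=bool)
        zeros = np.zeros(MINUTES_PER_DAY)
        return build_day_profile(date, zeros, zeros, zeros, wear, rmr_kcal_day, window)

    ts = pd.to_datetime(records["timestamp"])
    if (ts.dt.second != 0).any() or (ts.dt.microsecond != 0).any():
        raise ValueError("sub-minute timestamps are not supported; epoch is 1 minute")
    day_dates = ts.dt.date.unique()
    if len(day_dates) > 1:
        raise ValueError(f"records span multiple days: {sorted(day_dates)}")
    rec_date = day_dates[0]
    if date is not None and date != rec_date:
        raise ValueError(f"records are dated {rec_date}, expected {date}")

    minute_of_day = (ts.dt.hour * 60 + ts.dt.minute).to_numpy()
    if len(np.unique(minute_of_day)) != len(minute_of_day):
        raise ValueError("duplicate timestamps in day records")

    for col in ("mets", "kcal", "steps"):
        if (records[col].to_numpy() < 0).any():
            raise ValueError(f"negative values in column {col!r}")

    worn = (
        records["wear"].to_numpy().astype(bool)
        if "wear" in records.columns
        else np.ones(len(records), dtype=bool)
    )

    mets = np.zeros(MINUTES_PER_DAY)
    kcal = np.zeros(MINUTES_PER_DAY)
    steps = np.zeros(MINUTES_PER_DAY)
    wear = np.zeros(MINUTES_PER_DAY, dtype=bool)
    idx = minute_of_day[worn]
    mets[idx] = records["mets"].to_numpy()[worn]
    kcal[idx] = records["kcal"].to_numpy()[worn]
    steps[idx] = records["steps"].to_numpy()[worn]
    wear[idx] = True
    return build_day_profile(rec_date, mets, kcal, steps, wear, rmr_kcal_day, window)


def validate_week(
    days: Sequence[DayProfile],
    rmr_kcal_day: float,
    participant_id: str = "",
    label: str = "",
) -> ParticipantWeek:
    """Assemble 7 consecutive days into a week and apply the validity rule.

    A day is valid iff worn minutes cover at least 80% of the waking
    window (768 of 960 minutes for the default 16-hour window); the week
    is valid iff at least 6 of the 7 days are valid.
    """
    if len(days) != 7:
        raise ValueError(f"a participant week needs exactly 7 days, got {len(days)}")
    dates = [d.date for d in days]
    deltas = {(b - a).days for a, b in zip(dates, dates[1:])}
    if deltas != {1}:
        raise ValueError(f"days must be consecutive calendar days, got {dates}")
    n_valid = sum(d.valid for d in days)
    return ParticipantWeek(
        participant_id=participant_id,
        label=label,
        days=list(days),
        rmr_kcal_day=rmr_kcal_day,
        n_valid_days=n_valid,
        valid=n_valid >= MIN_VALID_DAYS,
    )


def week_from_frame(
    frame: pd.DataFrame,
    rmr_kcal_day: float,
    *,
    participant_id: str = "",
    label: str = "",
    window: WakingWindow = DEFAULT_WAKING_WINDOW,
) -> ParticipantWeek:
    """Build a :class:`ParticipantWeek` from a 7-day minute-record frame.

    The frame uses the minute-CSV dialect written by the synthetic
    cohort generator (columns ``timestamp, mets, kcal, steps, wear``);
    missing rows are tolerated and treated as non-wear.
    """
    ts = pd.to_datetime(frame["timestamp"])
    frame = frame.assign(_date=ts.dt.date)
    grouped = dict(tuple(frame.groupby("_date", sort=True)))
    dates = sorted(grouped)
    if not dates:
        raise ValueError("empty week frame")
    start, end = dates[0], dates[-1]
    all_dates = [start + dt.timedelta(days=i) for i in range(7)]
    if end > all_dates[-1]:
        raise ValueError(f"records span more than 7 days ({start} .. {end})")
    days = [
        impute_nonwear(
            grouped.get(d, pd.DataFrame(columns=frame.columns)).drop(
                columns="_date", errors="ignore"
            ),
            rmr_kcal_day,
            date=d,
            window=window,
        )
        for d in all_dates
    ]
    return validate_week(days, rmr_kcal_day, participant_id, label)


def week_to_frame(week: ParticipantWeek) -> pd.DataFrame:
    """Serialise a processed week back to the minute-CSV dialect.

    ``wear`` is 1 for observed minutes and 0 for imputed ones; imputed
    minutes carry their resting-rate assignments so the frame always
    holds the full 7 x 1440 grid.
    """
    frames = []
    for day in week.days:
        start = dt.datetime.combine(day.date, dt.time())
        stamps = pd.date_range(start, periods=MINUTES_PER_DAY, freq="min")
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": stamps,
                    "mets": day.mets,
                    "kcal": day.kcal,
                    "steps": day.steps,
                    "wear": (~day.imputed).astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
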