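"""The six health-harnessing physical-activity dimensions.

Given a valid :class:`~mdpa.minutes.ParticipantWeek` this module computes

* PAL — physical activity level, mean daily total energy expenditure
  divided by resting metabolic rate (unitless),
* sedentary time — percentage of the waking day below 1.8 METs,
* moderate activity — mean daily minutes at >= 3.0 METs (vigorous
  minutes included),
* vigorous bouts — weekly minutes at >= 6.0 METs accumulated in runs of
  at least 10 consecutive minutes,
* MVPA bouts — weekly minutes at >= 3.0 METs accumulated in runs of at
  least 10 consecutive minutes,
* steps — mean daily step count.

Bout detection uses strict contiguity: a bout is a maximal run of
consecutive qualifying minutes, runs are cut at day boundaries, and the
entire maximal run counts once it reaches the minimum length (a 23-min
run contributes 23 minutes).  An optional interruption tolerance can
merge runs separated by short sub-threshold gaps; it defaults to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .minutes import ParticipantWeek

__all__ = [
    "DimensionProfile",
    "InvalidWeekError",
    "compute_pal",
    "sedentary_percent",
    "moderate_minutes_daily",
    "bouted_minutes",
    "mean_daily_steps",
    "multidimensional_profile",
    "profiles_to_frame",
    "DIMENSION_NAMES",
]

DIMENSION_NAMES = (
    "pal",
    "sedentary_pct",
    "moderate_min_day",
    "vigorous_bout_min_week",
    "mvpa_bout_min_week",
    "steps_day",
)

MODERATE_MET = 3.0
VIGOROUS_MET = 6.0
SEDENTARY_MET = 1.8
MIN_BOUT_LEN = 10


class InvalidWeekError(ValueError):
    """Raised when a dimension is requested for an invalid week."""


def _require_valid(week: ParticipantWeek) -> None:
    if not week.valid:
        raise InvalidWeekError(
            f"week {week.label!r} of participant {week.participant_id!r} is "
            f"invalid ({week.n_valid_days} valid days); dimensions are only "
            f"defined for valid weeks"
        )


def compute_pal(week: ParticipantWeek) -> float:
    """Physical activity level: mean over days of daily TEE / RMR."""
    _require_valid(week)
    if week.rmr_kcal_day <= 0:
        raise ValueError("resting metabolic rate must be positive")
    tees = np.array([d.tee_kcal for d in week.days])
    return float(np.mean(tees) / week.rmr_kcal_day)


def sedentary_percent(week: ParticipantWeek) -> float:
    """Percentage of the waking day spent below 1.8 METs, averaged over days."""
    _require_valid(week)
    fracs = [
        float((d.waking("mets") < SEDENTARY_MET).mean()) for d in week.days
    ]
    return 100.0 * float(np.mean(fracs))


def moderate_minutes_daily(week: ParticipantWeek) -> float:
    """Mean daily minutes at >= 3.0 METs (vigorous minutes included)."""
    _require_valid(week)
    counts = [int((d.mets >= MODERATE_MET).sum()) for d in week.days]
    return float(np.mean(counts))


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a boolean vector."""
    if not mask.any():
        return np.empty(0, dtype=int)
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return edges[1::2] - edges[0::2]


def _bouted_in_day(
    mask: np.ndarray, min_bout_len: int, max_interruption: int
) -> int:
    if max_interruption <= 0:
        lengths = _run_lengths(mask)
        return int(lengths[lengths >= min_bout_len].sum())
    # Tolerant rule: runs separated by sub-threshold gaps of at most
    # `max_interruption` minutes are merged; only qualifying minutes are
    # counted, and the merged bout qualifies on its qualifying-minute total.
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    total = 0
    i = 0
    while i < len(starts):
        j = i
        qual = ends[i] - starts[i]
        while j + 1 < len(starts) and starts[j + 1] - ends[j] <= max_interruption:
            j += 1
            qual += ends[j] - starts[j]
        if qual >= min_bout_len:
            total += qual
        i = j + 1
    return total


def bouted_minutes(
    week: ParticipantWeek,
    met_threshold: float,
    min_bout_len: int = MIN_BOUT_LEN,
    max_interruption: int = 0,
) -> float:
    """Weekly minutes at or above a MET threshold accumulated in bouts.

    A bout is a maximal run of consecutive minutes with METs >= the
    threshold inside a single calendar day; only runs of at least
    ``min_bout_len`` minutes count, and every minute of a qualifying
    run is counted.
    """
    _require_valid(week)
    if met_threshold < 0:
        raise ValueError("MET threshold must be non-negative")
    if min_bout_len < 1:
        raise ValueError("minimum bout length must be at least 1 minute")
    total = 0
    for day in week.days:
        total += _bouted_in_day(day.mets >= met_threshold, min_bout_len, max_interruption)
    return float(total)


def mean_daily_steps(week: ParticipantWeek) -> float:
    """Mean daily step count (total weekly steps / 7)."""
    _require_valid(week)
    return float(sum(d.total_steps for d in week.days) / 7.0)


@dataclass(frozen=True)
class DimensionProfile:
    """The six physical-activity dimensions for one participant-week."""

    pal: float
    sedentary_pct: float
    moderate_min_day: float
    vigorous_bout_min_week: float
    mvpa_bout_min_week: float
    steps_day: float

    def __post_init__(self) -> None:
        if self.pal <= 0:
            raise ValueError("PAL must be positive")
        if not (0.0 <= self.sedentary_pct <= 100.0):
            raise ValueError("sedentary percentage must lie in [0, 100]")
        if self.mvpa_bout_min_week < self.vigorous_bout_min_week:
            raise ValueError("MVPA bout minutes cannot be below vigorous bout minutes")
        if self.moderate_min_day * 7 + 1e-9 < self.mvpa_bout_min_week:
            raise ValueError("bouted MVPA cannot exceed total weekly moderate minutes")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def multidimensional_profile(week: ParticipantWeek) -> DimensionProfile:
    """Compute all six dimensions for a valid week."""
    return DimensionProfile(
        pal=compute_pal(week),
        sedentary_pct=sedentary_percent(week),
        moderate_min_day=moderate_minutes_daily(week),
        vigorous_bout_min_week=bouted_minutes(week, VIGOROUS_MET),
        mvpa_bout_min_week=bouted_minutes(week, MODERATE_MET),
        steps_day=mean_daily_steps(week),
    )


def profiles_to_frame(
    profiles: Mapping[tuple[str, str], DimensionProfile]
) -> pd.DataFrame:
    """Tabulate per-participant-week profiles (rows keyed by id and week)."""
    rows = []
    for (pid, label), prof in profiles.items():
        row = {"participant_id": pid, "week": label}
        row.update(prof.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
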