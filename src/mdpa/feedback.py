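"""Feedback computations: health targets, segment review, activity planning.

Mirrors the feedback surface of a multidimensional activity display:

* five configurable health targets — daily calorie burn, sedentary time
  (the only "at most" target), daily moderate minutes, weekly bouted
  MVPA and weekly bouted vigorous activity — scored with a traffic
  light (green = hit, amber = within a proportional band of the target,
  red = missed);
* segment tagging — the energy cost, mean intensity and class
  composition of any interval of a day;
* forward planning — superimposing compendium activities onto a
  recorded week and recomputing the dimensions and target attainment,
  leaving the recorded week untouched.

Planned activities cost ``MET x RMR/1440 kcal`` per minute — the same
personalised scaling the imputation rule uses at 1 MET.
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .dimensions import DimensionProfile, multidimensional_profile
from .minutes import (
    MINUTES_PER_DAY,
    IntensityClass,
    ParticipantWeek,
    classify_intensity,
    intensity_codes,
)

__all__ = [
    "HealthTargetSet",
    "TargetStatus",
    "TargetResult",
    "TargetReport",
    "PlannedActivity",
    "SegmentSummary",
    "PlanOutcome",
    "evaluate_targets",
    "activity_energy_cost",
    "tag_segment",
    "plan_superimpose",
    "load_compendium",
]

#: Deterministic steps/min assigned to planned minutes, by intensity class.
PLAN_CADENCE = {
    IntensityClass.SEDENTARY: 0,
    IntensityClass.LIGHT: 75,
    IntensityClass.MODERATE: 105,
    IntensityClass.VIGOROUS: 125,
}


class TargetStatus(str, enum.Enum):
    GREEN = "green"
    AMBER = "amber"
    RED = "red"


@dataclass(frozen=True)
class HealthTargetSet:
    """The five health targets with a shared proportional amber band.

    Defaults follow public-health guideline magnitudes: calorie burn of
    1.6 x RMR per day (a lower-active-threshold PAL), at most 65% of the
    waking day sedentary, 120 moderate minutes/day, 150 bouted MVPA
    minutes/week and 75 bouted vigorous minutes/week.  All are
    per-participant configurable.
    """

    calorie_burn_kcal_day: float
    sedentary_pct_max: float = 65.0
    moderate_min_day: float = 120.0
    mvpa_bout_min_week: float = 150.0
    vigorous_bout_min_week: float = 75.0
    amber_band: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "calorie_burn_kcal_day",
            "moderate_min_day",
            "mvpa_bout_min_week",
            "vigorous_bout_min_week",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"target {name} must be positive")
        if not (0 < self.sedentary_pct_max <= 100):
            raise ValueError("sedentary target must lie in (0, 100]")
        if not (0 <= self.amber_band < 1):
            raise ValueError("amber band must lie in [0, 1)")

    @classmethod
    def default(cls, rmr_kcal_day: float) -> "HealthTargetSet":
        return cls(calorie_burn_kcal_day=1.6 * rmr_kcal_day)


@dataclass(frozen=True)
class TargetResult:
    name: str
    value: float
    target: float
    direction: str  # "at_least" | "at_most"
    status: TargetStatus


@dataclass
class TargetReport:
    """Traffic-light attainment for the five health targets."""

    results: list[TargetResult]

    def status(self, name: str) -> TargetStatus:
        for r in self.results:
            if r.name == name:
                return r.status
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {**asdict(r), "status": r.status.value}
                for r in self.results
            ]
        )


def _score(value: float, target: float, direction: str, band: float) -> TargetStatus:
    if direction == "at_least":
        if value >= target:
            return TargetStatus.GREEN
        if value >= target * (1.0 - band):
            return TargetStatus.AMBER
        return TargetStatus.RED
    if value <= target:
        return TargetStatus.GREEN
    if value <= target * (1.0 + band):
        return TargetStatus.AMBER
    return TargetStatus.RED


def evaluate_targets(
    profile: DimensionProfile,
    targets: HealthTargetSet,
    rmr_kcal_day: float,
) -> TargetReport:
    """Score a week's dimension profile against the five health targets.

    Daily calorie burn is recovered from the profile as PAL x RMR.
    Sedentary time is the single "at most" dimension; every other
    target is "at least".  A value exactly on target is green.
    """
    if rmr_kcal_day <= 0:
        raise ValueError("resting metabolic rate must be positive")
    band = targets.amber_band
    spec = [
        ("calorie_burn", profile.pal * rmr_kcal_day, targets.calorie_burn_kcal_day, "at_least"),
        ("sedentary", profile.sedentary_pct, targets.sedentary_pct_max, "at_most"),
        ("moderate", profile.moderate_min_day, targets.moderate_min_day, "at_least"),
        ("mvpa_bouts", profile.mvpa_bout_min_week, targets.mvpa_bout_min_week, "at_least"),
        ("vigorous_bouts", profile.vigorous_bout_min_week, targets.vigorous_bout_min_week, "at_least"),
    ]
    return TargetReport(
        results=[
            TargetResult(name, value, target, direction, _score(value, target, direction, band))
            for name, value, target, direction in spec
        ]
    )


def activity_energy_cost(
    met_value: float, duration_min: float, rmr_kcal_day: float
) -> float:
    """Personalised energy cost of an activity: MET x RMR/1440 x minutes.

    One MET is anchored to the participant's measured resting rate, so a
    1-MET activity costs exactly the resting assignment used by
    non-wear imputation.  The intensity category of the activity is
    :func:`mdpa.minutes.classify_intensity` of its MET value.
    """
    if met_value <= 0 or duration_min <= 0 or rmr_kcal_day <= 0:
        raise ValueError("MET value, duration and RMR must all be positive")
    return met_value * (rmr_kcal_day / MINUTES_PER_DAY) * duration_min


@dataclass(frozen=True)
class SegmentSummary:
    total_kcal: float
    mean_mets: float
    total_steps: int
    class_minutes: dict[str, int]


def tag_segment(
    week: ParticipantWeek, day: int, start_minute: int, end_minute: int
) -> SegmentSummary:
    """Summarise a half-open minute interval of one day of a week.

    Returns the segment's energy cost, mean MET level, steps and the
    minute count in each intensity class (which partition the segment).
    """
    if not (0 <= day < len(week.days)):
        raise ValueError(f"day index {day} out of range")
    if not (0 <= start_minute < end_minute <= MINUTES_PER_DAY):
        raise ValueError(
            f"invalid interval [{start_minute}, {end_minute}); must be non-empty "
            f"and lie within the 1440-minute day"
        )
    d = week.days[day]
    sl = slice(start_minute, end_minute)
    codes = intensity_codes(d.mets[sl])
    counts = {
        cls.name.lower(): int((codes == cls.value).sum()) for cls in IntensityClass
    }
    return SegmentSummary(
        total_kcal=float(d.kcal[sl].sum()),
        mean_mets=float(d.mets[sl].mean()),
        total_steps=int(d.steps[sl].sum()),
        class_minutes=counts,
    )


@dataclass(frozen=True)
class PlannedActivity:
    """A forward-planned activity drawn from the MET compendium."""

    name: str
    met_value: float
    start_minute: int  # clock minute of day, 0..1439
    duration_min: int
    days: tuple[int, ...] = (0,)  # day indices within the week, 0..6

    def __post_init__(self) -> None:
        if self.met_value <= 0:
            raise ValueError("MET value must be positive")
        if self.duration_min < 1:
            raise ValueError("duration must be at least 1 minute")
        if not (0 <= self.start_minute and self.start_minute + self.duration_min <= MINUTES_PER_DAY):
            raise ValueError("activity must fit within a single day")
        if not all(0 <= d <= 6 for d in self.days):
            raise ValueError("day indices must lie in 0..6")

    @property
    def intensity(self) -> IntensityClass:
        return classify_intensity(self.met_value)

    def minute_intervals(self) -> list[tuple[int, int, int]]:
        """(day, start, end) half-open intervals covered by this plan."""
        return [
            (d, self.start_minute, self.start_minute + self.duration_min)
            for d in self.days
        ]


@dataclass
class PlanOutcome:
    profile: DimensionProfile
    report: TargetReport
    week: ParticipantWeek


def plan_superimpose(
    week: ParticipantWeek,
    planned_activities: list[PlannedActivity],
    targets: HealthTargetSet | None = None,
) -> PlanOutcome:
    """Superimpose planned activities on a recorded week.

    Planned minutes replace the underlying minutes: METs become the
    plan's compendium value, kcal the personalised per-minute cost, and
    steps a deterministic cadence for the plan's intensity class.  The
    dimensions and target attainment are recomputed on the modified
    copy; the original week is never modified.  Plans that overlap one
    another raise ``ValueError``.
    """
    covered: set[tuple[int, int]] = set()
    for plan in planned_activities:
        for d, s, e in plan.minute_intervals():
            minutes = {(d, m) for m in range(s, e)}
            if covered & minutes:
                raise ValueError(f"planned activity {plan.name!r} overlaps another plan")
            covered |= minutes

    new_week = copy.deepcopy(week)
    rmr = week.rmr_kcal_day
    for plan in planned_activities:
        kcal_min = plan.met_value * rmr / MINUTES_PER_DAY
        cadence = PLAN_CADENCE[plan.intensity]
        for d, s, e in plan.minute_intervals():
            day = new_week.days[d]
            day.mets[s:e] = plan.met_value
            day.kcal[s:e] = kcal_min
            day.steps[s:e] = cadence
            day.imputed[s:e] = False

    profile = multidimensional_profile(new_week)
    if targets is None:
        targets = HealthTargetSet.default(rmr)
    report = evaluate_targets(profile, targets, rmr)
    return PlanOutcome(profile=profile, report=report, week=new_week)


def load_compendium() -> pd.DataFrame:
    """Bundled mini-compendium of activities with MET values.

    A small synthetic excerpt-style table (activity, met_value,
    category) in the spirit of the standard compendium of physical
    activities; the full compendium is external and out of scope.
    """
    with resources.files("mdpa.data").joinpath("compendium.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    return frame
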