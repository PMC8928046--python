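"""Synthetic minute-level two-arm trial generator.

Generates a cohort of participants with the statistical structure a
wearable-feedback RCT analysis assumes: two arms (default 36
intervention, 15 control), three 7-day assessment weeks (baseline, week
6, week 12), minute-by-minute device records (METs, kcal/min, steps,
wear flag) per participant-week, and group-level dimension
distributions calibrated to printed group summaries (means with 95%
CIs).

How a week is built
-------------------
Each participant-week first draws the six published activity dimensions
from normal distributions (between-person SD from the calibration,
person-level random effect shared across assessment weeks).  Because
the bouted dimensions are nested (vigorous bouts <= MVPA bouts <= 7 x
daily moderate minutes), the generator draws *structural* channels:
vigorous bout minutes, moderate bout minutes (MVPA minus vigorous) and
unbouted moderate minutes (7 x moderate/day minus MVPA), with variances
derived by subtraction so the published channels keep their calibrated
means and (approximately) their SDs while the nesting holds by
construction.

The drawn week is then rendered into minutes: a sleep block at 0.9 METs
outside the 16-h waking window; vigorous and moderate bouts cut into
runs of 10-60 minutes (truncated geometric lengths); unbouted moderate
minutes scattered as 1-9-minute runs; the remaining waking minutes
split into sedentary (< 1.8 METs) and light (1.8-3.0 METs) filler whose
within-band MET levels are solved so the day's mean MET equals the
drawn PAL.  Steps follow cadence bands (light 60-89, moderate 90-119,
vigorous 120-140 per minute) rescaled so the day total matches the
drawn steps dimension; kcal/min = METs x RMR/1440 exactly.  Finally
wear gaps are punched uniformly into the waking window to exercise
downstream non-wear imputation.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .minutes import (
    MINUTES_PER_DAY,
    DEFAULT_WAKING_WINDOW,
    WakingWindow,
)

__all__ = [
    "Channel",
    "ArmWeekParams",
    "SimulationConfig",
    "SimulatedTrial",
    "RawWeek",
    "ConfigError",
    "calibrate_from_summary",
    "reference_group_summary",
    "default_config",
    "simulate_participant_week",
    "simulate_trial",
    "draw_week_dimensions",
]

ARMS = ("intervention", "control")
DEFAULT_WEEKS = ("baseline", "week6", "week12")
DIMENSION_CHANNELS = (
    "pal",
    "sedentary_pct",
    "moderate_min_day",
    "vigorous_bout_min_week",
    "mvpa_bout_min_week",
    "steps_day",
)

SLEEP_METS = 0.9
SED_MET_LO, SED_MET_HI = 1.0, 1.8
LIGHT_MET_LO, LIGHT_MET_HI = 1.8, 3.0
MOD_MET_LO, MOD_MET_HI = 3.0, 6.0
VIG_MET_LO, VIG_MET_HI = 6.0, 7.5
#: Step cadence bands (steps/min) by intensity class.
CADENCE = {"light": (60, 90), "moderate": (90, 120), "vigorous": (120, 140)}

_Z975 = sps.norm.ppf(0.975)


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass(frozen=True)
class Channel:
    """Mean and between-person SD of one activity dimension."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError(f"channel SD must be non-negative, got {self.sd}")


@dataclass(frozen=True)
class ArmWeekParams:
    """Dimension distributions for one arm at one assessment week."""

    pal: Channel
    sedentary_pct: Channel
    moderate_min_day: Channel
    vigorous_bout_min_week: Channel
    mvpa_bout_min_week: Channel
    steps_day: Channel

    def validate(self, window_len: int) -> None:
        if not (0 <= self.sedentary_pct.mean <= 100):
            raise ConfigError("mean sedentary percentage must lie in [0, 100]")
        sed_min = self.sedentary_pct.mean / 100.0 * window_len
        if sed_min + self.moderate_min_day.mean > window_len:
            raise ConfigError(
                "infeasible dimension means: sedentary plus moderate minutes "
                "exceed the waking window"
            )
        if self.vigorous_bout_min_week.mean > self.mvpa_bout_min_week.mean + 1e-9:
            raise ConfigError("mean vigorous bouts cannot exceed mean MVPA bouts")
        if self.mvpa_bout_min_week.mean > 7 * self.moderate_min_day.mean + 1e-9:
            raise ConfigError(
                "mean bouted MVPA cannot exceed total weekly moderate minutes"
            )
        if self.pal.mean <= 0:
            raise ConfigError("mean PAL must be positive")


@dataclass
class SimulationConfig:
    """Full description of a simulated two-arm trial.

    ``params`` maps ``(arm, week_label)`` to the dimension distributions
    for that cell.  ``person_corr`` is the correlation between a
    participant's dimension draws across assessment weeks (a shared
    person-level random effect); ``within_day_sd_frac`` scales the
    day-to-day SD of the daily dimensions as a fraction of the cell
    mean.  The wear-gap process punches ``gaps_per_day`` (Poisson mean)
    gaps of exponential mean length ``gap_length_mean_min`` uniformly
    into the waking window.
    """

    params: dict[tuple[str, str], ArmWeekParams]
    n_intervention: int = 36
    n_control: int = 15
    assessment_weeks: tuple[str, ...] = DEFAULT_WEEKS
    person_corr: float = 0.7
    within_day_sd_frac: float = 0.10
    gaps_per_day: float = 1.0
    gap_length_mean_min: float = 15.0
    window: WakingWindow = field(default_factory=WakingWindow)
    sleep_mets: float = SLEEP_METS
    rmr_kcal_day_mean: float = 1600.0
    rmr_kcal_day_sd: float = 200.0
    bmi_mean: float = 27.5
    bmi_sd: float = 4.5
    female_fraction: float = 0.55
    start_date: dt.date = dt.date(2021, 1, 4)
    seed: int = 0

    def validate(self) -> None:
        if self.n_intervention <= 0 or self.n_control <= 0:
            raise ConfigError("arm sizes must be positive")
        if not (0 <= self.person_corr < 1):
            raise ConfigError("person-level correlation must lie in [0, 1)")
        if self.within_day_sd_frac < 0:
            raise ConfigError("within-day SD fraction must be non-negative")
        if self.gaps_per_day < 0 or self.gap_length_mean_min < 0:
            raise ConfigError("wear-gap parameters must be non-negative")
        if not (0 <= self.female_fraction <= 1):
            raise ConfigError("female fraction must lie in [0, 1]")
        if self.rmr_kcal_day_mean <= 0:
            raise ConfigError("mean RMR must be positive")
        for arm in ARMS:
            for week in self.assessment_weeks:
                if (arm, week) not in self.params:
                    raise ConfigError(f"missing dimension params for {(arm, week)}")
        for key, p in self.params.items():
            try:
                p.validate(self.window.length)
            except ConfigError as exc:
                raise ConfigError(f"cell {key}: {exc}") from exc

    # -- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if isinstance(obj, dt.date):
                return obj.isoformat()
            raise TypeError(type(obj))

        payload = dataclasses.asdict(self)
        payload["params"] = {
            f"{arm}/{week}": dataclasses.asdict(p)
            for (arm, week), p in self.params.items()
        }
        payload["start_date"] = self.start_date.isoformat()
        payload["window"] = dataclasses.asdict(self.window)
        return json.dumps(payload, indent=2, default=enc)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        params = {}
        for key, cell in raw.pop("params").items():
            arm, week = key.split("/")
            params[(arm, week)] = ArmWeekParams(
                **{name: Channel(**ch) for name, ch in cell.items()}
            )
        raw["params"] = params
        raw["window"] = WakingWindow(**raw["window"])
        raw["start_date"] = dt.date.fromisoformat(raw["start_date"])
        raw["assessment_weeks"] = tuple(raw["assessment_weeks"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class RawWeek:
    """Pre-imputation minute records for 7 days (with wear gaps)."""

    start_date: dt.date
    mets: np.ndarray  # (7, 1440)
    kcal: np.ndarray
    steps: np.ndarray
    wear: np.ndarray  # bool (7, 1440)

    def to_frame(self) -> pd.DataFrame:
        """Minute-CSV dialect: timestamp, mets, kcal, steps, wear (0/1)."""
        start = dt.datetime.combine(self.start_date, dt.time())
        stamps = pd.date_range(start, periods=7 * MINUTES_PER_DAY, freq="min")
        wear = self.wear.ravel()
        return pd.DataFrame(
            {
                "timestamp": stamps,
                "mets": np.where(wear, self.mets.ravel(), 0.0),
                "kcal": np.where(wear, self.kcal.ravel(), 0.0),
                "steps": np.where(wear, self.steps.ravel(), 0),
                "wear": wear.astype(int),
            }
        )


@dataclass
class SimulatedTrial:
    """A simulated cohort: participant table plus raw minute records."""

    config: SimulationConfig
    participants: pd.DataFrame
    weeks: dict[tuple[str, str], RawWeek]


# ---------------------------------------------------------------------------
# Calibration from printed group summaries
# ---------------------------------------------------------------------------

def calibrate_from_summary(
    group_summary: pd.DataFrame,
    n_per_group: Mapping[str, int] | None = None,
    **config_kwargs,
) -> SimulationConfig:
    """Convert printed group means and 95% CIs into a generator config.

    ``group_summary`` needs columns ``dimension, arm, week, mean,
    ci_low, ci_high`` (one row per dimension/arm/week cell).  The
    between-person SD for each cell is recovered from the normal
    approximation of the CI of a mean::

        SD = (ci_high - ci_low) / (2 * z_0.975) * sqrt(n)

    ``n_per_group`` maps arm name to sample size; by default the arm
    sizes of the returned config (36/15) are used.
    """
    n_per_group = dict(n_per_group or {})
    n_int = int(n_per_group.get("intervention", config_kwargs.get("n_intervention", 36)))
    n_ctl = int(n_per_group.get("control", config_kwargs.get("n_control", 15)))
    sizes = {"intervention": n_int, "control": n_ctl}

    params: dict[tuple[str, str], dict[str, Channel]] = {}
    for row in group_summary.itertuples(index=False):
        if row.ci_high < row.ci_low:
            raise ConfigError(
                f"CI upper bound below lower bound for "
                f"{(row.dimension, row.arm, row.week)}"
            )
        n = sizes[row.arm]
        sd = (row.ci_high - row.ci_low) / (2 * _Z975) * math.sqrt(n)
        params.setdefault((row.arm, row.week), {})[row.dimension] = Channel(
            mean=float(row.mean), sd=float(sd)
        )

    cell_params = {key: ArmWeekParams(**cells) for key, cells in params.items()}
    weeks = tuple(dict.fromkeys(group_summary["week"]))
    cfg = SimulationConfig(
        params=cell_params,
        n_intervention=n_int,
        n_control=n_ctl,
        assessment_weeks=weeks,
        **{k: v for k, v in config_kwargs.items() if k not in ("n_intervention", "n_control")},
    )
    cfg.validate()
    return cfg


#: Group-level summary (mean, 95% CI) of the six activity dimensions in a
#: two-arm wearable-feedback trial (36 intervention / 15 control, three
#: 7-day assessment weeks).  These printed summaries are the default
#: calibration targets for the generator: near-null between-arm
#: differences at week 6 and programmed differences at week 12.
_REFERENCE_SUMMARY_ROWS = [
    # dimension, arm, week, mean, ci_low, ci_high
    ("pal", "intervention", "baseline", 1.61, 1.55, 1.66),
    ("pal", "intervention", "week6", 1.62, 1.57, 1.67),
    ("pal", "intervention", "week12", 1.67, 1.63, 1.72),
    ("pal", "control", "baseline", 1.62, 1.55, 1.68),
    ("pal", "control", "week6", 1.65, 1.58, 1.72),
    ("pal", "control", "week12", 1.58, 1.52, 1.64),
    ("sedentary_pct", "intervention", "baseline", 69, 66, 73),
    ("sedentary_pct", "intervention", "week6", 69, 66, 72),
    ("sedentary_pct", "intervention", "week12", 66, 63, 69),
    ("sedentary_pct", "control", "baseline", 69, 64, 73),
    ("sedentary_pct", "control", "week6", 66, 62, 70),
    ("sedentary_pct", "control", "week12", 70, 65, 74),
    ("moderate_min_day", "intervention", "baseline", 111, 94, 129),
    ("moderate_min_day", "intervention", "week6", 118, 105, 130),
    ("moderate_min_day", "intervention", "week12", 132, 118, 147),
    ("moderate_min_day", "control", "baseline", 117, 99, 135),
    ("moderate_min_day", "control", "week6", 127, 107, 148),
    ("moderate_min_day", "control", "week12", 109, 89, 131),
    ("vigorous_bout_min_week", "intervention", "baseline", 42, 23, 65),
    ("vigorous_bout_min_week", "intervention", "week6", 48, 30, 70),
    ("vigorous_bout_min_week", "intervention", "week12", 50, 30, 73),
    ("vigorous_bout_min_week", "control", "baseline", 26, 12, 43),
    ("vigorous_bout_min_week", "control", "week6", 46, 24, 71),
    ("vigorous_bout_min_week", "control", "week12", 33, 14, 55),
    ("mvpa_bout_min_week", "intervention", "baseline", 539, 435, 646),
    ("mvpa_bout_min_week", "intervention", "week6", 584, 495, 675),
    ("mvpa_bout_min_week", "intervention", "week12", 658, 571, 750),
    ("mvpa_bout_min_week", "control", "baseline", 509, 400, 622),
    ("mvpa_bout_min_week", "control", "week6", 580, 441, 725),
    ("mvpa_bout_min_week", "control", "week12", 462, 340, 587),
    ("steps_day", "intervention", "baseline", 7403, 6705, 8093),
    ("steps_day", "intervention", "week6", 8207, 7269, 9114),
    ("steps_day", "intervention", "week12", 8782, 7987, 9656),
    ("steps_day", "control", "baseline", 7767, 6626, 8884),
    ("steps_day", "control", "week6", 8280, 7268, 9114),
    ("steps_day", "control", "week12", 7236, 6496, 7991),
]


#: Printed ANCOVA-adjusted week-12 differences (intervention - control)
#: accompanying the reference summaries; these are the programmed effects
#: of the default generator.
REFERENCE_ADJUSTED_DIFFERENCES_WK12 = {
    "pal": 0.09,
    # The sedentary effect is printed as -40 min/day of the 16-h waking
    # day; the percentage summary rounds it to -4. Program the finer
    # minutes-per-day value: -40/9.6 percentage points.
    "sedentary_pct": -40.0 / 9.6,
    "moderate_min_day": 24.0,
    "vigorous_bout_min_week": 18.0,
    "mvpa_bout_min_week": 195.0,
    "steps_day": 1545.0,
}


def reference_group_summary() -> pd.DataFrame:
    """The bundled calibration table of printed group summaries."""
    return pd.DataFrame(
        _REFERENCE_SUMMARY_ROWS,
        columns=["dimension", "arm", "week", "mean", "ci_low", "ci_high"],
    )


def default_config(seed: int = 0, **kwargs) -> SimulationConfig:
    """Generator with the reference calibration and programmed effects.

    Between-person SDs come from the printed per-cell CIs.  Cell means
    are arranged so that the *true* adjusted differences are known
    exactly: both arms share the pooled printed mean at baseline and
    week 6 (null effects), and at week 12 the intervention mean is the
    printed control mean plus the printed adjusted difference.  Because
    the printed summaries are internally consistent, the resulting
    week-12 intervention means sit within one unit of their printed
    cells.  An ANCOVA on such a trial estimates the programmed week-12
    difference without the confounding a chance baseline imbalance in
    the printed cells would otherwise introduce.
    """
    cfg = calibrate_from_summary(reference_group_summary(), seed=seed, **kwargs)
    n1, n2 = cfg.n_intervention, cfg.n_control
    new_params = dict(cfg.params)
    for week in ("baseline", "week6"):
        cells = {}
        for dim in DIMENSION_CHANNELS:
            ch_i = getattr(cfg.params[("intervention", week)], dim)
            ch_c = getattr(cfg.params[("control", week)], dim)
            pooled = (n1 * ch_i.mean + n2 * ch_c.mean) / (n1 + n2)
            cells[dim] = (Channel(pooled, ch_i.sd), Channel(pooled, ch_c.sd))
        new_params[("intervention", week)] = ArmWeekParams(
            **{d: cells[d][0] for d in DIMENSION_CHANNELS}
        )
        new_params[("control", week)] = ArmWeekParams(
            **{d: cells[d][1] for d in DIMENSION_CHANNELS}
        )
    wk12 = {}
    for dim in DIMENSION_CHANNELS:
        ctrl = getattr(cfg.params[("control", "week12")], dim)
        sd_i = getattr(cfg.params[("intervention", "week12")], dim).sd
        wk12[dim] = Channel(
            ctrl.mean + REFERENCE_ADJUSTED_DIFFERENCES_WK12[dim], sd_i
        )
    new_params[("intervention", "week12")] = ArmWeekParams(**wk12)
    cfg.params = new_params
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Dimension-level draws
# ---------------------------------------------------------------------------

def _structural_channels(p: ArmWeekParams) -> dict[str, Channel]:
    """Derive the generative channels from the published ones.

    Vigorous bouts, moderate bouts (MVPA - vigorous) and unbouted
    moderate minutes (7 x moderate/day - MVPA) are treated as
    independent, so the published nested channels keep their means
    exactly and their variances add.  A negative variance difference
    (over-dispersed inner channel) is floored at zero.
    """

    def sub_sd(outer_sd: float, inner_sd: float) -> float:
        return math.sqrt(max(outer_sd**2 - inner_sd**2, 0.0))

    vig = p.vigorous_bout_min_week
    modbout = Channel(
        mean=p.mvpa_bout_min_week.mean - vig.mean,
        sd=sub_sd(p.mvpa_bout_min_week.sd, vig.sd),
    )
    unbouted = Channel(
        mean=7 * p.moderate_min_day.mean - p.mvpa_bout_min_week.mean,
        sd=sub_sd(7 * p.moderate_min_day.sd, p.mvpa_bout_min_week.sd),
    )
    return {
        "pal": p.pal,
        "sedentary_pct": p.sedentary_pct,
        "vig_bout": vig,
        "mod_bout": modbout,
        "unbouted": unbouted,
        "steps_day": p.steps_day,
    }


_CHANNELS = ("pal", "sedentary_pct", "vig_bout", "mod_bout", "unbouted", "steps_day")
#: Channels that are rectified at zero (activity volumes cannot be negative).
_RECTIFIED = ("sedentary_pct", "vig_bout", "mod_bout", "unbouted", "steps_day")


@lru_cache(maxsize=8192)
def _rectified_location(mean: float, sd: float) -> float:
    """Location m such that E[max(m + sd*Z, 0)] equals ``mean``.

    Non-negative channels are drawn as rectified normals; without this
    correction the rectification would inflate low-mean/high-SD cells
    (heavily skewed channels such as vigorous bouts) differently in the
    two arms and bias the programmed between-arm differences.
    """
    if sd == 0 or mean >= 6 * sd:
        return mean
    if mean <= 1e-9 * max(sd, 1.0):
        return mean - 8.0 * sd

    def excess(m: float) -> float:
        z = m / sd
        return m * sps.norm.cdf(z) + sd * sps.norm.pdf(z) - mean

    from scipy.optimize import brentq

    return float(brentq(excess, mean - 12.0 * sd, mean))


def _draw_channels(
    params: ArmWeekParams,
    person_effects: np.ndarray,
    person_corr: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Draw one participant-week's structural channel values."""
    rho = person_corr
    chans = _structural_channels(params)
    noise = rng.standard_normal(len(_CHANNELS))
    out: dict[str, float] = {}
    for i, name in enumerate(_CHANNELS):
        ch = chans[name]
        z = rho * person_effects[i] + math.sqrt(1 - rho**2) * noise[i]
        loc = _rectified_location(ch.mean, ch.sd) if name in _RECTIFIED else ch.mean
        out[name] = loc + ch.sd * z
    # Rectify to the feasible orthant; the structural decomposition keeps
    # the nested dimension constraints satisfied automatically.
    out["sedentary_pct"] = float(np.clip(out["sedentary_pct"], 0.0, 100.0))
    for name in ("vig_bout", "mod_bout", "unbouted", "steps_day"):
        out[name] = max(out[name], 0.0)
    return out


def draw_week_dimensions(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Draw the dimension values of every participant-week, without
    rendering minutes.

    This is the generator's distributional layer: the same channel
    draws :func:`simulate_trial` renders into minute records, returned
    directly as published dimensions.  Useful for calibration studies
    (null rejection rates, large replicate counts) where the minute
    renderer's rounding noise is irrelevant.
    """
    config.validate()
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    rows = []
    participants = _draw_participants(config, rng)
    effects = {
        pid: rng.standard_normal(len(_CHANNELS))
        for pid in participants["participant_id"]
    }
    for row in participants.itertuples(index=False):
        for week in config.assessment_weeks:
            draws = _draw_channels(
                config.params[(row.arm, week)],
                effects[row.participant_id],
                config.person_corr,
                rng,
            )
            mvpa = draws["vig_bout"] + draws["mod_bout"]
            rows.append(
                {
                    "participant_id": row.participant_id,
                    "arm": row.arm,
                    "sex": row.sex,
                    "weight_status": row.weight_status,
                    "week": week,
                    "pal": draws["pal"],
                    "sedentary_pct": draws["sedentary_pct"],
                    "moderate_min_day": (mvpa + draws["unbouted"]) / 7.0,
                    "vigorous_bout_min_week": draws["vig_bout"],
                    "mvpa_bout_min_week": mvpa,
                    "steps_day": draws["steps_day"],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Minute rendering
# ---------------------------------------------------------------------------

def _cut_bouts(total: float, rng: np.random.Generator) -> list[int]:
    """Cut a weekly bout-minute total into bout lengths in {10..60}.

    Totals of at least 10 minutes are conserved exactly; totals in
    (0, 10) produce a single 10-minute bout with probability total/10,
    preserving the expectation.
    """
    t = int(round(total))
    if t <= 0:
        return []
    if t < 10:
        return [10] if rng.random() < t / 10.0 else []
    lengths: list[int] = []
    rem = t
    while rem >= 10:
        L = 10 + min(int(rng.geometric(0.12)) - 1, 50)
        L = min(L, rem)
        if 0 < rem - L < 10:
            # Avoid leaving an un-boutable remainder.
            L = rem if rem <= 60 else rem - 10
        lengths.append(L)
        rem -= L
    return lengths


def _cut_runs(total: int, rng: np.random.Generator) -> list[int]:
    """Cut scattered (unbouted) minutes into runs of 1-9 minutes."""
    lengths: list[int] = []
    rem = int(total)
    while rem > 0:
        L = min(int(rng.integers(1, 10)), rem)
        lengths.append(L)
        rem -= L
    return lengths


def _day_noise(rng: np.random.Generator, mean: float, frac: float) -> float:
    return float(rng.normal(0.0, frac * abs(mean))) if frac > 0 else 0.0


def _render_day(
    runs: list[tuple[int, str]],
    sed_minutes: int,
    pal_target: float,
    steps_target: float,
    rng: np.random.Generator,
    window: WakingWindow,
    sleep_mets: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one waking day; returns (mets, steps) full-length arrays.

    ``runs`` holds (length, kind) activity runs with kind in
    {"vigorous", "moderate"}.  Raises ``ConfigError`` when the activity
    budget cannot fit in the waking window.
    """
    wlen = window.length
    activity = sum(L for L, _ in runs)
    n_runs = len(runs)
    if activity + max(n_runs - 1, 0) > wlen:
        raise ConfigError(
            f"infeasible day budget: {activity} activity minutes in "
            f"{n_runs} runs exceed the {wlen}-minute waking window"
        )
    filler = wlen - activity
    sed_minutes = int(np.clip(sed_minutes, 0, filler))
    light_minutes = filler - sed_minutes

    # Per-minute MET draws for the activity runs.
    order = rng.permutation(n_runs) if n_runs else np.array([], dtype=int)
    run_mets: list[np.ndarray] = []
    for idx in order:
        L, kind = runs[idx]
        lo, hi = (VIG_MET_LO, VIG_MET_HI) if kind == "vigorous" else (MOD_MET_LO, MOD_MET_HI)
        run_mets.append(rng.uniform(lo, hi, L))
    activity_sum = float(sum(r.sum() for r in run_mets))

    # Solve the filler MET levels so the day's mean MET hits the PAL draw.
    sleep_total = sleep_mets * (MINUTES_PER_DAY - wlen)
    required = pal_target * MINUTES_PER_DAY - sleep_total - activity_sum
    lo_sum = sed_minutes * SED_MET_LO + light_minutes * LIGHT_MET_LO
    hi_sum = sed_minutes * (SED_MET_HI - 0.05) + light_minutes * (LIGHT_MET_HI - 0.05)

    # When the filler bands cannot carry the day's energy budget, move
    # the excess (or deficit) onto the activity-run minutes within their
    # own class bands, so high-PAL/low-PAL draws are not clipped.
    if run_mets and (required > hi_sum or required < lo_sum):
        caps = []
        floors = []
        for idx, r in zip(order, run_mets):
            if runs[idx][1] == "vigorous":
                caps.append(np.full(len(r), 12.0))
                floors.append(np.full(len(r), VIG_MET_LO))
            else:
                caps.append(np.full(len(r), MOD_MET_HI - 0.01))
                floors.append(np.full(len(r), MOD_MET_LO))
        flat = np.concatenate(run_mets)
        if required > hi_sum:
            head = np.concatenate(caps) - flat
            total = head.sum()
            if total > 0:
                flat = flat + head * (min(required - hi_sum, total) / total)
        else:
            foot = flat - np.concatenate(floors)
            total = foot.sum()
            if total > 0:
                flat = flat - foot * (min(lo_sum - required, total) / total)
        offsets = np.cumsum([0] + [len(r) for r in run_mets])
        run_mets = [flat[a:b] for a, b in zip(offsets[:-1], offsets[1:])]
        activity_sum = float(flat.sum())
        required = pal_target * MINUTES_PER_DAY - sleep_total - activity_sum
    lam = 0.0 if hi_sum <= lo_sum else float(np.clip((required - lo_sum) / (hi_sum - lo_sum), 0.0, 1.0))
    sed_level = SED_MET_LO + lam * (SED_MET_HI - 0.05 - SED_MET_LO)
    light_level = LIGHT_MET_LO + lam * (LIGHT_MET_HI - 0.05 - LIGHT_MET_LO)

    # Symmetric within-band jitter keeps the solved means exact.
    sed_jit = min(0.04, sed_level - SED_MET_LO, SED_MET_HI - 1e-6 - sed_level)
    light_jit = min(0.04, light_level - LIGHT_MET_LO, LIGHT_MET_HI - 1e-6 - light_level)
    filler_mets = np.concatenate(
        [
            sed_level + rng.uniform(-sed_jit, sed_jit, sed_minutes),
            light_level + rng.uniform(-light_jit, light_jit, light_minutes),
        ]
    )
    rng.shuffle(filler_mets)

    # Interleave: one filler minute between consecutive runs, the rest
    # spread multinomially over the n_runs + 1 gaps.
    n_gaps = n_runs + 1
    base = np.zeros(n_gaps, dtype=int)
    if n_runs > 1:
        base[1:-1] = 1
    extra = filler - int(base.sum())
    base += rng.multinomial(extra, np.full(n_gaps, 1.0 / n_gaps))

    pieces: list[np.ndarray] = []
    cursor = 0
    for i in range(n_runs):
        pieces.append(filler_mets[cursor : cursor + base[i]])
        cursor += base[i]
        pieces.append(run_mets[i])
    pieces.append(filler_mets[cursor:])
    waking = np.concatenate(pieces) if pieces else np.empty(0)

    mets = np.full(MINUTES_PER_DAY, sleep_mets)
    mets[window.slice] = waking

    steps = _render_steps(mets, steps_target, rng, window)
    return mets, steps


def _render_steps(
    mets: np.ndarray,
    steps_target: float,
    rng: np.random.Generator,
    window: WakingWindow,
) -> np.ndarray:
    """Cadence-band step counts rescaled to hit the day's step total."""
    steps = np.zeros(MINUTES_PER_DAY)
    w = window.slice
    wmets = mets[w]
    cadence = np.zeros(window.length)
    light = (wmets >= LIGHT_MET_LO) & (wmets < MOD_MET_LO)
    moderate = (wmets >= MOD_MET_LO) & (wmets < VIG_MET_LO)
    vigorous = wmets >= VIG_MET_LO
    cadence[light] = rng.uniform(*CADENCE["light"], int(light.sum()))
    cadence[moderate] = rng.uniform(*CADENCE["moderate"], int(moderate.sum()))
    cadence[vigorous] = rng.uniform(*CADENCE["vigorous"], int(vigorous.sum()))
    total = cadence.sum()
    target = max(int(round(steps_target)), 0)
    if total <= 0 or target == 0:
        return steps
    scaled = cadence * (target / total)
    ints = np.floor(scaled).astype(np.int64)
    deficit = target - int(ints.sum())
    if deficit > 0:
        frac = scaled - ints
        top = np.argsort(frac)[::-1][:deficit]
        ints[top] += 1
    steps[w] = ints
    return steps


def simulate_participant_week(
    arm_week_params: ArmWeekParams,
    participant_attrs: Mapping[str, float],
    seed: int | np.random.Generator,
    *,
    config: SimulationConfig | None = None,
    start_date: dt.date | None = None,
    channel_draws: Mapping[str, float] | None = None,
) -> RawWeek:
    """Simulate raw minute records for one participant over 7 days.

    ``participant_attrs`` must provide ``rmr_kcal_day``.  When
    ``channel_draws`` is given (the trial simulator passes its
    person-correlated draws), the between-person draw step is skipped.
    """
    cfg = config or SimulationConfig(
        params={(arm, week): arm_week_params for arm in ARMS for week in ("w",)},
        assessment_weeks=("w",),
    )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rmr = float(participant_attrs["rmr_kcal_day"])
    if rmr <= 0:
        raise ConfigError("participant RMR must be positive")
    arm_week_params.validate(cfg.window.length)

    if channel_draws is None:
        channel_draws = _draw_channels(
            arm_week_params, rng.standard_normal(len(_CHANNELS)), cfg.person_corr, rng
        )

    window = cfg.window
    frac = cfg.within_day_sd_frac

    # Weekly bout structure.
    vig_bouts = [(L, "vigorous") for L in _cut_bouts(channel_draws["vig_bout"], rng)]
    mod_bouts = [(L, "moderate") for L in _cut_bouts(channel_draws["mod_bout"], rng)]
    unbouted_total = int(round(channel_draws["unbouted"]))
    day_unbouted = rng.multinomial(unbouted_total, np.full(7, 1.0 / 7.0))

    day_runs: list[list[tuple[int, str]]] = [[] for _ in range(7)]
    for bout in vig_bouts + mod_bouts:
        day_runs[int(rng.integers(0, 7))].append(bout)
    for d in range(7):
        day_runs[d].extend((L, "moderate") for L in _cut_runs(day_unbouted[d], rng))

    mets = np.empty((7, MINUTES_PER_DAY))
    steps = np.empty((7, MINUTES_PER_DAY))
    wear = np.ones((7, MINUTES_PER_DAY), dtype=bool)
    for d in range(7):
        sed_pct = channel_draws["sedentary_pct"] + _day_noise(
            rng, channel_draws["sedentary_pct"], frac
        )
        sed_minutes = int(round(np.clip(sed_pct, 0.0, 100.0) / 100.0 * window.length))
        # Day-to-day PAL variation acts on the activity margin above rest,
        # not on the resting floor of 1.0.
        pal_margin = max(channel_draws["pal"] - 1.0, 0.1)
        pal_day = channel_draws["pal"] + _day_noise(rng, pal_margin, frac)
        steps_day = max(
            channel_draws["steps_day"] + _day_noise(rng, channel_draws["steps_day"], frac),
            0.0,
        )
        mets[d], steps[d] = _render_day(
            day_runs[d], sed_minutes, pal_day, steps_day, rng, window, cfg.sleep_mets
        )
        # Wear gaps, uniform within the waking window.
        for _ in range(int(rng.poisson(cfg.gaps_per_day))):
            length = max(int(round(rng.exponential(cfg.gap_length_mean_min))), 1)
            start = int(rng.integers(window.start_minute, window.end_minute))
            wear[d, start : min(start + length, window.end_minute)] = False

    kcal = mets * (rmr / MINUTES_PER_DAY)
    return RawWeek(
        start_date=start_date or cfg.start_date,
        mets=mets,
        kcal=kcal,
        steps=steps,
        wear=wear,
    )


def _draw_participants(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = config.n_intervention + config.n_control
    arms = np.array(
        ["intervention"] * config.n_intervention + ["control"] * config.n_control
    )
    rng.shuffle(arms)
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    bmi = np.maximum(rng.normal(config.bmi_mean, config.bmi_sd, n), 16.0)
    rmr = np.maximum(
        rng.normal(config.rmr_kcal_day_mean, config.rmr_kcal_day_sd, n), 800.0
    )
    ids = [f"P{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "participant_id": ids,
            "arm": arms,
            "sex": sex,
            "bmi": np.round(bmi, 1),
            # BMI >= 30 is the binary weight-status stratification cutoff.
            "weight_status": (bmi >= 30.0).astype(int),
            "rmr_kcal_day": np.round(rmr, 0),
        }
    )


def simulate_trial(config: SimulationConfig) -> SimulatedTrial:
    """Simulate a full two-arm trial; reproducible given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    participants = _draw_participants(config, rng)
    effects = {
        pid: rng.standard_normal(len(_CHANNELS))
        for pid in participants["participant_id"]
    }
    weeks: dict[tuple[str, str], RawWeek] = {}
    for row in participants.itertuples(index=False):
        for w_idx, week in enumerate(config.assessment_weeks):
            params = config.params[(row.arm, week)]
            draws = _draw_channels(
                params, effects[row.participant_id], config.person_corr, rng
            )
            raw = simulate_participant_week(
                params,
                {"rmr_kcal_day": row.rmr_kcal_day},
                rng,
                config=config,
                start_date=config.start_date + dt.timedelta(weeks=6 * w_idx),
                channel_draws=draws,
            )
            weeks[(row.participant_id, week)] = raw
    return SimulatedTrial(config=config, participants=participants, weeks=weeks)
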