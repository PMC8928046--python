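"""Two-arm trial statistics: baseline-adjusted ANCOVA, BCa bootstrap,
Hedges g, subgroup descriptives and the activity-based eligibility
screen.

The estimand for every outcome is the adjusted mean difference
(intervention minus control) from the linear model

    follow_up ~ group + baseline + sex + weight_status

where sex and weight status (BMI >= 30) are the stratification factors
of the randomisation.  Confidence intervals come from a
bias-corrected-and-accelerated (BCa) bootstrap, resampling participants
with replacement stratified by arm so the allocation ratio is
preserved; the bias constant z0 is the normal quantile of the fraction
of bootstrap statistics below the observed value and the acceleration
is the jackknife skewness

    a = sum((theta_bar - theta_i)^3) / (6 * [sum((theta_bar - theta_i)^2)]^(3/2)).

Effect sizes are Hedges g: the adjusted difference divided by the
pooled follow-up SD, times the small-sample correction
J = 1 - 3 / (4 * (n1 + n2 - 2) - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AdjustedEffect",
    "EligibilityResult",
    "ancova_adjusted_difference",
    "adjusted_effect",
    "bca_bootstrap_ci",
    "hedges_g",
    "hedges_correction",
    "subgroup_descriptives",
    "eligibility_screen",
    "effects_to_frame",
    "PAL_ELIGIBILITY_CUTOFF",
]

#: Participants with a baseline physical activity level at or above this
#: value are classed as already highly active and excluded.
PAL_ELIGIBILITY_CUTOFF = 2.0


@dataclass
class AdjustedEffect:
    """ANCOVA-adjusted mean difference for one outcome at one time point."""

    outcome: str
    timepoint: str
    adjusted_md: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    hedges_g: float = float("nan")
    g_ci_low: float = float("nan")
    g_ci_high: float = float("nan")
    n1: int = 0
    n2: int = 0
    reps: int = 0
    seed: int | None = None
    robust_se: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def _design(
    table: pd.DataFrame,
    outcome: str,
    timepoint: str,
    baseline_label: str = "baseline",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (y, X, arm indicator) for the ANCOVA, with listwise deletion."""
    ycol, bcol = f"{outcome}_{timepoint}", f"{outcome}_{baseline_label}"
    for col in (ycol, bcol, "arm", "sex", "weight_status"):
        if col not in table.columns:
            raise KeyError(f"outcome table lacks column {col!r}")
    sub = table[[ycol, bcol, "arm", "sex", "weight_status"]].dropna()
    arms = set(sub["arm"])
    if not arms <= {"intervention", "control"}:
        raise ValueError(f"unknown arm labels: {arms - {'intervention', 'control'}}")
    if arms != {"intervention", "control"}:
        raise ValueError("both trial arms are required for an adjusted difference")
    y = sub[ycol].to_numpy(float)
    group = (sub["arm"] == "intervention").to_numpy(float)
    base = sub[bcol].to_numpy(float)
    sex = (sub["sex"].astype(str).str.lower().isin(("female", "f"))).to_numpy(float)
    weight = sub["weight_status"].to_numpy(float)
    X = np.column_stack([np.ones(len(y)), group, base, sex, weight])
    return y, X, group


_COVARIATE_NAMES = ("intercept", "group", "baseline", "sex", "weight_status")


def _fit_group_coef(y: np.ndarray, X: np.ndarray, warn: bool = False) -> float:
    """Least-squares group coefficient, dropping constant covariates."""
    keep = [0, 1]
    for j in range(2, X.shape[1]):
        if np.ptp(X[:, j]) > 0:
            keep.append(j)
        elif warn:
            warnings.warn(
                f"covariate {_COVARIATE_NAMES[j]!r} is constant and was dropped",
                RuntimeWarning,
                stacklevel=3,
            )
    if np.ptp(X[:, 1]) == 0:
        raise ValueError("all participants fall in one arm; no contrast to estimate")
    beta, *_ = np.linalg.lstsq(X[:, keep], y, rcond=None)
    return float(beta[1])


def ancova_adjusted_difference(
    table: pd.DataFrame,
    outcome: str,
    timepoint: str,
    baseline_label: str = "baseline",
) -> AdjustedEffect:
    """Point estimate of the adjusted mean difference (intervention - control).

    ``table`` has one row per participant with columns ``arm``, ``sex``,
    ``weight_status`` and ``{outcome}_{label}`` value columns.
    """
    y, X, group = _design(table, outcome, timepoint, baseline_label)
    n1, n2 = int(group.sum()), int((1 - group).sum())
    if min(n1, n2) < 2:
        raise ValueError("each arm needs at least 2 participants with complete data")
    md = _fit_group_coef(y, X, warn=True)
    return AdjustedEffect(
        outcome=outcome, timepoint=timepoint, adjusted_md=md, n1=n1, n2=n2
    )


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------

def _bca_interval(
    observed: float,
    boot: np.ndarray,
    jack: np.ndarray,
    level: float,
) -> tuple[float, float]:
    """Adjusted-percentile bounds from bootstrap and jackknife statistics."""
    if np.ptp(boot) == 0:
        warnings.warn(
            "degenerate bootstrap distribution; returning a point-mass interval",
            RuntimeWarning,
            stacklevel=3,
        )
        return float(boot[0]), float(boot[0])
    reps = len(boot)
    below = np.sum(boot < observed) + 0.5 * np.sum(boot == observed)
    prop = min(max(below / reps, 0.5 / reps), 1 - 0.5 / reps)
    z0 = sps.norm.ppf(prop)
    theta_bar = jack.mean()
    d = theta_bar - jack
    denom = (d**2).sum() ** 1.5
    a = 0.0 if denom == 0 else (d**3).sum() / (6.0 * denom)
    alpha = (1.0 - level) / 2.0
    lo_hi = []
    for z_alpha in (sps.norm.ppf(alpha), sps.norm.ppf(1 - alpha)):
        adj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
        lo_hi.append(float(np.quantile(boot, sps.norm.cdf(adj))))
    return lo_hi[0], lo_hi[1]


def bca_bootstrap_ci(
    statistic_fn: Callable,
    data,
    *,
    strata: np.ndarray | None = None,
    reps: int = 5000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI of a statistic.

    ``data`` is either an integer ``n`` — then ``statistic_fn`` receives
    integer row-index arrays into ``0..n-1`` (the fast path) — or a
    DataFrame/array, in which case ``statistic_fn`` receives the
    resampled object itself.  When ``strata`` is given (length-n label
    array) resampling is with replacement *within* each stratum, so a
    trial's allocation ratio is preserved.
    """
    if reps < 100:
        raise ValueError("at least 100 bootstrap replications are required")
    if not (0 < level < 1):
        raise ValueError("confidence level must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if isinstance(data, (int, np.integer)):
        n = int(data)
        stat = statistic_fn
    else:
        obj = data
        n = len(obj)
        if isinstance(obj, pd.DataFrame):
            def stat(idx, _obj=obj):
                return statistic_fn(_obj.iloc[idx])
        else:
            arr = np.asarray(obj)
            def stat(idx, _arr=arr):
                return statistic_fn(_arr[idx])
    if n < 2:
        raise ValueError("need at least 2 observations to bootstrap")

    observed = float(stat(np.arange(n)))

    if strata is None:
        groups = [np.arange(n)]
    else:
        strata = np.asarray(strata)
        if len(strata) != n:
            raise ValueError("strata labels must match the data length")
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]

    boot = np.empty(reps)
    for r in range(reps):
        idx = np.concatenate(
            [g[rng.integers(0, len(g), len(g))] for g in groups]
        )
        boot[r] = stat(idx)

    jack = np.empty(n)
    all_idx = np.arange(n)
    for i in range(n):
        jack[i] = stat(np.delete(all_idx, i))

    return _bca_interval(observed, boot, jack, level)


# ---------------------------------------------------------------------------
# Hedges g
# ---------------------------------------------------------------------------

def hedges_correction(n1: int, n2: int) -> float:
    """Small-sample correction J = 1 - 3 / (4 * (n1 + n2 - 2) - 1)."""
    df = n1 + n2 - 2
    if df < 1:
        raise ValueError("need at least 3 participants across arms")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    return float(
        np.sqrt(
            ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        )
    )


def hedges_g(
    table: pd.DataFrame,
    adjusted_md: float,
    outcome: str,
    timepoint: str,
) -> float:
    """Hedges g for an adjusted mean difference.

    The denominator is the follow-up SD pooled across arms; the
    numerator is the ANCOVA-adjusted difference, so g carries its sign.
    """
    ycol = f"{outcome}_{timepoint}"
    sub = table[[ycol, "arm"]].dropna()
    a = sub.loc[sub["arm"] == "intervention", ycol].to_numpy(float)
    b = sub.loc[sub["arm"] == "control", ycol].to_numpy(float)
    if min(len(a), len(b)) < 2:
        raise ValueError("each arm needs at least 2 participants")
    s = _pooled_sd(a, b)
    if s == 0:
        raise ValueError("pooled follow-up SD is zero; effect size undefined")
    return hedges_correction(len(a), len(b)) * adjusted_md / s


# ---------------------------------------------------------------------------
# Full adjusted effect (point estimate + BCa CI + effect size)
# ---------------------------------------------------------------------------

def adjusted_effect(
    table: pd.DataFrame,
    outcome: str,
    timepoint: str,
    *,
    baseline_label: str = "baseline",
    reps: int = 5000,
    level: float = 0.95,
    seed: int | None = 0,
    robust: bool = True,
) -> AdjustedEffect:
    """ANCOVA-adjusted difference with BCa CI and Hedges g (with CI).

    One stratified bootstrap (participants resampled within arm) drives
    both the difference CI and the effect-size CI.  ``robust`` adds the
    heteroscedasticity-robust (HC3) model SE of the group coefficient.
    """
    ycol, bcol = f"{outcome}_{timepoint}", f"{outcome}_{baseline_label}"
    sub = table[[ycol, bcol, "arm", "sex", "weight_status"]].dropna().reset_index(drop=True)
    y, X, group = _design(sub, outcome, timepoint, baseline_label)
    n1, n2 = int(group.sum()), int((1 - group).sum())
    if min(n1, n2) < 2:
        raise ValueError("each arm needs at least 2 participants with complete data")
    md = _fit_group_coef(y, X, warn=True)
    g_obs = hedges_g(sub, md, outcome, timepoint)

    grp_bool = group.astype(bool)

    def md_stat(idx: np.ndarray) -> float:
        return _fit_group_coef(y[idx], X[idx])

    def g_stat(idx: np.ndarray) -> float:
        md_i = _fit_group_coef(y[idx], X[idx])
        gi = grp_bool[idx]
        s = _pooled_sd(y[idx][gi], y[idx][~gi])
        return hedges_correction(int(gi.sum()), int((~gi).sum())) * md_i / s if s else 0.0

    rng = np.random.default_rng(seed)
    ci_low, ci_high = bca_bootstrap_ci(
        md_stat, len(y), strata=group, reps=reps, level=level, seed=rng
    )
    g_low, g_high = bca_bootstrap_ci(
        g_stat, len(y), strata=group, reps=reps, level=level, seed=rng
    )

    robust_se = float("nan")
    if robust:
        import statsmodels.api as sm

        keep = [0, 1] + [j for j in range(2, X.shape[1]) if np.ptp(X[:, j]) > 0]
        fit = sm.OLS(y, X[:, keep]).fit(cov_type="HC3")
        robust_se = float(fit.bse[1])

    return AdjustedEffect(
        outcome=outcome,
        timepoint=timepoint,
        adjusted_md=md,
        ci_low=ci_low,
        ci_high=ci_high,
        hedges_g=g_obs,
        g_ci_low=g_low,
        g_ci_high=g_high,
        n1=n1,
        n2=n2,
        reps=reps,
        seed=seed,
        robust_se=robust_se,
    )


def effects_to_frame(effects: Sequence[AdjustedEffect]) -> pd.DataFrame:
    """Tabulate adjusted effects (one row per outcome x time point)."""
    frame = pd.DataFrame([e.as_dict() for e in effects])
    cols = [
        "outcome", "timepoint", "adjusted_md", "ci_low", "ci_high",
        "hedges_g", "g_ci_low", "g_ci_high", "n1", "n2", "reps", "seed",
        "robust_se",
    ]
    return frame[cols]


# ---------------------------------------------------------------------------
# Subgroups and eligibility
# ---------------------------------------------------------------------------

def subgroup_descriptives(
    table: pd.DataFrame,
    outcome: str,
    by: str,
    timepoints: Sequence[str] = ("baseline", "week6", "week12"),
    baseline_pal_col: str = "pal_baseline",
) -> pd.DataFrame:
    """Unadjusted mean (SD) per subgroup x arm x time point.

    ``by`` is ``"sex"`` or ``"baseline_activity"``; the latter splits at
    the cohort median baseline PAL, ties going to the low group.  Empty
    cells are reported with ``n = 0`` and missing means, not errors.
    """
    if by == "sex":
        labels = table["sex"].astype(str)
        groups = sorted(labels.unique())
    elif by == "baseline_activity":
        med = table[baseline_pal_col].median()
        labels = pd.Series(
            np.where(table[baseline_pal_col] <= med, "low", "high"),
            index=table.index,
        )
        groups = ["low", "high"]
    else:
        raise ValueError("subgroup variable must be 'sex' or 'baseline_activity'")
    if labels.isna().any():
        raise ValueError(f"subgroup variable {by!r} has missing values")

    rows = []
    for sub in groups:
        for arm in ("intervention", "control"):
            mask = (labels == sub) & (table["arm"] == arm)
            for tp in timepoints:
                vals = table.loc[mask, f"{outcome}_{tp}"].dropna()
                rows.append(
                    {
                        "subgroup": sub,
                        "arm": arm,
                        "timepoint": tp,
                        "n": len(vals),
                        "mean": float(vals.mean()) if len(vals) else float("nan"),
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class EligibilityResult:
    included: list[str]
    excluded: list[tuple[str, str]]  # (participant id, reason)


def eligibility_screen(
    baseline_pal: Mapping[str, float] | pd.Series,
    cutoff: float = PAL_ELIGIBILITY_CUTOFF,
) -> EligibilityResult:
    """Screen out participants already highly active at baseline.

    Inclusion requires baseline PAL strictly below the cutoff (default
    2.0); a participant at exactly the cutoff is excluded.
    """
    if isinstance(baseline_pal, pd.Series):
        items = baseline_pal.items()
    else:
        items = baseline_pal.items()
    included, excluded = [], []
    for pid, pal in items:
        if pal < cutoff:
            included.append(pid)
        else:
            excluded.append((pid, f"baseline PAL {pal:.2f} >= {cutoff} (highly active)"))
    return EligibilityResult(included=included, excluded=excluded)
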