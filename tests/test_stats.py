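"""Trial statistics: ANCOVA, BCa bootstrap, Hedges g, subgroups, screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mdpa.stats import (
    PAL_ELIGIBILITY_CUTOFF,
    adjusted_effect,
    ancova_adjusted_difference,
    bca_bootstrap_ci,
    eligibility_screen,
    hedges_correction,
    hedges_g,
    subgroup_descriptives,
)
from mdpa.stats import _bca_interval


def make_table(n1=36, n2=15, delta=0.0, seed=0, rho=0.7, sd=1.0, mean=10.0):
    """Outcome table with correlated baseline/follow-up values."""
    rng = np.random.default_rng(seed)
    n = n1 + n2
    arm = np.array(["intervention"] * n1 + ["control"] * n2)
    u = rng.standard_normal(n)
    base = mean + sd * (rho * u + np.sqrt(1 - rho**2) * rng.standard_normal(n))
    follow = (
        mean
        + delta * (arm == "intervention")
        + sd * (rho * u + np.sqrt(1 - rho**2) * rng.standard_normal(n))
    )
    return pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "arm": arm,
            "sex": rng.choice(["female", "male"], n),
            "weight_status": rng.integers(0, 2, n),
            "y_baseline": base,
            "y_week12": follow,
        }
    )


class TestAncova:
    def test_noise_free_identity(self):
        """follow-up = baseline + delta * group recovers delta exactly."""
        table = make_table(seed=1)
        table["y_week12"] = table["y_baseline"] + 2.5 * (
            table["arm"] == "intervention"
        )
        eff = ancova_adjusted_difference(table, "y", "week12")
        assert eff.adjusted_md == pytest.approx(2.5, abs=1e-10)
        assert (eff.n1, eff.n2) == (36, 15)

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        table = make_table(delta=1.0, seed=2)
        eff = ancova_adjusted_difference(table, "y", "week12")
        X = np.column_stack(
            [
                np.ones(len(table)),
                (table["arm"] == "intervention").astype(float),
                table["y_baseline"],
                (table["sex"] == "female").astype(float),
                table["weight_status"].astype(float),
            ]
        )
        fit = sm.OLS(table["y_week12"].to_numpy(), X).fit()
        assert eff.adjusted_md == pytest.approx(fit.params[1], abs=1e-10)

    def test_constant_covariate_dropped_with_warning(self):
        table = make_table(seed=3)
        table["weight_status"] = 0
        with pytest.warns(RuntimeWarning, match="weight_status"):
            eff = ancova_adjusted_difference(table, "y", "week12")
        assert np.isfinite(eff.adjusted_md)

    def test_single_arm_rejected(self):
        table = make_table(seed=4)
        table["arm"] = "intervention"
        with pytest.raises(ValueError, match="arm"):
            ancova_adjusted_difference(table, "y", "week12")

    def test_unbiased_under_null(self):
        """Mean estimate over replicate null tables is within MC error of 0."""
        ests = np.array(
            [
                ancova_adjusted_difference(
                    make_table(delta=0.0, seed=s), "y", "week12"
                ).adjusted_md
                for s in range(2000)
            ]
        )
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean()) < 3 * se


class TestBcaBootstrap:
    def test_symmetric_statistic_close_to_percentile(self, rng):
        x = rng.standard_normal(200)
        lo, hi = bca_bootstrap_ci(np.mean, x, reps=4000, seed=1)
        plo, phi = np.percentile(
            [np.mean(rng.choice(x, len(x))) for _ in range(4000)], [2.5, 97.5]
        )
        spread = phi - plo
        assert abs(lo - plo) < 0.15 * spread
        assert abs(hi - phi) < 0.15 * spread

    def test_exhaustive_resample_oracle_n5(self):
        """Interval construction matches a hand-rolled BCa on the fully
        enumerated bootstrap distribution of a 5-point sample."""
        from itertools import product

        x = np.array([1.0, 2.0, 3.0, 7.0, 20.0])
        n = len(x)
        boot = np.array([np.mean(x[list(idx)]) for idx in product(range(n), repeat=n)])
        observed = x.mean()
        jack = np.array([np.delete(x, i).mean() for i in range(n)])

        # Independent oracle from the textbook formulas.
        z0 = sps.norm.ppf(np.mean(boot < observed) + 0.5 * np.mean(boot == observed))
        d = jack.mean() - jack
        a = (d**3).sum() / (6.0 * ((d**2).sum()) ** 1.5)
        bounds = []
        for alpha in (0.025, 0.975):
            za = sps.norm.ppf(alpha)
            adj = sps.norm.cdf(z0 + (z0 + za) / (1 - a * (z0 + za)))
            bounds.append(np.quantile(boot, adj))

        lo, hi = _bca_interval(observed, boot, jack, 0.95)
        assert lo == pytest.approx(bounds[0], rel=1e-12)
        assert hi == pytest.approx(bounds[1], rel=1e-12)

    def test_matches_scipy_bca(self, rng):
        """Cross-check against scipy.stats.bootstrap's independent BCa."""
        x = rng.gamma(2.0, 2.0, 80)
        lo, hi = bca_bootstrap_ci(np.mean, x, reps=9999, seed=5)
        res = sps.bootstrap(
            (x,),
            np.mean,
            method="BCa",
            n_resamples=9999,
            confidence_level=0.95,
            random_state=np.random.default_rng(6),
        )
        spread = res.confidence_interval.high - res.confidence_interval.low
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.1 * spread)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.1 * spread)

    def test_deterministic_under_seed(self, rng):
        x = rng.standard_normal(50)
        assert bca_bootstrap_ci(np.mean, x, reps=500, seed=9) == bca_bootstrap_ci(
            np.mean, x, reps=500, seed=9
        )

    def test_degenerate_distribution_point_mass(self):
        x = np.full(20, 3.0)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            lo, hi = bca_bootstrap_ci(np.mean, x, reps=200, seed=0)
        assert lo == hi == 3.0

    def test_stratified_resampling_preserves_arm_sizes(self):
        strata = np.array([0] * 30 + [1] * 10)
        seen = []

        def stat(idx):
            seen.append(((strata[idx] == 0).sum(), (strata[idx] == 1).sum()))
            return float(idx.mean())

        bca_bootstrap_ci(stat, 40, strata=strata, reps=100, seed=0)
        # Every bootstrap resample keeps 30 + 10 (jackknife rows drop one).
        assert all(a + b in (39, 40) and a in (29, 30) for a, b in seen)

    def test_too_few_reps_rejected(self, rng):
        with pytest.raises(ValueError, match="100"):
            bca_bootstrap_ci(np.mean, rng.standard_normal(10), reps=50)


class TestHedgesG:
    def test_correction_closed_form(self):
        assert hedges_correction(36, 15) == pytest.approx(1 - 3 / 195)
        assert hedges_correction(36, 15) == pytest.approx(0.9846, abs=1e-4)

    def test_zero_difference_gives_zero(self):
        table = make_table(seed=7)
        assert hedges_g(table, 0.0, "y", "week12") == 0.0

    def test_magnitude_example(self):
        """md 0.09 over pooled SD 0.11 with n 36/15 is a large effect."""
        g = hedges_correction(36, 15) * 0.09 / 0.11
        assert g == pytest.approx(0.81, abs=0.01)

    def test_hand_computed_small_table(self):
        table = pd.DataFrame(
            {
                "arm": ["intervention"] * 2 + ["control"] * 2,
                "y_week12": [3.0, 5.0, 1.0, 2.0],
            }
        )
        # pooled sd = sqrt(((1)*2 + (1)*0.5) / 2) = sqrt(1.25)
        g = hedges_g(table, 1.0, "y", "week12")
        expected = hedges_correction(2, 2) * 1.0 / np.sqrt(1.25)
        assert g == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("c", [0.1, 3.0, 250.0])
    def test_scale_invariance(self, c):
        table = make_table(delta=1.0, seed=8)
        eff = ancova_adjusted_difference(table, "y", "week12")
        g1 = hedges_g(table, eff.adjusted_md, "y", "week12")
        scaled = table.copy()
        scaled[["y_baseline", "y_week12"]] *= c
        eff2 = ancova_adjusted_difference(scaled, "y", "week12")
        g2 = hedges_g(scaled, eff2.adjusted_md, "y", "week12")
        assert g2 == pytest.approx(g1, rel=1e-9)

    def test_zero_pooled_sd_rejected(self):
        table = pd.DataFrame(
            {"arm": ["intervention"] * 2 + ["control"] * 2, "y_week12": [1.0] * 4}
        )
        with pytest.raises(ValueError, match="pooled"):
            hedges_g(table, 1.0, "y", "week12")


class TestAdjustedEffect:
    def test_full_effect_contract(self):
        table = make_table(delta=1.0, seed=10)
        eff = adjusted_effect(table, "y", "week12", reps=400, seed=3)
        assert eff.ci_low <= eff.adjusted_md <= eff.ci_high
        assert np.sign(eff.hedges_g) == np.sign(eff.adjusted_md)
        assert eff.g_ci_low <= eff.hedges_g <= eff.g_ci_high
        assert eff.reps == 400 and (eff.n1, eff.n2) == (36, 15)
        assert np.isfinite(eff.robust_se) and eff.robust_se > 0

    def test_reproducible(self):
        table = make_table(delta=0.5, seed=11)
        e1 = adjusted_effect(table, "y", "week12", reps=300, seed=4)
        e2 = adjusted_effect(table, "y", "week12", reps=300, seed=4)
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)


class TestSubgroupsAndEligibility:
    def test_hand_built_cells(self):
        table = pd.DataFrame(
            {
                "arm": ["intervention", "intervention", "control", "control"],
                "sex": ["female", "male", "female", "male"],
                "weight_status": [0, 0, 0, 0],
                "pal_baseline": [1.5, 1.6, 1.4, 1.7],
                "pal_week12": [1.8, 1.6, 1.5, 1.6],
            }
        )
        desc = subgroup_descriptives(table, "pal", "sex", timepoints=("week12",))
        cell = desc[(desc["subgroup"] == "female") & (desc["arm"] == "intervention")]
        assert cell["mean"].iloc[0] == pytest.approx(1.8)
        assert cell["n"].iloc[0] == 1

    def test_uniform_data_subgroups_equal_overall(self):
        table = make_table(seed=12)
        table["y_week12"] = 5.0
        table["pal_baseline"] = table["y_baseline"]
        desc = subgroup_descriptives(table, "y", "baseline_activity", ("week12",))
        assert np.allclose(desc.loc[desc["n"] > 0, "mean"], 5.0)

    def test_median_split_ties_go_low(self):
        table = make_table(seed=13)
        table["pal_baseline"] = np.where(np.arange(len(table)) < 26, 1.5, 1.9)
        desc = subgroup_descriptives(table, "y", "baseline_activity", ("week12",))
        n_low = desc[(desc["subgroup"] == "low")]["n"].sum()
        assert n_low == 26  # the 1.5 block sits at/below the median

    def test_sex_specific_effect_ordering(self):
        table = make_table(seed=14)
        table["y_week12"] = table["y_baseline"] + 2.0 * (
            (table["arm"] == "intervention") & (table["sex"] == "female")
        )
        desc = subgroup_descriptives(table, "y", "sex", ("week12",))
        piv = desc.pivot(index="subgroup", columns="arm", values="mean")
        female_diff = piv.loc["female", "intervention"] - piv.loc["female", "control"]
        male_diff = piv.loc["male", "intervention"] - piv.loc["male", "control"]
        assert female_diff > male_diff

    def test_eligibility_boundary(self):
        res = eligibility_screen({"a": 1.99, "b": 2.0, "c": 2.4})
        assert res.included == ["a"]
        assert [pid for pid, _ in res.excluded] == ["b", "c"]
        assert "2.00 >= 2.0" in res.excluded[0][1]

    def test_eligibility_empty_cohort(self):
        res = eligibility_screen({})
        assert res.included == [] and res.excluded == []

    def test_eligibility_counts_mixed_cohort(self, rng):
        pals = pd.Series(
            np.concatenate([rng.uniform(1.3, 1.95, 52), rng.uniform(2.0, 2.3, 5)]),
            index=[f"P{i}" for i in range(57)],
        )
        res = eligibility_screen(pals)
        assert len(res.included) == 52 and len(res.excluded) == 5
        assert PAL_ELIGIBILITY_CUTOFF == 2.0
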