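"""Synthetic cohort generator: calibration, determinism, recovery of
configured dimension values."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mdpa.dimensions import DIMENSION_NAMES, multidimensional_profile
from mdpa.pipeline import process_raw_week
from mdpa.synthetic import (
    ArmWeekParams,
    Channel,
    ConfigError,
    SimulationConfig,
    calibrate_from_summary,
    default_config,
    draw_week_dimensions,
    reference_group_summary,
    simulate_participant_week,
    simulate_trial,
)
from mdpa.synthetic import _rectified_location

from conftest import zero_sd_params


def sd_oracle(ci_low, ci_high, n):
    """Independent hand computation of the CI-to-SD normal approximation."""
    z = sps.norm.ppf(0.975)
    return (ci_high - ci_low) / (2 * z) * math.sqrt(n)


class TestCalibration:
    def test_ci_to_sd_example_cells(self):
        summary = reference_group_summary()
        cfg = calibrate_from_summary(summary)
        # Intervention baseline PAL cell 1.61 (1.55-1.66), n=36.
        ch = cfg.params[("intervention", "baseline")].pal
        assert ch.mean == pytest.approx(1.61)
        assert ch.sd == pytest.approx(sd_oracle(1.55, 1.66, 36), rel=1e-9)
        assert ch.sd == pytest.approx(0.168, abs=2e-3)
        # Control week-12 PAL cell 1.58 (1.52-1.64), n=15.
        ch = cfg.params[("control", "week12")].pal
        assert ch.sd == pytest.approx(sd_oracle(1.52, 1.64, 15), rel=1e-9)
        assert ch.sd == pytest.approx(0.119, abs=2e-3)

    def test_degenerate_ci_gives_zero_sd(self):
        summary = pd.DataFrame(
            [("pal", arm, "baseline", 1.6, 1.6, 1.6) for arm in ("intervention", "control")]
            + [
                (dim, arm, "baseline", m, m, m)
                for arm in ("intervention", "control")
                for dim, m in [
                    ("sedentary_pct", 60.0),
                    ("moderate_min_day", 100.0),
                    ("vigorous_bout_min_week", 20.0),
                    ("mvpa_bout_min_week", 200.0),
                    ("steps_day", 7000.0),
                ]
            ],
            columns=["dimension", "arm", "week", "mean", "ci_low", "ci_high"],
        )
        cfg = calibrate_from_summary(summary)
        assert cfg.params[("intervention", "baseline")].pal.sd == 0.0

    def test_inverted_ci_rejected(self):
        summary = reference_group_summary()
        summary.loc[0, ["ci_low", "ci_high"]] = [1.66, 1.55]
        with pytest.raises(ConfigError, match="upper bound"):
            calibrate_from_summary(summary)

    def test_infeasible_means_rejected(self):
        p = zero_sd_params(sed=90.0, mod=200.0)  # 864 + 200 > 960
        with pytest.raises(ConfigError, match="waking window"):
            p.validate(960)

    def test_default_config_programs_published_differences(self):
        from mdpa.synthetic import REFERENCE_ADJUSTED_DIFFERENCES_WK12

        cfg = default_config()
        for dim, diff in REFERENCE_ADJUSTED_DIFFERENCES_WK12.items():
            for week in ("baseline", "week6"):
                a = getattr(cfg.params[("intervention", week)], dim).mean
                b = getattr(cfg.params[("control", week)], dim).mean
                assert a == pytest.approx(b)
            d = (
                getattr(cfg.params[("intervention", "week12")], dim).mean
                - getattr(cfg.params[("control", "week12")], dim).mean
            )
            assert d == pytest.approx(diff)


class TestTrialStructure:
    def test_allocation_counts(self):
        trial = simulate_trial(default_config(seed=3))
        parts = trial.participants
        assert len(parts) == 51
        assert (parts["arm"] == "intervention").sum() == 36
        assert (parts["arm"] == "control").sum() == 15
        assert len(trial.weeks) == 51 * 3

    def test_weight_status_cutoff(self):
        parts = simulate_trial(default_config(seed=3)).participants
        assert (parts["weight_status"] == (parts["bmi"] >= 30).astype(int)).all()

    def test_seeded_determinism_byte_identical(self):
        t1 = simulate_trial(default_config(seed=11))
        t2 = simulate_trial(default_config(seed=11))
        assert t1.participants.equals(t2.participants)
        for key in t1.weeks:
            a, b = t1.weeks[key], t2.weeks[key]
            assert a.to_frame().equals(b.to_frame())

    def test_different_seed_differs(self):
        t1 = simulate_trial(default_config(seed=11))
        t2 = simulate_trial(default_config(seed=12))
        key = next(iter(t1.weeks))
        assert not np.array_equal(t1.weeks[key].mets, t2.weeks[key].mets)

    def test_json_round_trip(self):
        cfg = default_config(seed=7)
        back = SimulationConfig.from_json(cfg.to_json())
        assert back.params == cfg.params
        assert back.window == cfg.window
        assert back.assessment_weeks == cfg.assessment_weeks


class TestDimensionRecovery:
    def test_zero_sd_week_recovers_exact_dimensions(self, noise_free_config):
        """With all noise off, pipeline dimensions equal configured means."""
        p = zero_sd_params(pal=1.5, sed=60.0, mod=120.0, vig=0.0, mvpa=300.0, steps=7000.0)
        raw = simulate_participant_week(
            p, {"rmr_kcal_day": 1600.0}, 5, config=noise_free_config
        )
        prof = multidimensional_profile(process_raw_week(raw, 1600.0, "x", "w"))
        assert prof.moderate_min_day == pytest.approx(120.0)
        assert prof.sedentary_pct == pytest.approx(60.0)
        assert prof.mvpa_bout_min_week == pytest.approx(300.0)
        assert prof.steps_day == pytest.approx(7000.0)
        assert prof.pal == pytest.approx(1.5, abs=0.01)

    def test_all_resting_week(self, noise_free_config):
        """All waking minutes near 1 MET: PAL ~ 1 and fully sedentary."""
        p = zero_sd_params(pal=1.0, sed=100.0, mod=0.0, vig=0.0, mvpa=0.0, steps=0.0)
        raw = simulate_participant_week(
            p, {"rmr_kcal_day": 1440.0}, 5, config=noise_free_config
        )
        prof = multidimensional_profile(process_raw_week(raw, 1440.0, "x", "w"))
        assert prof.pal == pytest.approx(1.0, abs=0.01)
        assert prof.sedentary_pct == pytest.approx(100.0)
        assert prof.steps_day == 0.0

    def test_calibrated_cell_monte_carlo_means(self):
        """Replicate weeks from one calibrated cell recover its means.

        Gaps are disabled so the generator itself (not downstream
        non-wear imputation) is what is being measured.
        """
        cfg = default_config()
        cfg = SimulationConfig(**{**cfg.__dict__, "gaps_per_day": 0.0})
        params = cfg.params[("intervention", "week12")]
        rng = np.random.default_rng(99)
        from mdpa.synthetic import _CHANNELS, _draw_channels

        n = 600
        vals = {d: [] for d in DIMENSION_NAMES}
        for _ in range(n):
            draws = _draw_channels(params, rng.standard_normal(len(_CHANNELS)), 0.0, rng)
            raw = simulate_participant_week(
                params, {"rmr_kcal_day": 1600.0}, rng, config=cfg, channel_draws=draws
            )
            prof = multidimensional_profile(process_raw_week(raw, 1600.0, "x", "w"))
            for d in DIMENSION_NAMES:
                vals[d].append(getattr(prof, d))
        for d in DIMENSION_NAMES:
            arr = np.asarray(vals[d])
            target = getattr(params, d).mean
            se = arr.std(ddof=1) / math.sqrt(n)
            assert abs(arr.mean() - target) < 3 * se + 0.01 * abs(target), (
                f"{d}: mean {arr.mean():.3f} vs configured {target:.3f} (se {se:.3f})"
            )

    def test_distribution_layer_matches_config(self):
        """Channel-draw layer: cell means/SDs and nesting invariants."""
        cfg = default_config(seed=13)
        big = SimulationConfig(
            **{**cfg.__dict__, "n_intervention": 600, "n_control": 600, "person_corr": 0.0}
        )
        df = draw_week_dimensions(big)
        assert (df["mvpa_bout_min_week"] >= df["vigorous_bout_min_week"] - 1e-9).all()
        assert (7 * df["moderate_min_day"] >= df["mvpa_bout_min_week"] - 1e-9).all()
        cell = df[(df["arm"] == "intervention") & (df["week"] == "week12")]
        for dim in DIMENSION_NAMES:
            ch = getattr(cfg.params[("intervention", "week12")], dim)
            se = ch.sd / math.sqrt(len(cell)) if ch.sd else 1e-9
            assert abs(cell[dim].mean() - ch.mean) < 4 * se + 0.01 * abs(ch.mean)

    def test_rectified_location_correction(self):
        """E[max(loc + sd*Z, 0)] equals the requested mean (numeric check)."""
        for mean, sd in [(42.0, 64.3), (33.0, 40.5), (5.0, 20.0), (100.0, 10.0)]:
            loc = _rectified_location(mean, sd)
            z = loc / sd
            rectified = loc * sps.norm.cdf(z) + sd * sps.norm.pdf(z)
            assert rectified == pytest.approx(mean, rel=1e-6)
        assert _rectified_location(10.0, 0.0) == 10.0

    def test_wear_gaps_land_in_waking_window(self):
        cfg = default_config(seed=2)
        cfg.gaps_per_day = 3.0
        trial = simulate_trial(
            SimulationConfig(**{**cfg.__dict__, "n_intervention": 3, "n_control": 2})
        )
        w = cfg.window
        for raw in trial.weeks.values():
            nonwear = ~raw.wear
            assert not nonwear[:, : w.start_minute].any()
            assert not nonwear[:, w.end_minute :].any()
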