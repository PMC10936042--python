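"""Synthetic-cohort generator: trace structure, determinism, planted
daily-duration targets, covariates and markers."""

import numpy as np
import pandas as pd
import pytest

from actiprofile import preprocess as pp
from actiprofile.cohort import (
    ArchetypeSpec,
    CohortConfig,
    ConfigurationError,
    default_archetypes,
    default_marker_effects,
    generate_cohort,
    generate_covariates,
    generate_markers,
    generate_trace,
    traces_from_frame,
    traces_to_frame,
    _flat_day,
)
from actiprofile.preprocess import MINUTES_PER_DAY, mean_daily_durations, process_trace


class TestArchetypeSpec:
    def test_weights_must_sum_to_one(self):
        bad = np.full((7, 48, 3), 0.5)
        with pytest.raises(ConfigurationError):
            ArchetypeSpec("bad", bad)

    def test_negative_weights_rejected(self):
        w = np.tile(np.array([1.5, -0.25, -0.25]), (7, 48, 1))
        with pytest.raises(ConfigurationError):
            ArchetypeSpec("bad", w)

    def test_wear_window_order_enforced(self):
        w = np.tile(_flat_day(0.8, 0.15, 0.05), (7, 1, 1))
        with pytest.raises(ConfigurationError):
            ArchetypeSpec("bad", w, wear_start_mean=1200, wear_end_mean=600)

    def test_target_daily_minutes_closed_form(self):
        w = np.tile(_flat_day(0.5, 0.3, 0.2), (7, 1, 1))
        spec = ArchetypeSpec("t", w, wear_start_mean=480, wear_end_mean=1080,
                             gaps_per_day=0.0)
        t = spec.target_daily_minutes
        # 600-min window, weights 0.5/0.3/0.2
        assert t["sedentary"] == pytest.approx(300.0)
        assert t["light"] == pytest.approx(180.0)
        assert t["mvpa"] == pytest.approx(120.0)


class TestGenerateTrace:
    def test_full_week_grid(self):
        t = generate_trace(default_archetypes()[0], seed=1)
        assert len(t.cpm) == 7 * MINUTES_PER_DAY
        assert t.cpm.min() >= 0

    def test_deterministic_given_seed(self):
        a = default_archetypes()[1]
        t1 = generate_trace(a, seed=42)
        t2 = generate_trace(a, seed=42)
        np.testing.assert_array_equal(t1.cpm, t2.cpm)

    def test_different_seed_differs(self):
        a = default_archetypes()[1]
        assert not np.array_equal(generate_trace(a, 1).cpm, generate_trace(a, 2).cpm)

    def test_mean_durations_near_target(self):
        # average processed durations over participants should approach the
        # archetype's closed-form expectation
        for spec in default_archetypes():
            target = spec.target_daily_minutes
            got = {"sedentary": [], "light": [], "mvpa": []}
            for s in range(12):
                series, daily, _ = process_trace(generate_trace(spec, seed=s))
                sed, light, mvpa = mean_daily_durations(series, daily)
                got["sedentary"].append(sed)
                got["light"].append(light)
                got["mvpa"].append(mvpa)
            for cat in got:
                mean = np.mean(got[cat])
                tol = max(25.0, 0.15 * target[cat])
                assert abs(mean - target[cat]) < tol, (spec.name, cat, mean, target[cat])

    def test_planted_gap_detected_as_nonwear(self):
        w = np.tile(_flat_day(0.6, 0.3, 0.1), (7, 1, 1))
        spec = ArchetypeSpec("gappy", w, gaps_per_day=3.0, wear_start_mean=300,
                             wear_end_mean=1350)
        trace = generate_trace(spec, seed=5)
        wear = pp.detect_nonwear(trace)
        # with 3 expected 60+ minute gaps per day, some non-wear must be
        # detected inside the wear window
        grid = wear.reshape(7, MINUTES_PER_DAY)
        assert (~grid[:, 400:1200]).sum() > 0


class TestGenerateCohort:
    def test_sizes_and_labels(self):
        cfg = CohortConfig(n_participants=12, seed=3)
        traces, labels = generate_cohort(cfg)
        assert len(traces) == 12 and len(labels) == 12
        assert set(labels) <= {0, 1, 2, 3}
        assert len({t.participant_id for t in traces}) == 12

    def test_reproducible(self):
        cfg = CohortConfig(n_participants=6, seed=9)
        t1, l1 = generate_cohort(cfg)
        t2, l2 = generate_cohort(cfg)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(t1[3].cpm, t2[3].cpm)

    def test_degenerate_weights(self):
        cfg = CohortConfig(n_participants=8, seed=1,
                           archetype_weights=[0, 0, 1, 0])
        _, labels = generate_cohort(cfg)
        assert (labels == 2).all()

    def test_bad_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_participants=5, archetype_weights=[0.5, 0.5, 0.5, 0.5])


@pytest.fixture(scope="module")
def cohort():
    cfg = CohortConfig(n_participants=400, seed=11,
                       marker_effects=default_marker_effects())
    rng = np.random.default_rng(11)
    labels = rng.choice(4, size=400)
    cov = generate_covariates(labels, cfg, seed=12)
    markers = generate_markers(labels, cov, cfg.marker_effects, seed=13)
    return labels, cov, markers


class TestCovariatesAndMarkers:

    def test_covariate_schema(self, cohort):
        _, cov, _ = cohort
        expected = {"participant_id", "age", "sex", "ethnicity", "marital_status",
                    "income_poverty_ratio", "smoking", "alcohol_g_day",
                    "energy_kcal", "sat_fat_g", "caffeine_mg", "cvd",
                    "diabetes", "cancer"}
        assert expected <= set(cov.columns)
        assert cov["age"].between(20, 65).all()

    def test_marker_positivity(self, cohort):
        _, _, markers = cohort
        for col in ("insulin", "triglycerides", "glucose", "crp",
                    "tot_hdl_ratio", "waist_cm", "bmi", "homa_ir"):
            assert (markers[col] > 0).all(), col

    def test_homa_ir_consistent(self, cohort):
        _, _, markers = cohort
        expected = markers["glucose"] * markers["insulin"] / 22.5
        np.testing.assert_allclose(markers["homa_ir"], expected)

    def test_planted_insulin_effect_direction(self, cohort):
        labels, _, markers = cohort
        log_ins = np.log(markers["insulin"].to_numpy())
        # archetype 0 = Lowest activity (no planted shift); 3 = Highest
        # activity (-0.20 on log insulin)
        diff = log_ins[labels == 3].mean() - log_ins[labels == 0].mean()
        assert diff < -0.05

    def test_misaligned_inputs_rejected(self, cohort):
        labels, cov, _ = cohort
        with pytest.raises(ConfigurationError):
            generate_markers(labels[:-1], cov, None, seed=1)


class TestTraceFrames:
    def test_round_trip(self):
        cfg = CohortConfig(n_participants=3, seed=2)
        traces, _ = generate_cohort(cfg)
        df = traces_to_frame(traces)
        assert isinstance(df, pd.DataFrame)
        back = traces_from_frame(df)
        assert len(back) == 3
        for a, b in zip(traces, back):
            assert a.participant_id == b.participant_id
            np.testing.assert_array_equal(a.cpm, b.cpm)
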