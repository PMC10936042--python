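"""Non-wear detection, wear-bout filtering, intensity classification,
screening, and sedentary-bout metrics."""

import numpy as np
import pytest

from actiprofile import preprocess as pp
from actiprofile.preprocess import (
    ActivityTrace,
    DataError,
    ScreeningError,
    Thresholds,
    classify_intensity,
    detect_nonwear,
    filter_short_wear,
    mean_daily_durations,
    screen_valid,
    sedentary_bout_metrics,
)

from conftest import make_day_trace, make_week_trace


def brute_force_nonwear(cpm: np.ndarray, min_len=60, allow_n=2, allow_max=49) -> np.ndarray:
    """Independent oracle: a minute is non-wear iff it lies in some window
    of length >= min_len where every count is < 50 and at most allow_n
    counts are non-zero. O(n^2) enumeration of all windows."""
    n = len(cpm)
    wear = np.ones(n, dtype=bool)
    for a in range(n):
        nonzero = 0
        for b in range(a, n):
            if cpm[b] > allow_max:
                break
            if cpm[b] > 0:
                nonzero += 1
            if nonzero > allow_n:
                break
            if b - a + 1 >= min_len:
                wear[a : b + 1] = False
    return wear


class TestDetectNonwear:
    def test_sixty_zero_minutes_flagged(self):
        cpm = np.concatenate([[500], np.zeros(60, int), [500]])
        wear = detect_nonwear(make_day_trace(cpm))
        assert wear[0] and wear[-1]
        assert not wear[1:61].any()

    def test_59_zero_minutes_all_wear(self):
        cpm = np.concatenate([[500], np.zeros(59, int), [500]])
        assert detect_nonwear(make_day_trace(cpm)).all()

    def test_allowance_minute_inside_run(self):
        # 30 zeros + one 40-cpm minute + 30 zeros: one allowance used,
        # 61-minute non-wear period
        cpm = np.concatenate([np.zeros(30, int), [40], np.zeros(30, int)])
        assert not detect_nonwear(make_day_trace(cpm)).any()

    def test_50cpm_terminates_run(self):
        # a >=50-cpm minute splits the zeros into two 30-min runs: all wear
        cpm = np.concatenate([np.zeros(30, int), [60], np.zeros(30, int)])
        assert detect_nonwear(make_day_trace(cpm)).all()

    def test_three_allowance_minutes_break_window(self):
        # three interspersed low-count minutes exceed the allowance
        block = np.zeros(90, int)
        block[[20, 45, 70]] = 30
        wear = detect_nonwear(make_day_trace(block))
        oracle = brute_force_nonwear(block)
        np.testing.assert_array_equal(wear, oracle)

    def test_negative_cpm_rejected(self):
        with pytest.raises(DataError):
            make_day_trace([-1, 0, 0])

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        # zero-inflated counts with low-count and active minutes mixed
        cpm = rng.choice(
            [0, 0, 0, 0, 10, 40, 49, 50, 60, 200, 2500],
            p=[0.55, 0.1, 0.05, 0.05, 0.04, 0.04, 0.02, 0.02, 0.03, 0.05, 0.05],
            size=300,
        )
        wear = detect_nonwear(make_day_trace(cpm))
        np.testing.assert_array_equal(wear, brute_force_nonwear(cpm))


class TestFilterShortWear:
    def _mask(self, wear_run: int):
        # non-wear padding (500 min zeros), a wear run, non-wear padding
        cpm = np.concatenate([
            np.zeros(500, int), np.full(wear_run, 300), np.zeros(500, int)
        ])
        trace = make_day_trace(cpm)
        return trace, detect_nonwear(trace)

    def test_90_minute_run_reclassified(self):
        trace, wear = self._mask(90)
        assert wear.sum() == 90
        assert filter_short_wear(trace, wear).sum() == 0

    def test_120_minute_run_reclassified(self):
        trace, wear = self._mask(120)
        assert filter_short_wear(trace, wear).sum() == 0

    def test_121_minute_run_retained(self):
        trace, wear = self._mask(121)
        assert filter_short_wear(trace, wear).sum() == 121

    def test_all_wear_unchanged(self):
        cpm = np.full(1440, 300)
        trace = make_day_trace(cpm)
        wear = detect_nonwear(trace)
        np.testing.assert_array_equal(filter_short_wear(trace, wear), wear)

    def test_monotone_in_threshold(self, rng):
        cpm = rng.choice([0, 300], p=[0.6, 0.4], size=1440)
        trace = make_day_trace(cpm)
        wear = detect_nonwear(trace)
        totals = [
            filter_short_wear(trace, wear, Thresholds(min_wear_bout_minutes=t)).sum()
            for t in (0, 30, 60, 120, 240)
        ]
        assert totals == sorted(totals, reverse=True)


class TestClassifyIntensity:
    @pytest.mark.parametrize(
        "cpm,expected",
        [(0, pp.SEDENTARY), (99, pp.SEDENTARY), (100, pp.LIGHT),
         (1951, pp.LIGHT), (1952, pp.MVPA), (5000, pp.MVPA)],
    )
    def test_cutpoint_boundaries(self, cpm, expected):
        trace = make_day_trace([cpm] * 3)
        series = classify_intensity(trace, np.ones(3, bool))
        assert series.category[0] == expected

    def test_mask_precedence(self):
        trace = make_day_trace([0, 0, 0])
        series = classify_intensity(trace, np.zeros(3, bool))
        assert (series.category == pp.NONWEAR).all()


class TestScreening:
    def _series_with_wear(self, minutes_per_day):
        grid = np.zeros((7, 1440), int)
        for d, m in enumerate(minutes_per_day):
            grid[d, 400 : 400 + m] = 300
        trace = make_week_trace(grid)
        wear = filter_short_wear(trace, detect_nonwear(trace))
        return classify_intensity(trace, wear)

    def test_600_minutes_is_valid(self):
        daily, _ = screen_valid(self._series_with_wear([600] * 7))
        assert all(d.valid for d in daily)

    def test_599_minutes_is_invalid(self):
        daily, _ = screen_valid(self._series_with_wear([599] * 7))
        assert not any(d.valid for d in daily)

    @pytest.mark.parametrize("n_valid,expected", [(3, False), (4, True)])
    def test_eligibility_threshold(self, n_valid, expected):
        minutes = [700] * n_valid + [300] * (7 - n_valid)
        _, eligible = screen_valid(self._series_with_wear(minutes))
        assert eligible is expected

    def test_durations_sum_to_wear(self):
        rng = np.random.default_rng(7)
        grid = rng.choice([0, 50, 500, 2500], p=[0.3, 0.3, 0.3, 0.1], size=(7, 1440))
        trace = make_week_trace(grid)
        wear = filter_short_wear(trace, detect_nonwear(trace))
        series = classify_intensity(trace, wear)
        daily, _ = screen_valid(series)
        for d in daily:
            assert d.sedentary_minutes + d.light_minutes + d.mvpa_minutes == d.wear_minutes


class TestMeanDailyDurations:
    def test_simple_average(self):
        # 4 valid days, 25 MVPA min each
        grid = np.zeros((7, 1440), int)
        for d in range(4):
            grid[d, 400:1000] = 50  # 600 sedentary
            grid[d, 1000:1025] = 2500  # 25 mvpa
        trace = make_week_trace(grid)
        wear = filter_short_wear(trace, detect_nonwear(trace))
        series = classify_intensity(trace, wear)
        daily, eligible = screen_valid(series)
        assert eligible
        sed, light, mvpa = mean_daily_durations(series, daily)
        assert mvpa == 25.0
        assert light == 0.0
        assert sed == 600.0

    def test_no_valid_days_raises(self):
        grid = np.zeros((7, 1440), int)
        trace = make_week_trace(grid)
        series = classify_intensity(trace, np.zeros(len(trace), bool))
        daily, _ = screen_valid(series)
        with pytest.raises(ScreeningError):
            mean_daily_durations(series, daily)


def _series_from_labels(label_grid):
    """(7, 1440) arrays of category codes -> IntensitySeries directly."""
    import numpy as np
    from actiprofile.preprocess import IntensitySeries

    label_grid = np.asarray(label_grid, dtype=np.int8)
    return IntensitySeries(
        participant_id="L",
        weekday=np.repeat(np.arange(1, 8), 1440),
        minute_of_day=np.tile(np.arange(1440), 7),
        category=label_grid.reshape(-1),
    )


def _daily_all_valid(series):
    daily, _ = screen_valid(series)
    return daily


class TestSedentaryBoutMetrics:
    def _metrics_from_day(self, day_labels):
        grid = np.zeros((7, 1440), np.int8)
        # make day 1 valid: labels as given, padded with light activity
        pattern = np.asarray(day_labels, dtype=np.int8)
        grid[0, : len(pattern)] = pattern
        grid[0, len(pattern) : 700] = pp.LIGHT
        series = _series_from_labels(grid)
        daily = _daily_all_valid(series)
        return sedentary_bout_metrics(series, daily)

    def test_worked_fragment_interruptions(self):
        # S,S,A,S,A: one qualifying 2-min bout ending in activity,
        # 3 sedentary minutes total on the day -> but day padding adds no
        # sedentary time, so 1 interruption / (3/60 h) = 20
        m = self._metrics_from_day([pp.SEDENTARY, pp.SEDENTARY, pp.LIGHT,
                                    pp.SEDENTARY, pp.LIGHT])
        assert m.total_sedentary_minutes == 3
        assert m.interruptions_per_sed_hour == pytest.approx(20.0)

    def test_worked_fragment_percent_15_30(self):
        # one 20-min bout + 10 isolated sedentary minutes = 30 sed min;
        # 20/30 of sedentary time in the [15,30) category
        labels = [pp.SEDENTARY] * 20
        for _ in range(10):
            labels += [pp.LIGHT, pp.SEDENTARY]
        m = self._metrics_from_day(labels)
        assert m.total_sedentary_minutes == 30
        assert m.pct_sed_15_30 == pytest.approx(100 * 20 / 30)
        assert m.pct_sed_ge30 == 0.0

    def test_30_minute_bout_in_ge30_category(self):
        labels = [pp.SEDENTARY] * 30 + [pp.LIGHT]
        m = self._metrics_from_day(labels)
        assert m.pct_sed_ge30 == pytest.approx(100.0)
        assert m.pct_sed_15_30 == 0.0

    def test_bout_ending_at_nonwear_not_interruption(self):
        labels = [pp.SEDENTARY] * 10 + [pp.NONWEAR] * 5
        m = self._metrics_from_day(labels)
        assert m.interruptions_per_sed_hour == 0.0

    def test_no_sedentary_time_reports_missing(self):
        grid = np.full((7, 1440), pp.LIGHT, np.int8)
        series = _series_from_labels(grid)
        m = sedentary_bout_metrics(series, _daily_all_valid(series))
        assert m.interruptions_per_sed_hour is None
        assert m.pct_sed_15_30 == 0.0

    def test_bout_category_partition(self, rng):
        # percentages over all bout-length categories cover all sedentary time
        grid = rng.choice(
            [pp.SEDENTARY, pp.LIGHT, pp.MVPA], p=[0.7, 0.2, 0.1], size=(7, 1440)
        ).astype(np.int8)
        series = _series_from_labels(grid)
        daily = _daily_all_valid(series)
        m = sedentary_bout_metrics(series, daily)
        # recompute short-bout and isolated-minute shares by enumeration
        total = short = 0
        for wd in range(1, 8):
            cats = grid[wd - 1]
            i = 0
            while i < 1440:
                if cats[i] == pp.SEDENTARY:
                    j = i
                    while j + 1 < 1440 and cats[j + 1] == pp.SEDENTARY:
                        j += 1
                    length = j - i + 1
                    total += length
                    if length < 15:
                        short += length
                    i = j + 1
                else:
                    i += 1
        pct_short = 100 * short / total
        assert m.pct_sed_15_30 + m.pct_sed_ge30 + pct_short == pytest.approx(100.0)


class TestTraceValidation:
    def test_duplicate_minutes_rejected(self):
        with pytest.raises(DataError):
            ActivityTrace("X", [1, 1], [5, 5], [0, 0])

    def test_missing_cpm_rejected(self):
        with pytest.raises(DataError):
            ActivityTrace("X", [1], [5], [np.nan])
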