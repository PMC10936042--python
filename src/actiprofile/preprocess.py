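"""Accelerometer cleaning and movement-behavior metrics.

Implements the minute-epoch processing chain used for hip-worn uniaxial
activity counts: non-wear detection (60-min zero runs with a 2-minute
low-count allowance), exclusion of short wear bouts, valid-day and
participant screening, intensity classification by cut-points, mean daily
durations, and sedentary-bout / interruption metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Intensity codes used throughout the package.
NONWEAR, SEDENTARY, LIGHT, MVPA = 0, 1, 2, 3
CATEGORY_NAMES = {NONWEAR: "nonwear", SEDENTARY: "sedentary", LIGHT: "light", MVPA: "mvpa"}

MINUTES_PER_DAY = 1440
WEEK_MINUTES = 7 * MINUTES_PER_DAY  # 10,080


@dataclass(frozen=True)
class Thresholds:
    """Processing thresholds (counts-per-minute and duration rules).

    Defaults follow the standard NHANES 2003–2006 uniaxial protocol:
    sedentary < 100 cpm, light 100–1951 cpm, MVPA >= 1952 cpm; non-wear is
    a run of >= 60 min of zeros allowing up to 2 minutes below 50 cpm;
    wear bouts must exceed 120 min; a valid day has >= 600 wear minutes and
    eligibility requires >= 4 valid days.
    """

    sedentary_max: int = 99
    light_max: int = 1951
    nonwear_min_minutes: int = 60
    nonwear_allowance_minutes: int = 2
    nonwear_allowance_max_cpm: int = 49
    min_wear_bout_minutes: int = 120
    valid_day_wear_minutes: int = 600
    min_valid_days: int = 4


DEFAULT_THRESHOLDS = Thresholds()


class DataError(ValueError):
    """Raised for malformed input data (negative counts, duplicates...)."""


class ScreeningError(ValueError):
    """Raised when a computation requires valid days that do not exist."""


@dataclass
class ActivityTrace:
    """One participant's week of minute-epoch activity counts.

    Entries are keyed by (weekday, minute_of_day); weekday is 1..7 with
    Monday = 1. Up to 10,080 entries (7 days x 1440 minutes).
    """

    participant_id: str
    weekday: np.ndarray  # int, 1..7
    minute_of_day: np.ndarray  # int, 0..1439
    cpm: np.ndarray  # non-negative int
    epoch_seconds: int = 60

    def __post_init__(self) -> None:
        self.weekday = np.asarray(self.weekday, dtype=np.int64)
        self.minute_of_day = np.asarray(self.minute_of_day, dtype=np.int64)
        self.cpm = np.asarray(self.cpm)
        if len({len(self.weekday), len(self.minute_of_day), len(self.cpm)}) != 1:
            raise DataError("weekday, minute_of_day and cpm must be aligned")
        if len(self.cpm) > WEEK_MINUTES:
            raise DataError(f"trace has more than {WEEK_MINUTES} entries")
        if np.any(pd.isna(self.cpm)):
            raise DataError("missing cpm values are rejected, not imputed")
        self.cpm = self.cpm.astype(np.int64)
        if np.any(self.cpm < 0):
            raise DataError("negative cpm")
        if np.any((self.weekday < 1) | (self.weekday > 7)):
            raise DataError("weekday outside 1..7")
        if np.any((self.minute_of_day < 0) | (self.minute_of_day >= MINUTES_PER_DAY)):
            raise DataError("minute_of_day outside 0..1439")
        key = self.weekday * MINUTES_PER_DAY + self.minute_of_day
        if len(np.unique(key)) != len(key):
            raise DataError("duplicate (weekday, minute_of_day) entries")

    def __len__(self) -> int:
        return len(self.cpm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "weekday": self.weekday,
                "minute_of_day": self.minute_of_day,
                "cpm": self.cpm,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, participant_id: str | None = None) -> "ActivityTrace":
        pid = participant_id if participant_id is not None else str(df["participant_id"].iloc[0])
        return cls(
            participant_id=pid,
            weekday=df["weekday"].to_numpy(),
            minute_of_day=df["minute_of_day"].to_numpy(),
            cpm=df["cpm"].to_numpy(),
        )


@dataclass
class IntensitySeries:
    """Per-minute intensity categories aligned to a trace."""

    participant_id: str
    weekday: np.ndarray
    minute_of_day: np.ndarray
    category: np.ndarray  # codes NONWEAR/SEDENTARY/LIGHT/MVPA


@dataclass
class DailySummary:
    weekday: int
    wear_minutes: int
    sedentary_minutes: int
    light_minutes: int
    mvpa_minutes: int
    valid: bool


@dataclass
class BoutMetrics:
    """Per-participant durations and sedentary accumulation metrics.

    Percent fields are of total sedentary time on valid days;
    interruptions_per_sed_hour is None when there is no sedentary time.
    """

    sedentary_min_per_day: float
    light_min_per_day: float
    mvpa_min_per_day: float
    pct_sed_15_30: float
    pct_sed_ge30: float
    interruptions_per_sed_hour: float | None
    n_valid_days: int = 0
    total_sedentary_minutes: int = 0


def _day_slices(trace_weekday: np.ndarray):
    """Yield (weekday, index array) per day present, in weekday order."""
    for wd in range(1, 8):
        idx = np.nonzero(trace_weekday == wd)[0]
        if len(idx):
            yield wd, idx


def detect_nonwear(trace: ActivityTrace, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Flag non-wear minutes.

    A minute is non-wear iff it lies inside some window of at least
    ``nonwear_min_minutes`` consecutive minutes in which every count is
    below 50 cpm and at most ``nonwear_allowance_minutes`` counts are
    non-zero. A count >= 50 cpm always breaks a candidate window. Scanning
    is per calendar day (day boundaries break runs).

    Returns a boolean *wear* mask aligned to the trace (True = wear).
    """
    if np.any(trace.cpm < 0):
        raise DataError("negative cpm")
    wear = np.ones(len(trace), dtype=bool)
    min_len = thresholds.nonwear_min_minutes
    allow_n = thresholds.nonwear_allowance_minutes
    allow_max = thresholds.nonwear_allowance_max_cpm
    for _, idx in _day_slices(trace.weekday):
        order = idx[np.argsort(trace.minute_of_day[idx])]
        minutes = trace.minute_of_day[order]
        cpm = trace.cpm[order]
        n = len(order)
        # Non-contiguous recorded minutes break runs, like day boundaries.
        breaks = np.nonzero(np.diff(minutes) != 1)[0]
        seg_starts = np.concatenate([[0], breaks + 1])
        seg_ends = np.concatenate([breaks, [n - 1]])
        for s0, s1 in zip(seg_starts, seg_ends):
            _flag_segment(cpm, s0, s1, min_len, allow_n, allow_max, wear, order)
    return wear


def _flag_segment(cpm, s0, s1, min_len, allow_n, allow_max, wear, order) -> None:
    """Two-pointer sweep: for each right end r, the longest valid window
    [L(r), r]; flag it when it reaches min_len. The union over r of these
    maximal windows equals the union of all valid windows of length >= min_len."""
    left = s0
    nonzero_in_window = 0
    cur_start = cur_end = None  # open interval of the flagged union
    for r in range(s0, s1 + 1):
        c = cpm[r]
        if c > allow_max:
            left = r + 1
            nonzero_in_window = 0
            continue
        if c > 0:
            nonzero_in_window += 1
            while nonzero_in_window > allow_n:
                if cpm[left] > 0:
                    nonzero_in_window -= 1
                left += 1
        if r - left + 1 >= min_len:
            if cur_start is None:
                cur_start, cur_end = left, r
            elif left <= cur_end + 1:
                cur_end = r
            else:
                wear[order[cur_start : cur_end + 1]] = False
                cur_start, cur_end = left, r
    if cur_start is not None:
        wear[order[cur_start : cur_end + 1]] = False


def filter_short_wear(
    trace: ActivityTrace, wear: np.ndarray, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> np.ndarray:
    """Reclassify wear runs not exceeding ``min_wear_bout_minutes`` as non-wear.

    Runs are maximal consecutive wear minutes within a day; a run is kept
    only if strictly longer than the threshold (120-min runs are dropped).
    """
    out = wear.copy()
    for _, idx in _day_slices(trace.weekday):
        order = idx[np.argsort(trace.minute_of_day[idx])]
        minutes = trace.minute_of_day[order]
        w = out[order]
        n = len(order)
        i = 0
        while i < n:
            if not w[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and w[j + 1] and minutes[j + 1] == minutes[j] + 1:
                j += 1
            if j - i + 1 <= thresholds.min_wear_bout_minutes:
                out[order[i : j + 1]] = False
            i = j + 1
    return out


def classify_intensity(
    trace: ActivityTrace, wear: np.ndarray, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> IntensitySeries:
    """Label each minute sedentary / light / MVPA by cut-points; non-wear wins."""
    if np.any(trace.cpm < 0):
        raise DataError("negative cpm")
    cat = np.full(len(trace), NONWEAR, dtype=np.int8)
    sed = trace.cpm <= thresholds.sedentary_max
    light = (trace.cpm > thresholds.sedentary_max) & (trace.cpm <= thresholds.light_max)
    mvpa = trace.cpm > thresholds.light_max
    cat[wear & sed] = SEDENTARY
    cat[wear & light] = LIGHT
    cat[wear & mvpa] = MVPA
    return IntensitySeries(
        participant_id=trace.participant_id,
        weekday=trace.weekday.copy(),
        minute_of_day=trace.minute_of_day.copy(),
        category=cat,
    )


def screen_valid(
    series: IntensitySeries, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[list[DailySummary], bool]:
    """Per-day wear summaries; a day is valid at >= 600 wear minutes and a
    participant is eligible with >= 4 valid days."""
    daily: list[DailySummary] = []
    for wd, idx in _day_slices(series.weekday):
        cat = series.category[idx]
        sed = int(np.sum(cat == SEDENTARY))
        li = int(np.sum(cat == LIGHT))
        mv = int(np.sum(cat == MVPA))
        wearmin = sed + li + mv
        daily.append(
            DailySummary(
                weekday=wd,
                wear_minutes=wearmin,
                sedentary_minutes=sed,
                light_minutes=li,
                mvpa_minutes=mv,
                valid=wearmin >= thresholds.valid_day_wear_minutes,
            )
        )
    eligible = sum(d.valid for d in daily) >= thresholds.min_valid_days
    return daily, eligible


def mean_daily_durations(
    series: IntensitySeries, daily: list[DailySummary]
) -> tuple[float, float, float]:
    """Mean sedentary / light / MVPA minutes per valid day."""
    valid = [d for d in daily if d.valid]
    if not valid:
        raise ScreeningError("no valid days: mean daily durations undefined")
    n = len(valid)
    sed = sum(d.sedentary_minutes for d in valid) / n
    li = sum(d.light_minutes for d in valid) / n
    mv = sum(d.mvpa_minutes for d in valid) / n
    return sed, li, mv


def _sedentary_bouts_one_day(cat_day: np.ndarray, minutes_day: np.ndarray):
    """Maximal sedentary runs within one day; runs break where recorded
    minutes are non-contiguous. Yields (length, next_category_or_None)."""
    n = len(cat_day)
    i = 0
    while i < n:
        if cat_day[i] == SEDENTARY:
            j = i
            while (
                j + 1 < n
                and cat_day[j + 1] == SEDENTARY
                and minutes_day[j + 1] == minutes_day[j] + 1
            ):
                j += 1
            nxt = None
            if j + 1 < n and minutes_day[j + 1] == minutes_day[j] + 1:
                nxt = int(cat_day[j + 1])
            yield j - i + 1, nxt
            i = j + 1
        else:
            i += 1


def sedentary_bout_metrics(
    series: IntensitySeries,
    daily: list[DailySummary],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> BoutMetrics:
    """Sedentary accumulation metrics over valid days.

    Qualifying bouts are maximal sedentary runs of >= 2 consecutive minutes
    (bouts "lasting > 1 min"), broken at day boundaries and non-wear.
    ``pct_sed_15_30`` covers bout lengths in [15, 30) min and
    ``pct_sed_ge30`` lengths >= 30 min, both as a percentage of all
    sedentary minutes on valid days. An interruption is a qualifying bout
    followed immediately by an active (light or MVPA) minute; the count is
    divided by total sedentary hours.
    """
    sed_pd, light_pd, mvpa_pd = mean_daily_durations(series, daily)
    valid_days = {d.weekday for d in daily if d.valid}
    total_sed = 0
    min_15_30 = 0
    min_ge30 = 0
    interruptions = 0
    for wd, idx in _day_slices(series.weekday):
        if wd not in valid_days:
            continue
        order = idx[np.argsort(series.minute_of_day[idx])]
        cat = series.category[order]
        minutes = series.minute_of_day[order]
        total_sed += int(np.sum(cat == SEDENTARY))
        for length, nxt in _sedentary_bouts_one_day(cat, minutes):
            if 15 <= length < 30:
                min_15_30 += length
            elif length >= 30:
                min_ge30 += length
            if length >= 2 and nxt in (LIGHT, MVPA):
                interruptions += 1
    if total_sed == 0:
        return BoutMetrics(sed_pd, light_pd, mvpa_pd, 0.0, 0.0, None,
                           n_valid_days=len(valid_days), total_sedentary_minutes=0)
    return BoutMetrics(
        sedentary_min_per_day=sed_pd,
        light_min_per_day=light_pd,
        mvpa_min_per_day=mvpa_pd,
        pct_sed_15_30=100.0 * min_15_30 / total_sed,
        pct_sed_ge30=100.0 * min_ge30 / total_sed,
        interruptions_per_sed_hour=interruptions / (total_sed / 60.0),
        n_valid_days=len(valid_days),
        total_sedentary_minutes=total_sed,
    )


def process_trace(
    trace: ActivityTrace, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[IntensitySeries, list[DailySummary], bool]:
    """Full cleaning chain: non-wear, short-bout filter, classification,
    screening. Returns the labelled series, daily summaries, eligibility."""
    wear = detect_nonwear(trace, thresholds)
    wear = filter_short_wear(trace, wear, thresholds)
    series = classify_intensity(trace, wear, thresholds)
    daily, eligible = screen_valid(series, thresholds)
    return series, daily, eligible


def metrics_table(
    results: dict[str, BoutMetrics],
) -> pd.DataFrame:
    """Assemble per-participant metrics into a tidy table."""
    rows = []
    for pid, m in results.items():
        rows.append(
            {
                "participant_id": pid,
                "sedentary_min_per_day": m.sedentary_min_per_day,
                "light_min_per_day": m.light_min_per_day,
                "mvpa_min_per_day": m.mvpa_min_per_day,
                "pct_sed_15_30": m.pct_sed_15_30,
                "pct_sed_ge30": m.pct_sed_ge30,
                "interruptions_per_sed_hour": m.interruptions_per_sed_hour,
                "n_valid_days": m.n_valid_days,
            }
        )
    return pd.DataFrame(rows)
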