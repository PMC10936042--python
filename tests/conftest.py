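import numpy as np
import pytest

from actiprofile.preprocess import ActivityTrace, MINUTES_PER_DAY


def make_day_trace(cpm_by_minute, weekday: int = 1, pid: str = "T") -> ActivityTrace:
    """One-day trace from an explicit per-minute cpm vector."""
    cpm = np.asarray(cpm_by_minute, dtype=np.int64)
    return ActivityTrace(
        participant_id=pid,
        weekday=np.full(len(cpm), weekday),
        minute_of_day=np.arange(len(cpm)),
        cpm=cpm,
    )


def make_week_trace(cpm_grid) -> ActivityTrace:
    """Full-week trace from a (7, 1440) cpm grid."""
    cpm = np.asarray(cpm_grid, dtype=np.int64)
    assert cpm.shape == (7, MINUTES_PER_DAY)
    return ActivityTrace(
        participant_id="W",
        weekday=np.repeat(np.arange(1, 8), MINUTES_PER_DAY),
        minute_of_day=np.tile(np.arange(MINUTES_PER_DAY), 7),
        cpm=cpm.reshape(-1),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
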