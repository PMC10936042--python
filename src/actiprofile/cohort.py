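"""Synthetic cohort generator for minute-epoch accelerometry studies.

Emulates 7-day hip-accelerometer wear at 60-s epochs with diurnal
structure: per-archetype minute-resolution category weights (sedentary /
light / MVPA), daily wear windows, within-day non-wear gaps, plus a
covariate table and cardiometabolic markers with planted archetype effects.

Four default archetypes mirror the movement-behavior profiles this kind of
analysis recovers in adult cohorts: "Lowest activity", "Early-morning
movers", "Least sedentary movers", and "Highest activity".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ActivityTrace, MINUTES_PER_DAY

# cpm ranges per intensity category (uniform draws within category).
SED_RANGE = (0, 99)
LIGHT_RANGE = (100, 1951)
MVPA_RANGE = (1952, 6000)


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass
class ArchetypeSpec:
    """A behavioral archetype: diurnal category weights and wear habits.

    ``block_weights`` holds per-weekday piecewise-constant 30-min blocks of
    (sedentary, light, mvpa) probability weights, shape (7, 48, 3); they are
    expanded to minute resolution on demand. Wear windows are normal in
    start/end minute (clipped); non-wear gaps within the window are Poisson
    in count with shifted-exponential lengths (minimum 60 min so that each
    planted gap is detectable by the standard non-wear rule).
    """

    name: str
    block_weights: np.ndarray  # (7, 48, 3), rows sum to 1
    wear_start_mean: float = 480.0  # minutes from midnight
    wear_start_sd: float = 30.0
    wear_end_mean: float = 1290.0
    wear_end_sd: float = 30.0
    gaps_per_day: float = 0.3
    gap_min_minutes: int = 60
    gap_mean_extra_minutes: float = 40.0
    allowance_noise: bool = False  # inject <=2 min of 1-49 cpm per gap

    def __post_init__(self) -> None:
        self.block_weights = np.asarray(self.block_weights, dtype=float)
        if self.block_weights.shape != (7, 48, 3):
            raise ConfigurationError("block_weights must have shape (7, 48, 3)")
        if np.any(self.block_weights < 0):
            raise ConfigurationError("category weights must be non-negative")
        sums = self.block_weights.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ConfigurationError("category weights must sum to 1 per block")
        if not (0 <= self.wear_start_mean < self.wear_end_mean <= MINUTES_PER_DAY):
            raise ConfigurationError("wear window must be ordered within the day")
        if self.gaps_per_day < 0 or self.gap_mean_extra_minutes < 0:
            raise ConfigurationError("gap parameters must be non-negative")

    @property
    def minute_weights(self) -> np.ndarray:
        """(7, 1440, 3) per-minute category weights."""
        return np.repeat(self.block_weights, MINUTES_PER_DAY // 48, axis=1)

    @property
    def target_daily_minutes(self) -> dict[str, float]:
        """Expected sedentary/light/MVPA minutes per day.

        Closed form: category weights summed over the mean wear window,
        scaled by the expected fraction of the window lost to gaps.
        """
        s = int(round(self.wear_start_mean))
        e = int(round(self.wear_end_mean))
        window = e - s
        gap_minutes = self.gaps_per_day * (self.gap_min_minutes + self.gap_mean_extra_minutes)
        keep = max(0.0, 1.0 - gap_minutes / window)
        mw = self.minute_weights[:, s:e, :].sum(axis=1).mean(axis=0) * keep
        total = mw.sum()
        if total > MINUTES_PER_DAY:
            raise ConfigurationError("target daily minutes exceed one day")
        return {"sedentary": mw[0], "light": mw[1], "mvpa": mw[2]}


def _blocks(sed: float, light: float, mvpa: float) -> np.ndarray:
    w = np.array([sed, light, mvpa], dtype=float)
    return w / w.sum()


def _flat_day(sed: float, light: float, mvpa: float) -> np.ndarray:
    return np.tile(_blocks(sed, light, mvpa), (48, 1))


def default_archetypes() -> list[ArchetypeSpec]:
    """The four standard archetypes, well separated in level and timing."""
    # Lowest activity: short wear day, dominated by sedentary time.
    low = np.tile(_flat_day(0.90, 0.09, 0.01), (7, 1, 1))

    # Early-morning movers: strong MVPA burst 06:00-08:00 Mon-Fri,
    # 07:00-12:00 Sat; otherwise moderately sedentary.
    em = np.tile(_flat_day(0.72, 0.26, 0.02), (7, 1, 1))
    for wd in range(5):  # Mon-Fri
        em[wd, 12:16] = _blocks(0.10, 0.25, 0.65)  # 06:00-08:00
    em[5, 14:24] = _blocks(0.25, 0.40, 0.35)  # Sat 07:00-12:00

    # Least sedentary movers: light activity dominates the whole day.
    ls = np.tile(_flat_day(0.22, 0.74, 0.04), (7, 1, 1))
    ls[:, 22:28] = _blocks(0.15, 0.70, 0.15)  # midday bump 11:00-14:00

    # Highest activity: elevated MVPA throughout the waking day.
    hi = np.tile(_flat_day(0.38, 0.36, 0.26), (7, 1, 1))

    return [
        ArchetypeSpec("Lowest activity", low, wear_start_mean=540, wear_end_mean=1260),
        ArchetypeSpec("Early-morning movers", em, wear_start_mean=350, wear_end_mean=1290),
        ArchetypeSpec("Least sedentary movers", ls, wear_start_mean=450, wear_end_mean=1320),
        ArchetypeSpec("Highest activity", hi, wear_start_mean=390, wear_end_mean=1320),
    ]


@dataclass
class CohortConfig:
    """Cohort-level generator settings."""

    n_participants: int = 200
    archetypes: list[ArchetypeSpec] = field(default_factory=default_archetypes)
    archetype_weights: np.ndarray | None = None  # default uniform
    seed: int = 0
    epoch_seconds: int = 60
    randomize_start_weekday: bool = False
    # Additive shifts on the log scale (LDL: raw scale), keyed by archetype
    # name then marker name.
    marker_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    age_mean_by_archetype: tuple[float, ...] = (40.4, 44.8, 41.4, 45.8)
    age_sd: float = 12.5

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        k = len(self.archetypes)
        if self.archetype_weights is None:
            self.archetype_weights = np.full(k, 1.0 / k)
        self.archetype_weights = np.asarray(self.archetype_weights, dtype=float)
        if len(self.archetype_weights) != k:
            raise ConfigurationError("one weight per archetype required")
        if np.any(self.archetype_weights < 0) or not np.isclose(self.archetype_weights.sum(), 1.0):
            raise ConfigurationError("archetype_weights must be a probability vector")


def default_marker_effects() -> dict[str, dict[str, float]]:
    """Planted log-scale marker shifts mirroring the expected pattern:
    morning movers and the most active profile have lower insulin,
    triglycerides and glucose than the least active profile."""
    return {
        "Early-morning movers": {"insulin": -0.22, "triglycerides": -0.10, "glucose": -0.02},
        "Highest activity": {"insulin": -0.20, "triglycerides": -0.15, "glucose": -0.01},
    }


def generate_trace(archetype: ArchetypeSpec, seed: int, start_weekday: int = 1) -> ActivityTrace:
    """Draw one participant's 7-day minute-epoch trace.

    Within each day a wear window is drawn, within-window non-wear gaps are
    placed, and each wear minute's category is sampled from the archetype's
    minute weights, then a cpm value uniform within the category's range.
    Non-wear minutes emit 0 cpm (optionally with <=2 low-count allowance
    minutes per gap). The trace always covers 7 x 1440 minutes.
    """
    if not isinstance(archetype, ArchetypeSpec):
        raise ConfigurationError("archetype must be an ArchetypeSpec")
    rng = np.random.default_rng(seed)
    mw = archetype.minute_weights
    cpm = np.zeros((7, MINUTES_PER_DAY), dtype=np.int64)
    for day in range(7):
        wd = (start_weekday - 1 + day) % 7  # 0-based weekday of this day
        start = int(np.clip(round(rng.normal(archetype.wear_start_mean, archetype.wear_start_sd)),
                            60, MINUTES_PER_DAY // 2))
        end = int(np.clip(round(rng.normal(archetype.wear_end_mean, archetype.wear_end_sd)),
                          start + 240, MINUTES_PER_DAY - 60))
        wear = np.zeros(MINUTES_PER_DAY, dtype=bool)
        wear[start:end] = True
        n_gaps = rng.poisson(archetype.gaps_per_day)
        for _ in range(n_gaps):
            length = archetype.gap_min_minutes + int(
                rng.exponential(archetype.gap_mean_extra_minutes)
            )
            if end - start <= length:
                continue
            g0 = int(rng.integers(start, end - length))
            wear[g0 : g0 + length] = False
            if archetype.allowance_noise and length > 4:
                n_noise = int(rng.integers(1, 3))
                pos = rng.choice(np.arange(g0 + 1, g0 + length - 1), size=n_noise, replace=False)
                cpm[wd, pos] = rng.integers(1, 50, size=n_noise)
        widx = np.nonzero(wear)[0]
        if len(widx) == 0:
            continue
        probs = mw[wd, widx]  # (n_wear, 3)
        u = rng.random(len(widx))
        cum = np.cumsum(probs, axis=1)
        cat = (u[:, None] > cum).sum(axis=1)  # 0 sed, 1 light, 2 mvpa
        vals = np.empty(len(widx), dtype=np.int64)
        for code, (lo, hi) in enumerate((SED_RANGE, LIGHT_RANGE, MVPA_RANGE)):
            m = cat == code
            vals[m] = rng.integers(lo, hi + 1, size=int(m.sum()))
        cpm[wd, widx] = vals
    weekday = np.repeat(np.arange(1, 8), MINUTES_PER_DAY)
    minute = np.tile(np.arange(MINUTES_PER_DAY), 7)
    return ActivityTrace(
        participant_id="", weekday=weekday, minute_of_day=minute, cpm=cpm.reshape(-1)
    )


def generate_cohort(config: CohortConfig) -> tuple[list[ActivityTrace], np.ndarray]:
    """Draw a cohort of traces plus the true archetype label per participant."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    labels = rng.choice(len(config.archetypes), size=n, p=config.archetype_weights)
    traces: list[ActivityTrace] = []
    for i in range(n):
        start_wd = int(rng.integers(1, 8)) if config.randomize_start_weekday else 1
        trace_seed = int(rng.integers(0, 2**31 - 1))
        t = generate_trace(config.archetypes[labels[i]], trace_seed, start_weekday=start_wd)
        t.participant_id = f"P{i:05d}"
        traces.append(t)
    return traces, labels


def generate_covariates(labels: np.ndarray, config: CohortConfig, seed: int) -> pd.DataFrame:
    """Demographic / lifestyle covariates with mild archetype structure."""
    rng = np.random.default_rng(seed)
    n = len(labels)
    age_means = np.asarray(config.age_mean_by_archetype, dtype=float)
    if len(age_means) < len(config.archetypes):
        age_means = np.resize(age_means, len(config.archetypes))
    age = np.clip(rng.normal(age_means[labels], config.age_sd), 20, 65)
    sex = rng.choice(["Male", "Female"], size=n, p=[0.465, 0.535])
    ethnicity = rng.choice(
        ["NH White", "NH Black", "Mexican American", "Other"],
        size=n, p=[0.50, 0.18, 0.22, 0.10],
    )
    marital = rng.choice(
        ["Married", "Divorced/Widowed", "Never married"], size=n, p=[0.70, 0.16, 0.14]
    )
    income_poverty = np.clip(rng.normal(3.0, 1.6, size=n), 0.0, 5.0)
    smoking = rng.choice(
        ["Non-smoker", "Light", "Moderate", "Heavy"], size=n, p=[0.757, 0.060, 0.118, 0.065]
    )
    alcohol = np.clip(rng.exponential(8.6, size=n), 0, 150)
    energy_kcal = np.clip(rng.normal(2200, 800, size=n), 600, 6000)
    sat_fat = np.clip(rng.normal(27.4, 13.1, size=n), 0, 120)
    caffeine = np.clip(rng.exponential(163.0, size=n), 0, 1500)
    cvd = rng.random(n) < 0.052
    diabetes = rng.random(n) < 0.076
    cancer = rng.random(n) < 0.049
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
            "marital_status": marital,
            "income_poverty_ratio": income_poverty,
            "smoking": smoking,
            "alcohol_g_day": alcohol,
            "energy_kcal": energy_kcal,
            "sat_fat_g": sat_fat,
            "caffeine_mg": caffeine,
            "cvd": cvd.astype(int),
            "diabetes": diabetes.astype(int),
            "cancer": cancer.astype(int),
        }
    )


# Baseline log-scale medians and spreads for the marker battery
# (insulin pmol/L, triglycerides mmol/L, glucose mmol/L, CRP mg/dL,
#  total/HDL ratio, waist cm, BMI kg/m2); LDL mmol/L is normal on the raw
# scale. Values chosen to match typical adult cohort distributions.
_MARKER_PARAMS: dict[str, tuple[float, float]] = {
    "insulin": (np.log(47.8), 0.60),
    "triglycerides": (np.log(1.3), 0.40),
    "glucose": (np.log(5.3), 0.09),
    "crp": (np.log(0.2), 0.90),
    "tot_hdl_ratio": (np.log(3.6), 0.22),
    "waist_cm": (np.log(96.2), 0.11),
    "bmi": (np.log(27.8), 0.15),
}
_LDL_MEAN, _LDL_SD = 3.0, 0.9


def generate_markers(
    labels: np.ndarray,
    covariates: pd.DataFrame,
    effects: dict[str, dict[str, float]] | None,
    seed: int,
    archetypes: list[ArchetypeSpec] | None = None,
) -> pd.DataFrame:
    """Cardiometabolic markers with planted archetype and covariate effects.

    Markers are log-normal (LDL normal); archetype effects are additive on
    the log scale; age and sex have modest log-scale effects. HOMA-IR is
    derived from the generated glucose and insulin.
    """
    from .associations import homa_ir

    if len(labels) != len(covariates):
        raise ConfigurationError("labels and covariates must be aligned")
    if archetypes is None:
        archetypes = default_archetypes()
    effects = effects or {}
    rng = np.random.default_rng(seed)
    n = len(labels)
    age_c = (covariates["age"].to_numpy() - 43.0) / 10.0
    male = (covariates["sex"] == "Male").to_numpy().astype(float)
    names = [a.name for a in archetypes]
    out = {"participant_id": covariates["participant_id"].to_numpy()}
    for marker, (mu, sigma) in _MARKER_PARAMS.items():
        if sigma < 0:
            raise ConfigurationError("marker sd must be non-negative")
        shift = np.array([effects.get(names[l], {}).get(marker, 0.0) for l in labels])
        # mild covariate structure: markers drift up with age; waist/ratio
        # higher in males.
        beta_age = 0.04 if marker in ("insulin", "glucose", "waist_cm") else 0.02
        beta_male = 0.05 if marker in ("waist_cm", "tot_hdl_ratio") else 0.0
        logv = mu + shift + beta_age * age_c + beta_male * male + rng.normal(0, sigma, n)
        out[marker] = np.exp(logv)
    ldl_shift = np.array([effects.get(names[l], {}).get("ldl", 0.0) for l in labels])
    out["ldl"] = rng.normal(_LDL_MEAN + ldl_shift + 0.05 * age_c, _LDL_SD, n)
    out["homa_ir"] = homa_ir(out["glucose"], out["insulin"])
    return pd.DataFrame(out)


def traces_to_frame(traces: list[ActivityTrace]) -> pd.DataFrame:
    """Long-format minute-epoch table (participant_id, weekday,
    minute_of_day, cpm) in the package's standard CSV layout."""
    if not traces:
        return pd.DataFrame(columns=["participant_id", "weekday", "minute_of_day", "cpm"])
    return pd.concat([t.to_frame() for t in traces], ignore_index=True)


def traces_from_frame(df: pd.DataFrame) -> list[ActivityTrace]:
    return [
        ActivityTrace.from_frame(g, participant_id=str(pid))
        for pid, g in df.groupby("participant_id", sort=True)
    ]
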