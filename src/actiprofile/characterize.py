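"""Profile characterization: covariate-adjusted comparisons and temporal
distribution heatmaps.

Differences between movement-behavior profiles in durations and sedentary
accumulation metrics are tested with one-way ANCOVA (partial F for the
profile factor after covariate adjustment) followed by Tukey–Kramer
post-hoc comparisons of the adjusted means. Temporal heatmaps give, per
profile and behavior, the percentage of members in that behavior for each
of the 10,080 minutes of the week.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._linmod import (
    adjusted_mean_rows,
    covariate_blocks,
    drop_collinear,
    fit_ols,
    profile_block,
)
from .imaging import N_COLS, N_ROWS
from .preprocess import LIGHT, MVPA, NONWEAR, SEDENTARY


@dataclass
class AncovaResult:
    outcome: str
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    adjusted_means: dict  # level -> (mean, ci_low, ci_high)
    pairwise: dict = field(default_factory=dict)  # (i, j) -> tukey p
    pairwise_diff: dict = field(default_factory=dict)  # (i, j) -> mean_i - mean_j


def ancova_compare(
    table: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    profile_col: str = "profile",
    always_pairwise: bool = False,
    alpha: float = 0.05,
) -> AncovaResult:
    """One-way ANCOVA for ``outcome`` across profiles.

    Fits outcome ~ profile + covariates; the profile factor is tested by
    partial F. Tukey–Kramer pairwise p-values of the covariate-adjusted
    means are computed when the overall test is significant at ``alpha``
    (or unconditionally with ``always_pairwise``).
    """
    levels_all = sorted(table[profile_col].unique(), key=str)
    if len(levels_all) < 2:
        raise ValueError("need at least two profiles")
    referent = levels_all[0]
    prof, levels = profile_block(table[profile_col], referent)
    covs, _ = covariate_blocks(table, covariates)
    x = pd.concat([prof, covs], axis=1)
    x = drop_collinear(x, protected=list(prof.columns))
    y = table[outcome].to_numpy(dtype=float)
    fit, xc = fit_ols(y, x)
    k = len(levels)

    prof_cols = [c for c in xc.columns if c.startswith("profile[")]
    if np.allclose(y, y[0]):
        f_stat, p_val = 0.0, 1.0
    else:
        ftest = fit.f_test(np.eye(len(xc.columns))[[list(xc.columns).index(c) for c in prof_cols]])
        f_stat, p_val = float(ftest.fvalue), float(ftest.pvalue)

    df_den = int(fit.df_resid)
    rows = adjusted_mean_rows(xc, levels, referent)
    cov_beta = fit.cov_params().to_numpy()
    beta = fit.params.to_numpy()
    tcrit = stats.t.ppf(0.975, df_den)
    adj = {}
    for level, r in rows.items():
        m = float(r @ beta)
        se = float(np.sqrt(r @ cov_beta @ r))
        adj[level] = (m, m - tcrit * se, m + tcrit * se)

    result = AncovaResult(
        outcome=outcome, f_statistic=f_stat, p_value=p_val,
        df_num=len(prof_cols), df_den=df_den, adjusted_means=adj,
    )
    if always_pairwise or p_val < alpha:
        for a in range(k):
            for b in range(a + 1, k):
                ra, rb = rows[levels[a]], rows[levels[b]]
                d = ra - rb
                diff = float(d @ beta)
                se = float(np.sqrt(d @ cov_beta @ d))
                if se == 0:
                    p = 1.0
                else:
                    q = abs(diff) / se * np.sqrt(2.0)
                    p = float(stats.studentized_range.sf(q, k, df_den))
                result.pairwise[(levels[a], levels[b])] = min(1.0, p)
                result.pairwise_diff[(levels[a], levels[b])] = diff
    return result


def temporal_heatmap(
    matrices: dict[str, np.ndarray], assignments: pd.Series
) -> dict:
    """Minute-by-minute behavior prevalence per profile.

    ``matrices`` maps participant id -> 168x60 categorical grid;
    ``assignments`` maps participant id -> profile id. Returns
    {profile: {behavior: length-10,080 percentage vector}} ordered Monday
    through Sunday; per minute the four percentages sum to 100.
    """
    out: dict = {}
    for profile, members in assignments.groupby(assignments):
        ids = list(members.index)
        if not ids:
            raise ValueError(f"profile {profile} is empty")
        stack = np.stack([matrices[i] for i in ids])  # (m, 168, 60)
        flat = stack.reshape(len(ids), N_ROWS * N_COLS)
        prof = {}
        for code, name in ((MVPA, "mvpa"), (LIGHT, "light"),
                           (SEDENTARY, "sedentary"), (NONWEAR, "nonwear")):
            prof[name] = 100.0 * np.mean(flat == code, axis=0)
        out[profile] = prof
    return out


def smooth_heatmap(vector: np.ndarray, window: int = 15) -> np.ndarray:
    """Centered moving average for display; raw values are the artifact."""
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(vector, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: len(vector)]


def profile_summary(
    table: pd.DataFrame,
    continuous: list[str],
    categorical: list[str],
    markers: list[str],
    profile_col: str = "profile",
) -> pd.DataFrame:
    """Descriptive table: mean (SD) for continuous covariates, count (%)
    for categorical, median (IQR) for markers — overall and per profile."""
    groups = [("Overall", table)] + [
        (str(p), g) for p, g in table.groupby(profile_col, sort=True)
    ]
    rows = []
    for name, g in groups:
        n = len(g)
        row: dict = {"group": name, "n": n}
        for c in continuous:
            v = g[c].astype(float)
            sd = v.std(ddof=1) if n > 1 else np.nan
            row[c] = f"{v.mean():.1f} ({sd:.1f})" if np.isfinite(sd) else f"{v.mean():.1f} (NA)"
        for c in categorical:
            counts = g[c].value_counts()
            row[c] = "; ".join(f"{lvl}: {cnt} ({100 * cnt / n:.1f}%)" for lvl, cnt in counts.items())
        for c in markers:
            v = g[c].astype(float)
            q1, med, q3 = v.quantile([0.25, 0.5, 0.75])
            row[c] = f"{med:.1f} ({q1:.1f}, {q3:.1f})"
        rows.append(row)
    return pd.DataFrame(rows)
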