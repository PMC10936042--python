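"""Shared design-matrix helpers for the covariate-adjusted analyses.

Categorical covariates are expanded to treatment-coded dummy blocks; the
profile factor is always treatment-coded against a referent level.
Adjusted (marginal) means are model predictions at the covariate sample
means, with categorical covariates held at their sample proportions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm


def is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool


def profile_block(profiles: pd.Series, referent) -> tuple[pd.DataFrame, list]:
    """Treatment-coded profile dummies (referent level dropped)."""
    levels = sorted(profiles.unique(), key=str)
    if referent not in levels:
        raise ValueError(f"referent profile {referent!r} not present")
    others = [l for l in levels if l != referent]
    cols = {f"profile[{l}]": (profiles == l).astype(float).to_numpy() for l in others}
    return pd.DataFrame(cols, index=profiles.index), levels


def covariate_blocks(
    df: pd.DataFrame, covariates: list[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand covariates into design columns; returns (frame, term->cols)."""
    pieces = []
    terms: dict[str, list[str]] = {}
    for cov in covariates:
        s = df[cov]
        if is_categorical(s):
            d = pd.get_dummies(s.astype(str), prefix=cov, drop_first=True).astype(float)
            pieces.append(d)
            terms[cov] = list(d.columns)
        else:
            pieces.append(s.astype(float).to_frame(cov))
            terms[cov] = [cov]
    out = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=df.index)
    return out, terms


def drop_collinear(x: pd.DataFrame, protected: list[str]) -> pd.DataFrame:
    """Greedily drop non-protected columns that are linearly dependent on
    the preceding ones (rank check via QR), warning per drop."""
    cols = list(x.columns)
    keep: list[str] = []
    m = np.empty((len(x), 0))
    for c in cols:
        cand = np.column_stack([m, x[c].to_numpy()])
        if np.linalg.matrix_rank(cand) > m.shape[1]:
            keep.append(c)
            m = cand
        else:
            if c in protected:
                raise ValueError(f"protected design column {c} is collinear")
            warnings.warn(f"dropping collinear covariate column {c}")
    return x[keep]


def fit_ols(y: np.ndarray, x: pd.DataFrame):
    xc = sm.add_constant(x, has_constant="add")
    return sm.OLS(np.asarray(y, dtype=float), xc.astype(float)).fit(), xc


def adjusted_mean_rows(
    xc: pd.DataFrame, levels: list, referent
) -> dict[object, np.ndarray]:
    """Per-profile prediction rows: profile dummies set to the level's
    pattern, every other column at its sample mean."""
    base = xc.mean(axis=0).to_numpy(dtype=float)
    colnames = list(xc.columns)
    prof_cols = {c: i for i, c in enumerate(colnames) if c.startswith("profile[")}
    rows = {}
    for level in levels:
        r = base.copy()
        for c, i in prof_cols.items():
            r[i] = 1.0 if c == f"profile[{level}]" else 0.0
        rows[level] = r
    return rows
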