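"""Profile–cardiometabolic-marker association analysis.

Markers are derived where needed (HOMA-IR, total/HDL ratio), skewed
markers are log-transformed, outcome-specific confounders are chosen by
backward elimination (retained at P < 0.2), and linear regression against
the least-active referent profile yields covariate-adjusted means with
95% confidence intervals, back-transformed to the original scale for
log-modelled markers.
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

# Markers modelled on the log scale under the default policy; LDL is the
# exception (approximately normal on the raw scale).
LOG_MARKERS = {
    "insulin", "triglycerides", "glucose", "homa_ir", "crp",
    "tot_hdl_ratio", "waist_cm", "bmi",
}


@dataclass
class AssociationResult:
    marker: str
    referent: object
    log_scale: bool
    # level -> (adjusted mean, ci_low, ci_high) on the reporting scale
    adjusted_means: dict
    # level -> p-value vs referent (referent itself absent)
    p_values: dict
    retained_covariates: list[str] = field(default_factory=list)
    coefficients: dict = field(default_factory=dict)  # level -> model-scale coef


def homa_ir(glucose: np.ndarray, insulin: np.ndarray, insulin_unit: str = "pmol/L") -> np.ndarray:
    """Homeostasis model assessment of insulin resistance.

    glucose in mmol/L; insulin either in pmol/L (used directly) or in
    uU/mL. Formula: glucose x insulin / 22.5.
    """
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if np.any(glucose <= 0):
        raise ValueError("glucose must be positive")
    if np.any(insulin < 0):
        raise ValueError("insulin must be non-negative")
    if insulin_unit not in ("pmol/L", "uU/mL"):
        raise ValueError("insulin_unit must be 'pmol/L' or 'uU/mL'")
    return glucose * insulin / 22.5


def total_hdl_ratio(total_chol: np.ndarray, hdl: np.ndarray) -> np.ndarray:
    total_chol = np.asarray(total_chol, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    if np.any(hdl <= 0):
        raise ValueError("HDL must be positive")
    return total_chol / hdl


def choose_transform(marker: str, values: np.ndarray, policy: str = "paper_default") -> bool:
    """Decide whether a marker is modelled on the log scale.

    ``paper_default``: every marker in the standard battery except LDL is
    log-transformed. ``test``: log-transform when a D'Agostino normality
    test rejects at alpha = 0.05.
    """
    values = np.asarray(values, dtype=float)
    if policy == "paper_default":
        use_log = marker.lower() != "ldl"
    elif policy == "test":
        _, p = stats.normaltest(values)
        use_log = p < 0.05
    else:
        raise ValueError(f"unknown transform policy {policy!r}")
    if use_log and np.any(values <= 0):
        raise ValueError(f"log transform requested for {marker} with non-positive values")
    return bool(use_log)


def backward_eliminate(
    table: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    profile_col: str = "profile",
    referent=None,
    threshold: float = 0.2,
    log_outcome: bool = False,
) -> list[str]:
    """Outcome-specific backward elimination of covariates.

    Iteratively refits outcome ~ profile + covariates and drops the single
    worst covariate with p >= threshold (categorical covariates tested and
    dropped as whole blocks by partial F) until all survivors have
    p < threshold. The profile factor is never eligible for removal.
    """
    if referent is None:
        referent = sorted(table[profile_col].unique(), key=str)[0]
    y = table[outcome].to_numpy(dtype=float)
    if log_outcome:
        y = np.log(y)
    retained = list(candidates)
    prof, _ = profile_block(table[profile_col], referent)
    while retained:
        covs, terms = covariate_blocks(table, retained)
        x = drop_collinear(pd.concat([prof, covs], axis=1), protected=list(prof.columns))
        fit, xc = fit_ols(y, x)
        cols = list(xc.columns)
        worst_term, worst_p = None, threshold
        for term in retained:
            tcols = [c for c in terms[term] if c in cols]
            if not tcols:  # fully collinear block: drop outright
                worst_term, worst_p = term, np.inf
                break
            contrast = np.eye(len(cols))[[cols.index(c) for c in tcols]]
            p = float(fit.f_test(contrast).pvalue)
            if p >= worst_p:
                worst_term, worst_p = term, p
        if worst_term is None:
            break
        retained.remove(worst_term)
    return retained


def fit_association(
    table: pd.DataFrame,
    marker: str,
    referent,
    covariates: list[str],
    log_scale: bool | None = None,
    profile_col: str = "profile",
    transform_policy: str = "paper_default",
) -> AssociationResult:
    """Linear regression of a (possibly log) marker on profile + covariates.

    Profiles are treatment-coded against ``referent``; adjusted means are
    computed at the covariate sample means and back-transformed (exp) when
    the marker is modelled on the log scale. Per-profile p-values come
    from the profile coefficients (no p-value for the referent).
    """
    values = table[marker].to_numpy(dtype=float)
    if log_scale is None:
        log_scale = choose_transform(marker, values, policy=transform_policy)
    y = np.log(values) if log_scale else values

    counts = table[profile_col].value_counts()
    if (counts == 0).any():
        raise ValueError("empty profile")
    prof, levels = profile_block(table[profile_col], referent)
    covs, _ = covariate_blocks(table, covariates)
    x = drop_collinear(pd.concat([prof, covs], axis=1), protected=list(prof.columns))
    fit, xc = fit_ols(y, x)

    rows = adjusted_mean_rows(xc, levels, referent)
    beta = fit.params.to_numpy()
    cov_beta = fit.cov_params().to_numpy()
    tcrit = stats.t.ppf(0.975, int(fit.df_resid))
    adj, pvals, coefs = {}, {}, {}
    cols = list(xc.columns)
    for level in levels:
        r = rows[level]
        m = float(r @ beta)
        se = float(np.sqrt(r @ cov_beta @ r))
        lo, hi = m - tcrit * se, m + tcrit * se
        if log_scale:
            m, lo, hi = np.exp(m), np.exp(lo), np.exp(hi)
        adj[level] = (m, lo, hi)
        colname = f"profile[{level}]"
        if colname in cols:
            i = cols.index(colname)
            pvals[level] = float(fit.pvalues.iloc[i])
            coefs[level] = float(beta[i])
    return AssociationResult(
        marker=marker, referent=referent, log_scale=bool(log_scale),
        adjusted_means=adj, p_values=pvals,
        retained_covariates=list(covariates), coefficients=coefs,
    )


def significance_tier(p: float) -> str:
    """Reporting tiers: *** P<0.01, ** P<0.05, * P<0.1."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for level, (m, lo, hi) in res.adjusted_means.items():
            rows.append(
                {
                    "marker": res.marker,
                    "profile": level,
                    "adjusted_mean": m,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_vs_referent": res.p_values.get(level, np.nan),
                    "significance": significance_tier(res.p_values[level])
                    if level in res.p_values else "",
                    "log_scale": res.log_scale,
                    "retained_covariates": ";".join(res.retained_covariates),
                }
            )
    return pd.DataFrame(rows)
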