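"""Residual-exposure stratification, per-stratum MR, heterogeneity and trend.

Stratifying directly on the exposure would condition on a collider (the
exposure is a common descendant of the instrument and the confounders) and
distort stratum-specific estimates.  The residual exposure -- measured
exposure minus its genetically predicted component, beta_GX * score -- is
independent of the instrument by construction, so strata defined on it
preserve instrument validity.  Within each stratum, a localized average
causal effect (LACE) is estimated by the ratio of coefficients; Cochran's
Q tests heterogeneity across strata, and an inverse-variance weighted
meta-regression of the LACEs on stratum exposure medians tests for a
linear trend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .grs import AssocEstimate, fit_exposure_assoc
from .survival import MREstimate, ratio_estimate, fit_outcome_assoc

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StratumEstimate:
    """LACE for one stratum with the stratum's measured-exposure median."""

    stratum_index: int
    n: int
    n_events: int
    exposure_median: float
    lace: float
    lace_se: float

    def __post_init__(self):
        if self.lace_se <= 0:
            raise ValueError("lace_se must be positive")


@dataclass(frozen=True)
class StratifiedResult:
    """Per-stratum LACEs plus heterogeneity and trend statistics."""

    strata: list[StratumEstimate]
    q_stat: float
    p_het: float
    trend_slope: float
    trend_se: float
    p_trend: float
    stratify_on: str
    n_strata: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stratum": s.stratum_index,
                "n": s.n,
                "n_events": s.n_events,
                "median": s.exposure_median,
                "lace": s.lace,
                "se": s.lace_se,
                "hr": np.exp(s.lace),
                "ci_low": np.exp(s.lace - 1.959963984540054 * s.lace_se),
                "ci_high": np.exp(s.lace + 1.959963984540054 * s.lace_se),
            }
            for s in self.strata
        ]
        return pd.DataFrame(rows)


def residualize(
    exposure: np.ndarray, score: np.ndarray, beta_gx: float
) -> np.ndarray:
    """Exposure minus its genetic contribution, beta_GX * score.

    Residuals are used only for stratum assignment; stratum medians are
    always taken on the measured exposure.
    """
    if not np.isfinite(beta_gx):
        raise ValueError("beta_gx must be finite")
    return np.asarray(exposure, dtype=float) - beta_gx * np.asarray(score, dtype=float)


def assign_quantile_strata(values: np.ndarray, k: int) -> np.ndarray:
    """Rank-based assignment into k strata of near-equal size (1..k).

    Strata sizes differ by at most 1 (the first ``n mod k`` strata get the
    extra member).  Ties are broken by stable input order, which makes the
    split deterministic even with heavily tied values.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if k < 2:
        raise ValueError("need at least 2 strata")
    if n < k:
        raise ValueError(f"cannot form {k} strata from {n} observations")
    if n < 10 * k:
        logger.warning("fewer than 10 observations per stratum on average")
    if np.all(values == values[0]):
        raise ValueError("degenerate stratifying variable: all values identical")
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    bounds = np.array_split(order, k)
    for idx, block in enumerate(bounds, start=1):
        labels[block] = idx
    return labels


def stratum_lace(
    time: np.ndarray,
    event: np.ndarray,
    score: np.ndarray,
    exposure: np.ndarray,
    labels: np.ndarray,
    covariates: pd.DataFrame | None = None,
    beta_gx: AssocEstimate | None = None,
    refit_beta_gx: bool = False,
    se_method: str = "ratio_delta2",
) -> list[StratumEstimate]:
    """Per-stratum ratio-of-coefficients estimates (LACEs).

    By default the full-cohort instrument-exposure association ``beta_gx``
    is reused in every stratum (the residual-method convention, which also
    stabilizes small strata); with ``refit_beta_gx`` it is re-estimated
    within each stratum.  Strata with no events or a failed Cox fit are
    dropped with a logged reason, never merged.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    score = np.asarray(score, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    labels = np.asarray(labels)
    if beta_gx is None and not refit_beta_gx:
        raise ValueError("either supply beta_gx or set refit_beta_gx=True")
    out: list[StratumEstimate] = []
    for idx in np.unique(labels):
        mask = labels == idx
        n_events = int(event[mask].sum())
        if n_events == 0:
            logger.warning("stratum %s has no events; dropped", idx)
            continue
        cov_k = covariates.loc[mask] if covariates is not None else None
        try:
            gy = fit_outcome_assoc(
                score[mask], time[mask], event[mask], cov_k,
                outcome_label=f"stratum {idx}",
            )
            gx = (
                fit_exposure_assoc(score[mask], exposure[mask], cov_k)
                if refit_beta_gx
                else beta_gx
            )
            mr = ratio_estimate(gy, gx, method=se_method)
        except (RuntimeError, ValueError) as exc:
            logger.warning("stratum %s dropped: %s", idx, exc)
            continue
        out.append(
            StratumEstimate(
                stratum_index=int(idx),
                n=int(mask.sum()),
                n_events=n_events,
                exposure_median=float(np.median(exposure[mask])),
                lace=mr.beta_iv,
                lace_se=mr.se_iv,
            )
        )
    return out


def cochran_q(strata: list[StratumEstimate]) -> tuple[float, float]:
    """Cochran's Q heterogeneity test across stratum estimates.

    Q = sum w_k (b_k - b_FE)^2 with w_k = 1/se_k^2 and b_FE the
    fixed-effect (inverse-variance weighted) mean; p from chi-squared with
    K - 1 degrees of freedom.
    """
    if len(strata) < 2:
        raise ValueError("Cochran Q needs at least 2 strata")
    b = np.array([s.lace for s in strata])
    se = np.array([s.lace_se for s in strata])
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    b_fe = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - b_fe) ** 2))
    p = float(stats.chi2.sf(q, df=len(strata) - 1))
    return q, max(p, 5e-324)


def trend_meta_regression(
    strata: list[StratumEstimate],
) -> tuple[float, float, float]:
    """Inverse-variance weighted linear meta-regression of LACE on median.

    Fits lace_k = a + b * median_k with weights 1/se_k^2 and returns the
    slope, its (fixed-effect) standard error and a two-sided Wald p-value
    using the normal approximation.
    """
    if len(strata) < 3:
        raise ValueError("trend meta-regression needs at least 3 strata")
    x = np.array([s.exposure_median for s in strata])
    y = np.array([s.lace for s in strata])
    se = np.array([s.lace_se for s in strata])
    if np.all(x == x[0]):
        raise ValueError("stratum medians are identical; trend undefined")
    X = sm.add_constant(x)
    w = 1.0 / se**2
    # fixed-effect meta-regression: covariance from the known se_k, not
    # from the residual scale
    xtwx_inv = np.linalg.inv(X.T @ (w[:, None] * X))
    beta = xtwx_inv @ (X.T @ (w * y))
    slope = float(beta[1])
    slope_se = float(np.sqrt(xtwx_inv[1, 1]))
    p = float(2 * stats.norm.sf(abs(slope / slope_se)))
    return slope, slope_se, max(p, 5e-324)


def stratified_analysis(
    time: np.ndarray,
    event: np.ndarray,
    score: np.ndarray,
    exposure: np.ndarray,
    covariates: pd.DataFrame | None = None,
    k: int = 10,
    beta_gx: AssocEstimate | None = None,
    refit_beta_gx: bool = False,
    se_method: str = "ratio_delta2",
    stratify_on: str = "residual_exposure",
    stratify_values: np.ndarray | None = None,
) -> StratifiedResult:
    """Full residual-stratified MR: strata, LACEs, Cochran Q and trend.

    When ``stratify_values`` is omitted, strata are quantiles of the
    residual exposure (exposure minus beta_GX * score); pass raw exposure
    explicitly to reproduce the collider-biased alternative in
    sensitivity checks.
    """
    if beta_gx is None:
        beta_gx = fit_exposure_assoc(score, exposure, covariates)
    if stratify_values is None:
        stratify_values = residualize(exposure, score, beta_gx.beta)
    labels = assign_quantile_strata(stratify_values, k)
    strata = stratum_lace(
        time, event, score, exposure, labels, covariates,
        beta_gx=beta_gx, refit_beta_gx=refit_beta_gx, se_method=se_method,
    )
    return _summarize(strata, stratify_on)


def _summarize(strata: list[StratumEstimate], stratify_on: str) -> StratifiedResult:
    if len(strata) >= 2:
        q, p_het = cochran_q(strata)
    else:
        q, p_het = np.nan, np.nan
    medians = {s.exposure_median for s in strata}
    if len(strata) >= 3 and len(medians) > 1:
        slope, slope_se, p_trend = trend_meta_regression(strata)
    else:
        slope, slope_se, p_trend = np.nan, np.nan, np.nan
    return StratifiedResult(
        strata=strata,
        q_stat=q,
        p_het=p_het,
        trend_slope=slope,
        trend_se=slope_se,
        p_trend=p_trend,
        stratify_on=stratify_on,
        n_strata=len(strata),
    )


def subgroup_analysis(
    cohort: pd.DataFrame,
    variable: str,
    score: np.ndarray,
    time_col: str = "time",
    event_col: str = "event",
    exposure_col: str = "hscrp",
    covariates: pd.DataFrame | None = None,
    k: int = 3,
    cutpoints: list[float] | None = None,
    beta_gx: AssocEstimate | None = None,
    se_method: str = "ratio_delta2",
) -> StratifiedResult:
    """MR across subgroups of a covariate (sex, age, BMI, LDL-C, ...).

    Binary variables (e.g. sex) use their natural groups.  Continuous
    variables are stratified on their *residual* values -- the variable
    minus its GRS-predicted component (from regressing the variable on
    the score) -- to avoid conditioning on an instrument descendant;
    clinical cutpoints (e.g. LDL-C >= 160 mg/dL) are applied to the raw
    variable when supplied.  Stratum "medians" are medians of the measured
    variable, so the trend test reads as a dose-response in that variable.
    """
    if variable not in cohort.columns:
        raise KeyError(
            f"unknown variable {variable!r}; available: {sorted(cohort.columns)}"
        )
    values = cohort[variable].to_numpy(dtype=float)
    time = cohort[time_col].to_numpy(dtype=float)
    event = cohort[event_col].to_numpy()
    exposure = cohort[exposure_col].to_numpy(dtype=float)
    if beta_gx is None:
        beta_gx = fit_exposure_assoc(score, exposure, covariates)
    uniq = np.unique(values)
    if len(uniq) == 1:
        raise ValueError(f"variable {variable!r} is constant")
    if len(uniq) == 2:
        labels = (values == uniq[1]).astype(int) + 1
    elif cutpoints is not None:
        labels = np.digitize(values, np.asarray(cutpoints, dtype=float)) + 1
        if len(np.unique(labels)) < 2:
            raise ValueError("cutpoints produce fewer than 2 non-empty groups")
    else:
        fitted = sm.OLS(values, sm.add_constant(score)).fit()
        residual_values = values - fitted.fittedvalues
        labels = assign_quantile_strata(residual_values, k)
    strata = stratum_lace(
        time, event, score, exposure, labels, covariates,
        beta_gx=beta_gx, se_method=se_method,
    )
    # report group positions on the measured variable's scale
    relabeled = [
        StratumEstimate(
            stratum_index=s.stratum_index,
            n=s.n,
            n_events=s.n_events,
            exposure_median=float(np.median(values[labels == s.stratum_index])),
            lace=s.lace,
            lace_se=s.lace_se,
        )
        for s in strata
    ]
    return _summarize(relabeled, stratify_on=variable)
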