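"""Fractional-polynomial synthesis of stratum-specific MR estimates.

Each stratum LACE is a local slope of the causal log-hazard curve h(x), so
the dose-response is recovered by meta-regressing the LACEs on the
*derivatives* of fractional-polynomial (FP) basis functions evaluated at
the stratum exposure medians, then integrating: with powers p from the
conventional family P = {-2, -1, -0.5, 0, 0.5, 1, 2, 3},

    f_p(x) = x^p (p != 0),   f_0(x) = ln x
    d_p(x) = p x^(p-1),      d_0(x) = 1/x

the fitted curve is h(x) = sum_j theta_j (f_pj(x) - f_pj(x_ref)), anchored
at HR(x_ref) = 1.  There is no intercept in the derivative regression: a
constant slope is exactly the power-1 basis, so an intercept would
double-count linearity.  Non-linearity is tested by comparing the
best-fitting degree-1 FP with the linear model via a chi-squared(1)
likelihood-ratio statistic; because the best power is selected on the same
data this reference is mildly anticonservative, and a seeded permutation
calibration is provided as an option.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .stratify import StratumEstimate

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class FPFit:
    """A fitted fractional-polynomial dose-response model."""

    degree: int
    powers: tuple[float, ...]
    coefficients: np.ndarray
    covariance: np.ndarray
    loglik: float

    def __post_init__(self):
        if len(self.powers) != self.degree:
            raise ValueError("number of powers must equal the degree")
        if any(p not in FP_POWERS for p in self.powers):
            raise ValueError(f"powers must come from {FP_POWERS}")


@dataclass(frozen=True)
class NonlinearityResult:
    """FP1-vs-linear comparison for one exposure scale."""

    best_fp1: FPFit
    linear_fit: FPFit
    statistic: float
    p_nonlinearity: float
    scale: str
    x_ref: float | None = None
    #: origin shift applied to ln-scale positions (0 on the absolute scale)
    position_shift: float = 0.0


def fp_basis(x: np.ndarray | float, power: float) -> np.ndarray | float:
    """Derivative d_p(x) of the FP transform (the LACE-space basis)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("FP transforms require strictly positive x")
    out = 1.0 / x if power == 0 else power * x ** (power - 1.0)
    return out if out.ndim else float(out)


def fp_transform(x: np.ndarray | float, power: float) -> np.ndarray | float:
    """The FP transform f_p(x) itself (the curve-space basis)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("FP transforms require strictly positive x")
    out = np.log(x) if power == 0 else x**power
    return out if out.ndim else float(out)


def _deriv_design(x: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    """Design matrix of FP derivatives, with the repeated-power extension.

    A repeated power p contributes the pair (x^p, x^p ln x); its
    derivative columns are (p x^(p-1), x^(p-1)(p ln x + 1)), and for p=0
    the pair (ln x, (ln x)^2) differentiates to (1/x, 2 ln x / x).
    """
    cols = []
    counts: dict[float, int] = {}
    for p in powers:
        k = counts.get(p, 0)
        if k == 0:
            cols.append(fp_basis(x, p))
        elif k == 1:
            if p == 0:
                cols.append(2.0 * np.log(x) / x)
            else:
                cols.append(x ** (p - 1.0) * (p * np.log(x) + 1.0))
        else:
            raise ValueError("powers may repeat at most once (degree <= 2)")
        counts[p] = k + 1
    return np.column_stack(cols)


def _curve_design(x: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    cols = []
    counts: dict[float, int] = {}
    for p in powers:
        k = counts.get(p, 0)
        if k == 0:
            cols.append(fp_transform(x, p))
        elif k == 1:
            cols.append(np.log(x) ** 2 if p == 0 else x**p * np.log(x))
        else:
            raise ValueError("powers may repeat at most once (degree <= 2)")
        counts[p] = k + 1
    return np.column_stack(cols)


def fit_fp(
    strata: list[StratumEstimate], powers: tuple[float, ...] | list[float]
) -> FPFit:
    """Weighted no-intercept regression of LACEs on FP derivative bases.

    Weights are 1/se_k^2; the coefficient covariance is the fixed-effect
    (X' W X)^{-1} using the known stratum standard errors, and the log
    likelihood is the Gaussian likelihood of each LACE at its fitted mean
    with its own se.
    """
    powers = tuple(float(p) for p in sorted(powers))
    degree = len(powers)
    if len(strata) <= degree:
        raise ValueError("need more strata than FP degree")
    x = np.array([s.exposure_median for s in strata])
    y = np.array([s.lace for s in strata])
    se = np.array([s.lace_se for s in strata])
    X = _deriv_design(x, powers)
    w = 1.0 / se**2
    xtwx = X.T @ (w[:, None] * X)
    if np.linalg.cond(xtwx) > 1e12:
        raise ValueError(f"singular FP basis for powers {powers} on these medians")
    cov = np.linalg.inv(xtwx)
    theta = cov @ (X.T @ (w * y))
    fitted = X @ theta
    loglik = float(np.sum(stats.norm.logpdf(y, loc=fitted, scale=se)))
    return FPFit(
        degree=degree, powers=powers, coefficients=theta, covariance=cov,
        loglik=loglik,
    )


def _candidate_powers(degree: int) -> list[tuple[float, ...]]:
    """All power multisets of the given degree, linear-preferred order."""
    cands = [
        tuple(sorted(c))
        for c in itertools.combinations_with_replacement(FP_POWERS, degree)
    ]
    linear = tuple([1.0] * degree)
    cands.sort(key=lambda c: (c != linear, c))
    return cands


def select_best_fp(strata: list[StratumEstimate], degree: int = 1) -> FPFit:
    """Exhaustive maximum-likelihood search over FP power sets.

    8 candidates for degree 1, 36 for degree 2.  Ties (within 1e-9 log
    likelihood) are broken toward the all-linear power set, then
    lexicographically.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    best: FPFit | None = None
    for powers in _candidate_powers(degree):
        try:
            fit = fit_fp(strata, powers)
        except ValueError:
            continue
        if best is None or fit.loglik > best.loglik + 1e-9:
            best = fit
    if best is None:
        raise ValueError("no fractional-polynomial model could be fitted")
    return best


def _ln_scale_strata(
    strata: list[StratumEstimate],
) -> tuple[list[StratumEstimate], float]:
    """Chain-rule transform of stratum estimates to the ln-exposure scale.

    A LACE per 1 mg/dL at median m corresponds to m * LACE per 1 unit of
    ln-exposure; positions become ln(m), shifted to a positive origin when
    necessary (FP transforms need x > 0; the shift is the standard FP
    origin convention and does not affect the linear basis, whose
    derivative is constant).
    """
    m = np.array([s.exposure_median for s in strata])
    u = np.log(m)
    shift = 1.0 - u.min() if u.min() <= 0 else 0.0
    return ([
        StratumEstimate(
            stratum_index=s.stratum_index,
            n=s.n,
            n_events=s.n_events,
            exposure_median=float(np.log(s.exposure_median) + shift),
            lace=s.lace * s.exposure_median,
            lace_se=s.lace_se * s.exposure_median,
        )
        for s in strata
    ], shift)


def test_nonlinearity(
    strata: list[StratumEstimate],
    scale: str = "absolute",
    n_permutations: int = 0,
    seed: int = 0,
    x_ref: float | None = None,
) -> NonlinearityResult:
    """Likelihood-ratio test of the best degree-1 FP against linear.

    statistic = 2 (loglik(best FP1) - loglik(linear)); p from
    chi-squared(1), or from a seeded permutation of the LACE-to-median
    pairing when ``n_permutations`` > 0.  On the "ln" scale the stratum
    estimates are first chain-rule transformed to ln-exposure units.
    """
    if scale not in ("absolute", "ln"):
        raise ValueError("scale must be 'absolute' or 'ln'")
    if len(strata) < 3:
        raise ValueError("non-linearity test needs at least 3 strata")
    if scale == "ln":
        work, shift = _ln_scale_strata(strata)
    else:
        work, shift = strata, 0.0
    linear = fit_fp(work, (1.0,))
    best = select_best_fp(work, degree=1)
    statistic = max(0.0, 2.0 * (best.loglik - linear.loglik))
    if best.powers == (1.0,):
        p = 1.0
    elif n_permutations > 0:
        p = _permutation_p(work, statistic, n_permutations, seed)
    else:
        p = float(stats.chi2.sf(statistic, df=1))
    return NonlinearityResult(
        best_fp1=best,
        linear_fit=linear,
        statistic=statistic,
        p_nonlinearity=min(max(p, 5e-324), 1.0),
        scale=scale,
        x_ref=x_ref,
        position_shift=shift,
    )


def fp_ladder_test(
    strata: list[StratumEstimate], scale: str = "absolute"
) -> dict:
    """Degree ladder: best FP2 vs best FP1 vs linear.

    An alternative to the default FP1-vs-linear comparison: returns the
    likelihood-ratio p-values for each rung (chi-squared with 1 df for
    FP1 vs linear, 2 df for FP2 vs FP1, reflecting the extra coefficient
    and selected power).  Subject to the same selection caveat as the
    default test.
    """
    if scale == "ln":
        work, _ = _ln_scale_strata(strata)
    else:
        work = strata
    linear = fit_fp(work, (1.0,))
    best1 = select_best_fp(work, degree=1)
    best2 = select_best_fp(work, degree=2)
    s1 = max(0.0, 2.0 * (best1.loglik - linear.loglik))
    s2 = max(0.0, 2.0 * (best2.loglik - best1.loglik))
    return {
        "p_fp1_vs_linear": float(stats.chi2.sf(s1, df=1)) if best1.powers != (1.0,) else 1.0,
        "p_fp2_vs_fp1": float(stats.chi2.sf(s2, df=2)),
        "best_fp1": best1,
        "best_fp2": best2,
        "scale": scale,
    }


def _permutation_p(
    strata: list[StratumEstimate], observed: float, n_perm: int, seed: int
) -> float:
    rng = np.random.default_rng(seed)
    medians = np.array([s.exposure_median for s in strata])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(strata))
        shuffled = [
            StratumEstimate(
                stratum_index=i + 1,
                n=strata[j].n,
                n_events=strata[j].n_events,
                exposure_median=float(medians[i]),
                lace=strata[j].lace,
                lace_se=strata[j].lace_se,
            )
            for i, j in enumerate(perm)
        ]
        linear = fit_fp(shuffled, (1.0,))
        best = select_best_fp(shuffled, degree=1)
        if 2.0 * (best.loglik - linear.loglik) >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)


def reconstruct_curve(
    fit: FPFit, x_grid: np.ndarray, x_ref: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Causal HR curve against a reference exposure, with pointwise CI.

    HR(x) = exp(sum_j theta_j (f_pj(x) - f_pj(x_ref))); the delta-method
    variance uses the coefficient covariance, so HR(x_ref) = 1 with a
    degenerate [1, 1] interval exactly at the reference.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if np.any(x_grid <= 0) or x_ref <= 0:
        raise ValueError("exposure grid and reference must be positive")
    G = _curve_design(x_grid, fit.powers) - _curve_design(
        np.array([x_ref]), fit.powers
    )
    h = G @ fit.coefficients
    var = np.einsum("ij,jk,ik->i", G, fit.covariance, G)
    sd = np.sqrt(np.maximum(var, 0.0))
    z = 1.959963984540054
    return np.exp(h), np.exp(h - z * sd), np.exp(h + z * sd)


def curve_in_exposure_units(
    fit: FPFit,
    x_grid: np.ndarray,
    x_ref: float,
    scale: str = "absolute",
    position_shift: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reconstruct a curve on an mg/dL grid regardless of analysis scale.

    For an ln-scale fit the grid and reference are mapped to the shifted
    log positions the fit was estimated on before anchoring.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if scale == "ln":
        return reconstruct_curve(
            fit, np.log(x_grid) + position_shift, math.log(x_ref) + position_shift
        )
    return reconstruct_curve(fit, x_grid, x_ref)
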