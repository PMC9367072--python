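"""Instrument-outcome association and the ratio-of-coefficients MR estimate.

The instrument-outcome association beta_GY is the log-hazard per unit GRS
from a covariate-adjusted Cox proportional-hazards model (Efron tie
handling).  The causal estimate is the Wald ratio beta_IV = beta_GY /
beta_GX, a log-hazard ratio per 1 mg/dL of exposure when the score is in
exposure units.  Standard errors come from first- or second-order delta
expansions, or a Fieller interval for weak instruments; the covariance
between the two stage estimates (one-sample overlap) is set to zero, which
is the usual practice and is logged as an assumption.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .grs import AssocEstimate

logger = logging.getLogger(__name__)

Z95 = float(stats.norm.ppf(0.975))

SE_METHODS = ("ratio_delta1", "ratio_delta2", "fieller")

#: |beta_GX| / se_GX below which a weak-instrument warning is emitted.
WEAK_INSTRUMENT_Z = 2.0


@dataclass(frozen=True)
class MREstimate:
    """A ratio-of-coefficients MR estimate on the log-hazard scale."""

    beta_iv: float
    se_iv: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    n: int
    n_events: int

    def __post_init__(self):
        if self.method not in SE_METHODS:
            raise ValueError(f"unknown se method {self.method!r}")


def fit_outcome_assoc(
    score: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    covariates: pd.DataFrame | None = None,
    outcome_label: str = "outcome",
) -> AssocEstimate:
    """Cox partial-likelihood estimate of the log-hazard per unit score.

    Ties are handled with the Efron approximation.  Raises if there are
    no events; warns below 10 events (the asymptotics are then fragile).
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events: the outcome association is not estimable")
    if n_events < 10:
        logger.warning("only %d events; Cox estimate may be unstable", n_events)
    cols = [score]
    if covariates is not None and covariates.shape[1] > 0:
        cols += [covariates[c].to_numpy(dtype=float) for c in covariates.columns]
    exog = np.column_stack(cols)
    model = PHReg(time, exog, status=event.astype(int), ties="efron")
    try:
        res = model.fit(disp=0)
    except Exception as exc:  # non-convergence surfaces with context
        raise RuntimeError(f"Cox fit failed for {outcome_label}: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise RuntimeError(f"Cox fit did not converge for {outcome_label}")
    return AssocEstimate(
        beta=float(res.params[0]),
        se=float(res.bse[0]),
        n=len(time),
        model="proportional_hazards",
        outcome_label=outcome_label,
        n_events=n_events,
    )


def ratio_estimate(
    beta_gy: AssocEstimate,
    beta_gx: AssocEstimate,
    method: str = "ratio_delta2",
) -> MREstimate:
    """Wald ratio beta_GY / beta_GX with a delta-method or Fieller interval.

    Methods
    -------
    ratio_delta1
        First-order delta: se = se_GY / |beta_GX| (ignores first-stage
        uncertainty).
    ratio_delta2
        Second-order delta: adds the beta_GY^2 se_GX^2 / beta_GX^4 term.
    fieller
        Fieller's theorem interval; exact under joint normality, may be
        unbounded for weak instruments (reported as +/- inf).
    """
    if method not in SE_METHODS:
        raise ValueError(f"method must be one of {SE_METHODS}")
    by, sy = beta_gy.beta, beta_gy.se
    bx, sx = beta_gx.beta, beta_gx.se
    if not all(map(math.isfinite, (by, sy, bx, sx))):
        raise ValueError("non-finite association estimates")
    if bx == 0:
        raise ValueError("instrument-exposure association is zero; ratio undefined")
    if sx > 0 and abs(bx) / sx < WEAK_INSTRUMENT_Z:
        logger.warning(
            "weak instrument: |beta_GX|/se_GX = %.2f < %.1f", abs(bx) / sx,
            WEAK_INSTRUMENT_Z,
        )
    logger.debug("one-sample cov(beta_GY, beta_GX) assumed 0")
    beta_iv = by / bx
    se1 = sy / abs(bx)
    se2 = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    if method == "ratio_delta1":
        se_iv = se1
        lo, hi = beta_iv - Z95 * se_iv, beta_iv + Z95 * se_iv
    elif method == "ratio_delta2":
        se_iv = se2
        lo, hi = beta_iv - Z95 * se_iv, beta_iv + Z95 * se_iv
    else:
        lo, hi = _fieller_interval(by, sy, bx, sx)
        se_iv = (hi - lo) / (2 * Z95) if math.isfinite(lo) and math.isfinite(hi) else se2
    z = beta_iv / se_iv if se_iv > 0 else math.inf * np.sign(beta_iv)
    p = float(2 * stats.norm.sf(abs(z))) if se_iv > 0 else (1.0 if beta_iv == 0 else 0.0)
    p = min(max(p, 5e-324), 1.0)
    n_events = beta_gy.n_events if beta_gy.n_events is not None else 0
    return MREstimate(
        beta_iv=beta_iv,
        se_iv=se_iv,
        hr=math.exp(beta_iv),
        ci_low=math.exp(lo),
        ci_high=math.exp(hi),
        p=p,
        method=method,
        n=beta_gy.n,
        n_events=n_events,
    )


def _fieller_interval(by, sy, bx, sx) -> tuple[float, float]:
    """Fieller CI for by/bx assuming independent normal estimates."""
    z2 = Z95**2
    a = bx**2 - z2 * sx**2
    b = -2 * by * bx
    c = by**2 - z2 * sy**2
    if a <= 0:
        logger.warning("Fieller interval is unbounded (weak instrument)")
        return -math.inf, math.inf
    disc = b**2 - 4 * a * c
    if disc < 0:  # pragma: no cover - cannot occur when a > 0
        return -math.inf, math.inf
    r = math.sqrt(disc)
    return (-b - r) / (2 * a), (-b + r) / (2 * a)


def _round_half_up(value: float, digits: int) -> str:
    q = Decimal(1).scaleb(-digits)
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_estimate(mr: MREstimate, digits: int = 2) -> str:
    """Render as ``"HR (CI_low-CI_high)"`` with round-half-up."""
    fmt = lambda v: _round_half_up(v, digits) if math.isfinite(v) else "inf"
    return f"{fmt(mr.hr)} ({fmt(mr.ci_low)}–{fmt(mr.ci_high)})"
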