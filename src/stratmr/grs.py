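"""Weighted genetic risk score construction and the instrument-exposure fit.

A genetic risk score (GRS) collapses a set of variants at a locus into a
single instrument: score_i = sum_j w_j * d_ij, with per-allele weights w_j
taken from an external GWAS so the score is expressed in exposure units
(mg/dL hsCRP).  This module reads weight tables, harmonizes them against a
dosage matrix's allele annotations, optionally clumps by linkage
disequilibrium, computes the score, and estimates the instrument-exposure
association beta_GX by covariate-adjusted least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}

WEIGHT_COLUMNS = ("variant_id", "effect_allele", "other_allele", "weight", "weight_se")


@dataclass(frozen=True)
class VariantWeight:
    """One instrument variant with its per-allele exposure weight."""

    variant_id: str
    effect_allele: str
    other_allele: str
    weight: float
    weight_se: float
    position: int | None = None

    def __post_init__(self):
        if self.effect_allele not in _VALID_ALLELES:
            raise ValueError(
                f"{self.variant_id}: invalid effect allele {self.effect_allele!r}"
            )
        if self.other_allele not in _VALID_ALLELES:
            raise ValueError(
                f"{self.variant_id}: invalid other allele {self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not np.isfinite(self.weight):
            raise ValueError(f"{self.variant_id}: non-finite weight")

    @property
    def is_palindromic(self) -> bool:
        return frozenset({self.effect_allele, self.other_allele}) in _PALINDROMIC


@dataclass(frozen=True)
class GRSVector:
    """Per-individual score (exposure units) and the variant count used."""

    score: np.ndarray
    n_variants_used: int


@dataclass(frozen=True)
class AssocEstimate:
    """A (beta, se, n) triple from a fitted association model."""

    beta: float
    se: float
    n: int
    model: str  # "linear" or "proportional_hazards"
    outcome_label: str = ""
    n_events: int | None = None

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be non-negative")


def read_weights(path) -> list[VariantWeight]:
    """Read a tab-separated variant-weight table.

    Expected header: variant_id, effect_allele, other_allele, weight,
    weight_se and optionally position.  Duplicated variant ids are an
    error; an empty table (header only) is allowed with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weight table {path} missing columns: {missing}")
    if df.empty:
        logger.warning("weight table %s is empty", path)
        return []
    dup = df["variant_id"][df["variant_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicated variant ids in weight table: {sorted(set(dup))}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                VariantWeight(
                    variant_id=row["variant_id"],
                    effect_allele=str(row["effect_allele"]).upper(),
                    other_allele=str(row["other_allele"]).upper(),
                    weight=float(row["weight"]),
                    weight_se=float(row["weight_se"]),
                    position=int(row["position"]) if "position" in df.columns else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"weight table row {i + 2} ({path}): {exc}") from exc
    return out


def harmonize(
    weights: list[VariantWeight],
    dosage_variants: list[str],
    counted_alleles: dict[str, tuple[str, str]],
    dosages: np.ndarray,
    drop_palindromic: bool = True,
) -> tuple[list[VariantWeight], np.ndarray]:
    """Align a dosage matrix to the weight table's effect alleles.

    ``counted_alleles`` maps variant id -> (counted allele, other allele)
    as annotated in the dosage source.  When the counted allele is the
    weight's *other* allele, the dosage column is flipped (d -> 2 - d) so
    every retained column counts the effect allele.  Palindromic (A/T or
    C/G) variants and variants absent from either source are dropped with
    a logged count.  Raises if no variants remain.

    Returns the retained weights and the aligned dosage matrix (columns in
    retained-weight order).  Idempotent: harmonizing already-harmonized
    output is the identity.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.shape[1] != len(dosage_variants):
        raise ValueError("dosage matrix width does not match variant list")
    col_of = {v: j for j, v in enumerate(dosage_variants)}
    kept: list[VariantWeight] = []
    cols: list[np.ndarray] = []
    n_pal = n_unmatched = n_flip = n_mismatch = 0
    for w in weights:
        if w.variant_id not in col_of:
            n_unmatched += 1
            continue
        if drop_palindromic and w.is_palindromic:
            n_pal += 1
            continue
        counted, other = counted_alleles[w.variant_id]
        counted, other = counted.upper(), other.upper()
        col = dosages[:, col_of[w.variant_id]]
        if counted == w.effect_allele and other == w.other_allele:
            pass
        elif counted == w.other_allele and other == w.effect_allele:
            col = 2.0 - col
            n_flip += 1
        else:
            n_mismatch += 1
            continue
        kept.append(w)
        cols.append(col)
    if n_pal:
        logger.info("harmonize: dropped %d palindromic variants", n_pal)
    if n_unmatched:
        logger.info("harmonize: dropped %d unmatched variants", n_unmatched)
    if n_mismatch:
        logger.info("harmonize: dropped %d allele-mismatched variants", n_mismatch)
    if n_flip:
        logger.info("harmonize: flipped dosage for %d variants", n_flip)
    if not kept:
        raise ValueError("no variants remain after harmonization")
    return kept, np.column_stack(cols)


def clump_by_ld(
    weights: list[VariantWeight], ld_matrix: np.ndarray, threshold: float = 0.1
) -> list[VariantWeight]:
    """Greedy LD clumping at pairwise r^2 < threshold.

    Candidates are visited in descending |weight / weight_se| order; a
    variant is retained iff its r^2 with every already-retained variant is
    below the threshold.  The LD matrix must be symmetric with unit
    diagonal and aligned to ``weights``.
    """
    r2 = np.asarray(ld_matrix, dtype=float)
    m = len(weights)
    if r2.shape != (m, m):
        raise ValueError("LD matrix shape does not match weight list")
    if not np.allclose(r2, r2.T, atol=1e-8):
        raise ValueError("LD matrix is not symmetric")
    if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
        raise ValueError("LD matrix diagonal must be 1")
    z = np.array(
        [abs(w.weight) / w.weight_se if w.weight_se > 0 else np.inf for w in weights]
    )
    order = np.argsort(-z, kind="stable")
    retained: list[int] = []
    for j in order:
        if all(r2[j, k] < threshold for k in retained):
            retained.append(j)
    retained.sort()
    return [weights[j] for j in retained]


def compute_score(
    dosages: np.ndarray, weights: list[VariantWeight]
) -> GRSVector:
    """Weighted allele count: score_i = sum_j w_j d_ij.

    Dosages must already be harmonized and column-aligned to ``weights``.
    Missing dosages (NaN) are mean-imputed per variant, keeping n constant.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2 or d.shape[1] != len(weights):
        raise ValueError(
            f"dosage matrix has {d.shape[1] if d.ndim == 2 else '?'} columns "
            f"but {len(weights)} weights supplied"
        )
    if np.isnan(d).any():
        col_means = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d = d.copy()
        d[idx] = np.take(col_means, idx[1])
    w = np.array([vw.weight for vw in weights])
    return GRSVector(score=d @ w, n_variants_used=len(weights))


def fit_exposure_assoc(
    score: np.ndarray,
    exposure: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> AssocEstimate:
    """OLS of exposure on the score with covariate adjustment (beta_GX).

    Raises on rank deficiency, naming the collinear columns.  A perfect
    fit (zero residual variance) is reported with se 0 and a warning.
    """
    score = np.asarray(score, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if not np.all(np.isfinite(exposure)):
        raise ValueError("exposure contains non-finite values")
    names = ["score"]
    cols = [score]
    if covariates is not None and covariates.shape[1] > 0:
        names += list(covariates.columns)
        cols += [covariates[c].to_numpy(dtype=float) for c in covariates.columns]
    X = np.column_stack(cols)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        bad = _collinear_columns(Xc, ["const"] + names)
        raise ValueError(f"design matrix is rank deficient; collinear: {bad}")
    if len(exposure) <= Xc.shape[1]:
        raise ValueError("fewer observations than model parameters")
    res = sm.OLS(exposure, Xc).fit()
    se = float(res.bse[1])
    if res.ssr < 1e-12 * max(1.0, float(np.sum(exposure**2))):
        logger.warning("exposure is an exact function of the design; se set to 0")
        se = 0.0
    return AssocEstimate(
        beta=float(res.params[1]),
        se=se,
        n=len(exposure),
        model="linear",
        outcome_label="exposure",
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Identify columns not independent of those before them (QR sweep)."""
    bad = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        if np.linalg.matrix_rank(cand) <= len(kept):
            bad.append(names[j])
        else:
            kept.append(j)
    return bad
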