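"""File formats: phenotype tables, dosage matrices, weight tables, results.

Plain-text formats only: phenotype and dosage tables are tab-separated
(comma accepted for ``.csv`` phenotypes), variant weights are
tab-separated, and dosages may alternatively come from a minimal VCF
(dosage = ALT allele count from the GT field).  Floats are written with 12
significant digits so a write/read round trip is exact at that precision
and repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"

PHENOTYPE_REQUIRED = ("id", "hscrp", "time", "event")

#: Non-palindromic allele pairs cycled for simulated variants.
_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


def read_phenotypes(path, covariate_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a phenotype table (TSV, or CSV for a ``.csv`` extension).

    Mandatory columns: id, hscrp, time, event.  Rows with missing
    exposure/time/event or non-positive time are dropped with a logged
    count; an event value outside {0, 1} is a parse error naming the row.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"id": str})
    for col in PHENOTYPE_REQUIRED + tuple(covariate_columns):
        if col not in df.columns:
            raise ValueError(f"phenotype file {path} missing column {col!r}")
    n0 = len(df)
    df = df.dropna(subset=["hscrp", "time", "event"])
    bad_event = df.index[~df["event"].isin((0, 1))]
    if len(bad_event):
        raise ValueError(
            f"event not in {{0,1}} at row {bad_event[0] + 2} of {path}"
        )
    nonpos = df["time"] <= 0
    if nonpos.any():
        logger.warning("dropping %d rows with non-positive time", int(nonpos.sum()))
        df = df[~nonpos]
    if len(df) < n0:
        logger.info("phenotypes: kept %d of %d rows", len(df), n0)
    logger.info("phenotypes: %d individuals read from %s", len(df), path)
    return df.reset_index(drop=True)


def read_dosages_table(path) -> tuple[list[str], np.ndarray, list[str], dict]:
    """Read a tab-separated dosage matrix (rows = individuals).

    The first column is ``id``; each remaining column is named
    ``<variant>_<counted>_<other>`` (e.g. ``rs4129267_C_T``), declaring
    the counted allele so harmonization can flip where needed.  Returns
    ``(ids, matrix, variant_ids, counted_alleles)`` with missing dosages
    as NaN.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"dosage file {path} missing 'id' column")
    variant_ids, counted = [], {}
    for col in df.columns.drop("id"):
        parts = col.rsplit("_", 2)
        if len(parts) != 3:
            raise ValueError(
                f"dosage column {col!r} is not <variant>_<counted>_<other>"
            )
        vid, a1, a2 = parts
        variant_ids.append(vid)
        counted[vid] = (a1.upper(), a2.upper())
    matrix = df.drop(columns="id").to_numpy(dtype=float)
    finite = matrix[np.isfinite(matrix)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise ValueError("dosages must lie in [0, 2]")
    return df["id"].tolist(), matrix, variant_ids, counted


def read_dosages_vcf(path) -> tuple[list[str], np.ndarray, list[str], dict]:
    """Read genotype dosages from a minimal VCF (counted allele = ALT).

    Dosage is the ALT allele count per GT; missing genotypes become NaN
    (mean-imputed downstream); multi-allelic records are skipped with a
    logged count.  Sample order is preserved.
    """
    from cyvcf2 import VCF  # deferred: only the VCF path needs it

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variant_ids, counted, cols = [], {}, []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gts = np.array(v.genotypes, dtype=object)
        dose = np.empty(len(samples))
        for i, g in enumerate(gts):
            alleles = [a for a in g[:-1]]
            dose[i] = np.nan if -1 in alleles else float(sum(a == 1 for a in alleles))
        vid = v.ID if v.ID else f"{v.CHROM}:{v.POS}"
        variant_ids.append(vid)
        counted[vid] = (v.ALT[0].upper(), v.REF.upper())
        cols.append(dose)
    if n_multi:
        logger.warning("skipped %d multi-allelic records", n_multi)
    if not cols:
        raise ValueError(f"no usable bi-allelic records in {path}")
    return samples, np.column_stack(cols), variant_ids, counted


def simulated_variant_ids(n_variants: int) -> list[str]:
    return [f"sim_v{j + 1:02d}" for j in range(n_variants)]


def simulated_alleles(n_variants: int) -> list[tuple[str, str]]:
    """Deterministic non-palindromic (effect, other) pairs for fixtures."""
    return [_ALLELE_CYCLE[j % len(_ALLELE_CYCLE)] for j in range(n_variants)]


def write_cohort_files(table: pd.DataFrame, config, outdir) -> dict[str, Path]:
    """Write a simulated cohort as phenotype + dosage + weight files.

    Produces ``phenotypes.tsv`` (analysis variables; the latent confounder
    is deliberately omitted, as it would be unobserved in real data),
    ``dosages.tsv`` (counted allele = effect allele), ``weights.tsv`` and
    ``config.yaml``.  Returns the paths keyed by role.
    """
    from .simulate import dosage_columns  # local import avoids a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dos_cols = dosage_columns(table)
    alleles = simulated_alleles(len(dos_cols))
    vids = simulated_variant_ids(len(dos_cols))

    pheno_cols = [
        "id", "age", "sex", "bmi", "ldl", "sbp", "egfr", "hba1c",
        "hscrp", "time", "event", "event_type", "kinship_flag",
    ]
    paths = {}
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    table[pheno_cols].to_csv(
        paths["phenotypes"], sep="\t", index=False, float_format=FLOAT_FORMAT
    )

    dos = table[dos_cols].copy()
    dos.columns = [
        f"{vid}_{ea}_{oa}" for vid, (ea, oa) in zip(vids, alleles)
    ]
    dos.insert(0, "id", table["id"])
    paths["dosages"] = outdir / "dosages.tsv"
    dos.to_csv(paths["dosages"], sep="\t", index=False, float_format=FLOAT_FORMAT)

    weights = pd.DataFrame(
        {
            "variant_id": vids,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "weight": np.asarray(config.variant_weights, dtype=float),
            "weight_se": np.full(len(vids), 0.005),
        }
    )
    paths["weights"] = outdir / "weights.tsv"
    weights.to_csv(paths["weights"], sep="\t", index=False, float_format=FLOAT_FORMAT)

    cfg = {
        "n_individuals": int(config.n_individuals),
        "n_variants": int(config.n_variants),
        "exposure_median": float(config.exposure_median),
        "exposure_log_sd": float(config.exposure_log_sd),
        "confounder_effect": float(config.confounder_effect),
        "causal_function": config.causal_function,
        "theta": float(config.theta),
        "baseline_hazard": float(config.baseline_hazard),
        "followup_years": float(config.followup_years),
        "censor_rate": float(config.censor_rate),
        "seed": int(config.seed),
    }
    paths["config"] = outdir / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


def write_estimates(estimates: list[dict], path) -> None:
    """Write MR estimates as a tab-separated table."""
    cols = [
        "outcome_label", "method", "beta_iv", "se_iv", "hr",
        "ci_low", "ci_high", "p", "n", "n_events",
    ]
    pd.DataFrame(estimates)[cols].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def write_stratified(result, path) -> None:
    """Write a stratified result: per-stratum rows plus a summary row."""
    df = result.to_frame()
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)
        fh.write(
            "# Q=%s\tp_het=%s\ttrend_slope=%s\ttrend_se=%s\tp_trend=%s\n"
            % tuple(
                FLOAT_FORMAT % v
                for v in (
                    result.q_stat, result.p_het, result.trend_slope,
                    result.trend_se, result.p_trend,
                )
            )
        )


def write_curve(x, hr, lo, hi, path) -> None:
    pd.DataFrame({"x": x, "hr": hr, "ci_low": lo, "ci_high": hi}).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )
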