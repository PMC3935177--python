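"""Readers, writers and data-preparation utilities.

Input files are plain TSV with a header row and sample identifiers in the
first column: a genotype matrix (values 0/1/2 or ``NA``), an expression
matrix (reals) and a one-column phenotype table.  The three inputs are
aligned on their shared sample set (an inner join; dropped samples are
logged).

Data preparation mirrors a typical eQTL pipeline: SNP filtering on
missingness and minor-allele frequency, a log-dose area-under-the-curve
summary of cytotoxicity dose-response assays as the phenotype, and
within-subject linear-regression imputation of missing viability readings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponse",
    "read_genotypes",
    "read_expression",
    "read_phenotype",
    "read_inputs",
    "write_results",
    "filter_snps",
    "auc_log_dose",
    "impute_missing_dose",
]

GENOTYPE_CODES = (0, 1, 2)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    dup = df.columns[df.columns.duplicated()].tolist()
    if dup:
        logger.warning("%s: duplicate column identifiers %s", path, dup)
    return df


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Samples x SNPs matrix of genotype codes 0/1/2 with NA for missing.

    Any other cell value is a parse error naming the offending cell.
    """
    df = _read_tsv(path)
    arr = df.to_numpy(dtype=float)
    bad = ~(np.isnan(arr) | np.isin(arr, GENOTYPE_CODES))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid genotype value {df.iat[r, c]!r} at sample "
            f"{df.index[r]!r}, SNP {df.columns[c]!r} (expected 0/1/2/NA)"
        )
    return df.astype(float)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Samples x transcripts matrix of real expression values."""
    df = _read_tsv(path)
    try:
        return df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from exc


def read_phenotype(path: str | Path) -> pd.Series:
    """One real phenotype value per sample (single-column TSV)."""
    df = _read_tsv(path)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: phenotype file must have exactly one column")
    try:
        return df.iloc[:, 0].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric phenotype cell ({exc})") from exc


def read_inputs(
    genotype_path: str | Path,
    expression_path: str | Path,
    phenotype_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Read and align the three inputs on their shared sample set."""
    g = read_genotypes(genotype_path)
    e = read_expression(expression_path)
    d = read_phenotype(phenotype_path)
    common = g.index.intersection(e.index).intersection(d.index)
    if len(common) == 0:
        raise ValueError("the three inputs share no sample identifiers")
    total = len(set(g.index) | set(e.index) | set(d.index))
    if total > len(common):
        logger.info(
            "aligned on %d shared samples (%d dropped)",
            len(common), total - len(common),
        )
    return g.loc[common], e.loc[common], d.loc[common]


def write_results(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write each named table as ``<outdir>/<name>.tsv``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, table in tables.items():
        p = outdir / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------

def filter_snps(
    genotypes: pd.DataFrame,
    max_missing: float = 0.3,
    min_maf: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop SNPs with missingness > *max_missing* or MAF < *min_maf*.

    The minor-allele frequency is computed from allele counts over
    non-missing genotypes: freq = (2*n_hom + n_het) / (2*n_nonmissing) for
    the allele counted by the 0/1/2 coding, minored against its complement.
    Both rules are strict inequalities, so a SNP sitting exactly on a
    threshold is retained.  Returns the filtered matrix and a removal
    report (snp, missing_fraction, maf, reason).
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    arr = genotypes.to_numpy(dtype=float)
    n_missing = np.isnan(arr).sum(axis=0)
    n_obs = len(genotypes) - n_missing
    miss_frac = n_missing / len(genotypes)
    with np.errstate(invalid="ignore"):
        allele_freq = np.nansum(arr, axis=0) / (2 * np.maximum(n_obs, 1))
    maf = np.minimum(allele_freq, 1.0 - allele_freq)
    maf = np.where(n_obs == 0, 0.0, maf)

    records = []
    keep = []
    for j, snp_name in enumerate(genotypes.columns):
        reasons = []
        if miss_frac[j] > max_missing:
            reasons.append("missingness")
        if maf[j] < min_maf:
            reasons.append("maf")
        if reasons:
            records.append(
                {
                    "snp": snp_name,
                    "missing_fraction": miss_frac[j],
                    "maf": maf[j],
                    "reason": "+".join(reasons),
                }
            )
        else:
            keep.append(snp_name)
    report = pd.DataFrame(
        records, columns=["snp", "missing_fraction", "maf", "reason"]
    )
    return genotypes[keep], report


# ---------------------------------------------------------------------------
# Dose-response phenotype
# ---------------------------------------------------------------------------

@dataclass
class DoseResponse:
    """Cell-viability percentages of one subject across a dose grid.

    Doses must be strictly increasing and positive; viability values are
    percentages (guard range [0, 200]; NaN marks a missing reading).
    """

    subject: str
    doses: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.doses.ndim != 1 or self.doses.shape != self.viability.shape:
            raise ValueError("doses and viability must be equal-length 1-D")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive (log-dose axis)")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        finite = self.viability[~np.isnan(self.viability)]
        if np.any((finite < 0) | (finite > 200)):
            raise ValueError("viability outside the [0, 200] guard range")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.viability).sum())


def auc_log_dose(dr: DoseResponse) -> float:
    """Area under the viability curve against natural-log dose.

    Trapezoidal quadrature on the ln(dose) axis over the observed range; a
    large area indicates strong chemo-resistance.  Missing viability values
    must be imputed first (:func:`impute_missing_dose`).
    """
    if dr.n_missing:
        raise ValueError(
            f"subject {dr.subject!r} has {dr.n_missing} missing viability "
            "values; impute with impute_missing_dose first"
        )
    if len(dr.doses) < 2:
        raise ValueError("AUC needs at least two doses")
    return float(np.trapezoid(dr.viability, np.log(dr.doses)))


def impute_missing_dose(dr: DoseResponse, log_dose: bool = True) -> DoseResponse:
    """Fill missing viability readings by within-subject linear regression.

    An ordinary least-squares line of viability on ln(dose) (or on the raw
    dose with ``log_dose=False``) is fitted to the subject's non-missing
    readings and evaluated at the missing doses; observed values are
    untouched.  At least two non-missing readings are required.  The log
    axis is the default because it matches the AUC summary.
    """
    miss = np.isnan(dr.viability)
    if not miss.any():
        return dr
    if (~miss).sum() < 2:
        raise ValueError(
            f"subject {dr.subject!r}: fewer than 2 observed readings; "
            "cannot impute"
        )
    x = np.log(dr.doses) if log_dose else dr.doses
    slope, intercept = np.polyfit(x[~miss], dr.viability[~miss], 1)
    filled = dr.viability.copy()
    filled[miss] = np.clip(slope * x[miss] + intercept, 0.0, 200.0)
    return DoseResponse(dr.subject, dr.doses.copy(), filled)
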