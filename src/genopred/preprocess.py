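"""SNP/sample quality control, missing-genotype imputation and fixed-effect
adjustment of phenotypes.

Filter order is fixed: marker filters (call rate, MAF, Hardy-Weinberg) on the
raw calls, then the sample missingness filter, then mean imputation. All
threshold comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AdjustedPhenotype, GenotypeMatrix
from .exceptions import (
    EmptyPanelError,
    InvalidParameterError,
    RankDeficientDesignError,
)

__all__ = [
    "QCThresholds",
    "hwe_pvalue",
    "marker_qc_table",
    "filter_markers",
    "filter_samples",
    "impute_missing",
    "run_qc",
    "adjust_phenotype",
]


@dataclass(frozen=True)
class QCThresholds:
    """Strict ("higher than" / "more than") QC cutoffs."""

    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_p_floor: float = 1e-5
    max_sample_missing: float = 0.10

    def __post_init__(self):
        for name in ("min_call_rate", "min_maf", "hwe_p_floor", "max_sample_missing"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")


def hwe_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg equilibrium p-value: 1-df Pearson chi-square against the
    proportions expected at the observed allele frequency.

    Monomorphic markers return 1.0 by convention.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise InvalidParameterError("genotype counts must be nonnegative")
    n = counts.sum()
    if n < 1:
        raise InvalidParameterError("need at least one called genotype")
    p = (2 * counts[0] + counts[1]) / (2 * n)  # frequency of the A allele
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def marker_qc_table(g: GenotypeMatrix, t: QCThresholds) -> pd.DataFrame:
    """Per-marker call rate, MAF, HWE p-value and pass/fail verdict."""
    vals = g.values
    n = g.n_individuals
    called = ~np.isnan(vals)
    n_called = called.sum(axis=0)
    call_rate = n_called / n

    n_AA = np.nansum(vals == 1.0, axis=0).astype(float)
    n_Aa = np.nansum(vals == 0.0, axis=0).astype(float)
    n_aa = np.nansum(vals == -1.0, axis=0).astype(float)

    maf = np.full(g.n_markers, np.nan)
    hwe_p = np.full(g.n_markers, np.nan)
    for j in range(g.n_markers):
        if n_called[j] == 0:
            continue
        # both frequencies from counts so boundary MAFs are exact in floating point
        p = (2 * n_AA[j] + n_Aa[j]) / (2 * n_called[j])
        q = (2 * n_aa[j] + n_Aa[j]) / (2 * n_called[j])
        maf[j] = min(p, q)
        hwe_p[j] = hwe_pvalue(int(n_AA[j]), int(n_Aa[j]), int(n_aa[j]))

    fail_cr = ~(call_rate > t.min_call_rate)
    fail_maf = ~(maf > t.min_maf)
    fail_hwe = ~(hwe_p > t.hwe_p_floor)
    keep = ~(fail_cr | fail_maf | fail_hwe)

    reason = np.where(
        fail_cr, "call_rate", np.where(fail_maf, "maf", np.where(fail_hwe, "hwe", ""))
    )
    return pd.DataFrame(
        {
            "marker_id": g.marker_ids,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "keep": keep,
            "fail_reason": reason,
        }
    )


def filter_markers(
    g: GenotypeMatrix, t: QCThresholds = QCThresholds()
) -> Tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep markers with call rate, MAF and HWE p strictly above their thresholds."""
    if g.n_markers == 0 or g.n_individuals == 0:
        raise EmptyPanelError("empty genotype panel")
    report = marker_qc_table(g, t)
    keep = report["keep"].to_numpy()
    if not keep.any():
        raise EmptyPanelError("marker QC removed every marker; downstream models undefined")
    return g.subset_markers(keep), report


def filter_samples(g: GenotypeMatrix, t: QCThresholds = QCThresholds()) -> GenotypeMatrix:
    """Remove individuals whose missing fraction strictly exceeds max_sample_missing."""
    if g.n_markers == 0 or g.n_individuals == 0:
        raise EmptyPanelError("empty genotype panel")
    miss_frac = np.isnan(g.values).mean(axis=1)
    keep = ~(miss_frac > t.max_sample_missing)
    if not keep.any():
        raise EmptyPanelError("sample QC removed every individual")
    return g.subset_individuals(keep)


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call with the marker's mean coded genotype."""
    vals = g.values
    fully_missing = np.isnan(vals).all(axis=0)
    if fully_missing.any():
        bad = g.marker_ids[fully_missing][:5].tolist()
        raise InvalidParameterError(
            f"markers with no called genotypes (e.g. {bad}); run filter_markers first"
        )
    if not np.isnan(vals).any():
        return g
    out = vals.copy()
    col_means = np.nanmean(out, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(out))
    out[nan_r, nan_c] = col_means[nan_c]
    return GenotypeMatrix(
        values=out,
        individual_ids=g.individual_ids,
        marker_ids=g.marker_ids,
        birth_year=g.birth_year,
        fractional=True,
    )


def run_qc(
    g: GenotypeMatrix, t: QCThresholds = QCThresholds()
) -> Tuple[GenotypeMatrix, pd.DataFrame]:
    """Full QC pipeline: marker filters -> sample filter -> mean imputation."""
    g, report = filter_markers(g, t)
    g = filter_samples(g, t)
    return impute_missing(g), report


def _design_matrix(
    pheno: pd.DataFrame, factors: Sequence[str], covariates: Sequence[str]
) -> Tuple[np.ndarray, list]:
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for f in factors:
        dummies = pd.get_dummies(pheno[f].astype("category"), prefix=f, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(str(c))
    for c in covariates:
        cols.append(pheno[c].to_numpy(dtype=float))
        names.append(str(c))
    return np.column_stack(cols), names


def adjust_phenotype(
    pheno: pd.DataFrame,
    factors: Sequence[str] = ("sex", "birth_year"),
    covariates: Sequence[str] = ("fatten_days", "init_weight"),
    response: str = "y",
    id_col: str = "id",
) -> AdjustedPhenotype:
    """OLS fixed-effect adjustment; returns residuals y* with zero mean.

    Factors get treatment coding with the first level as reference; covariate
    slopes are global. Raises on a rank-deficient design, naming the columns
    implicated.
    """
    missing = [c for c in (response, id_col, *factors, *covariates) if c not in pheno.columns]
    if missing:
        raise InvalidParameterError(f"phenotype table lacks columns: {missing}")
    y = pheno[response].to_numpy(dtype=float)
    X, names = _design_matrix(pheno, factors, covariates)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j in range(1, X.shape[1]):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                collinear.append(names[j])
        raise RankDeficientDesignError(
            f"adjustment design is rank deficient; collinear columns: {collinear}",
            columns=collinear,
        )

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    y_star = y - X @ beta
    return AdjustedPhenotype(
        ids=pheno[id_col].to_numpy(dtype=object),
        y_star=y_star,
        coefficients=dict(zip(names, beta.tolist())),
        design_columns=tuple(names),
    )
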