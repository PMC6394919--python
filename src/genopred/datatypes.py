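"""Core value objects shared across the pipeline.

Genotypes are coded additively as 1 / 0 / -1 for the homozygous-major,
heterozygous and homozygous-minor diploid states; missing calls are NaN.
After mean imputation entries may be fractional in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import DimensionMismatchError, InvalidParameterError

__all__ = [
    "GenotypeMatrix",
    "MarkerEffects",
    "AdjustedPhenotype",
    "KinshipMatrix",
    "VarianceComponents",
    "GEBVVector",
    "AccuracyReport",
]


def _as_str_array(ids: Sequence, n: int, name: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.shape != (n,):
        raise DimensionMismatchError(f"{name} must have length {n}, got {arr.shape}")
    if len(set(arr.tolist())) != n:
        raise InvalidParameterError(f"duplicate entries in {name}")
    return arr


@dataclass
class GenotypeMatrix:
    """n x m additive genotype matrix, NaN marks missing calls.

    ``fractional=False`` enforces the raw-call alphabet {-1, 0, 1, NaN};
    imputed matrices set ``fractional=True`` and allow values in [-1, 1].
    """

    values: np.ndarray
    individual_ids: np.ndarray
    marker_ids: np.ndarray
    birth_year: Optional[np.ndarray] = None
    fractional: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionMismatchError("genotype values must be 2-D (individuals x markers)")
        n, m = self.values.shape
        self.individual_ids = _as_str_array(self.individual_ids, n, "individual_ids")
        self.marker_ids = _as_str_array(self.marker_ids, m, "marker_ids")
        if self.birth_year is not None:
            self.birth_year = np.asarray(self.birth_year)
            if self.birth_year.shape != (n,):
                raise DimensionMismatchError("birth_year must align with individuals")
        finite = self.values[~np.isnan(self.values)]
        if self.fractional:
            if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
                raise InvalidParameterError("imputed genotype values must lie in [-1, 1]")
        else:
            if finite.size and not np.isin(finite, (-1.0, 0.0, 1.0)).all():
                bad = finite[~np.isin(finite, (-1.0, 0.0, 1.0))][0]
                raise InvalidParameterError(
                    f"genotype entries must be -1, 0 or 1 (or missing); found {bad!r}"
                )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            values=self.values[index],
            individual_ids=self.individual_ids[index],
            marker_ids=self.marker_ids,
            birth_year=None if self.birth_year is None else self.birth_year[index],
            fractional=self.fractional,
        )

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            values=self.values[:, index],
            individual_ids=self.individual_ids,
            marker_ids=self.marker_ids[index],
            birth_year=self.birth_year,
            fractional=self.fractional,
        )


@dataclass
class MarkerEffects:
    """Intercept plus one additive effect per marker."""

    intercept: float
    effects: np.ndarray
    marker_ids: Optional[np.ndarray] = None

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float).ravel()
        if self.marker_ids is not None:
            self.marker_ids = _as_str_array(self.marker_ids, self.effects.size, "marker_ids")

    @property
    def n_markers(self) -> int:
        return self.effects.size

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.effects))


@dataclass
class AdjustedPhenotype:
    """Residual phenotype y* after fixed-effect removal, aligned to individual ids."""

    ids: np.ndarray
    y_star: np.ndarray
    coefficients: dict = field(default_factory=dict)
    design_columns: tuple = ()

    def __post_init__(self):
        self.y_star = np.asarray(self.y_star, dtype=float).ravel()
        self.ids = _as_str_array(self.ids, self.y_star.size, "ids")

    @property
    def n(self) -> int:
        return self.y_star.size


@dataclass
class KinshipMatrix:
    """Symmetric genomic relationship matrix with its trace normalizer d."""

    K: np.ndarray
    d: float
    individual_ids: np.ndarray

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        n = self.K.shape[0]
        if self.K.shape != (n, n):
            raise DimensionMismatchError("K must be square")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise InvalidParameterError("K must be symmetric")
        self.individual_ids = _as_str_array(self.individual_ids, n, "individual_ids")

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def submatrix(self, index: np.ndarray) -> "KinshipMatrix":
        return KinshipMatrix(
            K=self.K[np.ix_(index, index)], d=self.d, individual_ids=self.individual_ids[index]
        )


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2_se: Optional[float] = None
    at_boundary: bool = False

    def __post_init__(self):
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise InvalidParameterError("variance components must be nonnegative")

    @property
    def h2(self) -> float:
        total = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / total if total > 0 else 0.0


@dataclass
class GEBVVector:
    values: np.ndarray
    mu: float
    individual_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.individual_ids = _as_str_array(self.individual_ids, self.values.size, "individual_ids")


@dataclass
class AccuracyReport:
    """Per-fold predictive correlations plus their aggregate summaries."""

    method: str
    fold_r: np.ndarray
    h2: float
    trait: str = "trait"

    def __post_init__(self):
        self.fold_r = np.asarray(self.fold_r, dtype=float).ravel()

    @property
    def mean_accuracy(self) -> float:
        return float(np.nanmean(self.fold_r))

    @property
    def cv(self) -> float:
        """Fold-to-fold coefficient of variation, sd(r)/mean(r)."""
        mean = np.nanmean(self.fold_r)
        if mean == 0:
            return float("nan")
        return float(np.nanstd(self.fold_r, ddof=1) / mean)

    @property
    def realized_accuracy(self) -> float:
        return self.mean_accuracy / np.sqrt(self.h2)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "trait": self.trait,
            "fold_r": self.fold_r.tolist(),
            "mean_accuracy": self.mean_accuracy,
            "cv": self.cv,
            "h2": self.h2,
            "realized_accuracy": self.realized_accuracy,
        }
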