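"""Validation schemes (random k-fold and generation split), accuracy metrics,
and the cross-method comparison driver.

Accuracy is the Pearson correlation between test-set adjusted phenotypes and
predicted GEBVs; realized accuracy divides the mean correlation by the square
root of trait heritability (estimated once on all data).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import bayesb as _bayesb
from . import elasticnet as _en
from . import gblup as _gblup
from .datatypes import AccuracyReport, GenotypeMatrix, KinshipMatrix, VarianceComponents
from .exceptions import InvalidParameterError, UndefinedCorrelationError

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationPlan",
    "kfold_split",
    "generation_split",
    "accuracy",
    "realized_accuracy",
    "MethodSpec",
    "run_comparison",
]


@dataclass
class ValidationPlan:
    """Either a k-fold assignment or a single train/test mask.

    kfold: ``fold_assignment[i]`` in {0..k-1}. generation: fold 0 marks the
    test set and -1 the training set, exposed via ``folds()`` as one split.
    """

    scheme: str
    fold_assignment: np.ndarray
    k: int
    seed: Optional[int] = None

    def __post_init__(self):
        if self.scheme not in ("kfold", "generation"):
            raise InvalidParameterError(f"unknown scheme {self.scheme!r}")
        self.fold_assignment = np.asarray(self.fold_assignment, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.fold_assignment.size

    def folds(self):
        """Yield (fold_index, test_mask) pairs."""
        if self.scheme == "kfold":
            for f in range(self.k):
                yield f, self.fold_assignment == f
        else:
            yield 0, self.fold_assignment == 0

    def checksum(self) -> str:
        return hashlib.sha256(self.fold_assignment.tobytes()).hexdigest()[:16]


def kfold_split(ids: Sequence, k: int = 5, seed: int = 0) -> ValidationPlan:
    """Random partition into k folds whose sizes differ by at most one."""
    n = len(ids)
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    if n < k:
        raise InvalidParameterError(f"cannot split {n} individuals into {k} folds")
    order = np.random.default_rng(seed).permutation(n)
    assignment = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(order, k)):
        assignment[chunk] = f
    return ValidationPlan(scheme="kfold", fold_assignment=assignment, k=k, seed=seed)


def generation_split(birth_years: Sequence[int], cutoff_year: int) -> ValidationPlan:
    """Train on individuals born up to cutoff_year, test on those born after."""
    years = np.asarray(birth_years)
    if np.any(np.equal(years, None)) or (hasattr(years, "dtype") and years.dtype == object):
        raise InvalidParameterError("every individual needs a birth year")
    test = years > cutoff_year
    if not test.any():
        raise InvalidParameterError(f"no individuals born after {cutoff_year}: empty test set")
    if test.all():
        raise InvalidParameterError(f"no individuals born up to {cutoff_year}: empty training set")
    assignment = np.where(test, 0, -1).astype(np.int64)
    return ValidationPlan(scheme="generation", fold_assignment=assignment, k=1)


def accuracy(y_star_test: np.ndarray, gebv_test: np.ndarray) -> float:
    """Sample Pearson correlation between adjusted phenotypes and GEBVs."""
    a = np.asarray(y_star_test, dtype=float).ravel()
    b = np.asarray(gebv_test, dtype=float).ravel()
    if a.size != b.size:
        raise InvalidParameterError("vectors must have equal length")
    if a.size < 3:
        raise InvalidParameterError("need at least 3 test individuals")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    ac = a - a.mean()
    bc = b - b.mean()
    return float(ac @ bc / np.sqrt((ac @ ac) * (bc @ bc)))


def realized_accuracy(r: float, h2: float) -> float:
    """r / sqrt(h2); values above 1 are reported as-is with a warning."""
    if h2 <= 0 or h2 > 1:
        raise InvalidParameterError("h2 must lie in (0, 1]")
    out = r / np.sqrt(h2)
    if out > 1:
        logger.warning("realized accuracy %.3f exceeds 1", out)
    return float(out)


@dataclass(frozen=True)
class MethodSpec:
    """A prediction method plus its settings, for run_comparison.

    name: "gblup", "bayesb" or "en". options: method-specific keyword
    settings (e.g. {"alpha": 0.001} for en, {"pi_null": 0.9, "n_iter": ...}
    for bayesb).
    """

    name: str
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in ("gblup", "bayesb", "en"):
            raise InvalidParameterError(f"unknown method {self.name!r}")

    @property
    def label(self) -> str:
        if self.name == "en":
            return f"en({self.options.get('alpha', 1.0)})"
        if self.name == "bayesb":
            return f"bayesb(pi={self.options.get('pi_null', 0.9)})"
        return "gblup"


def _predict_fold(
    method: MethodSpec,
    g: GenotypeMatrix,
    K: KinshipMatrix,
    y_star: np.ndarray,
    test_mask: np.ndarray,
    fold_seed: int,
) -> np.ndarray:
    """Fit on the training part and return GEBVs for the test individuals."""
    train_mask = ~test_mask
    y_train = y_star[train_mask]

    if method.name == "gblup":
        K_tr = K.submatrix(np.flatnonzero(train_mask))
        from .datatypes import AdjustedPhenotype

        vc = _gblup.reml_fit(
            K_tr,
            AdjustedPhenotype(ids=K_tr.individual_ids, y_star=y_train - y_train.mean()),
        )
        if vc.sigma_e2 <= 0:
            vc = VarianceComponents(sigma_g2=vc.sigma_g2, sigma_e2=1e-8)
        gebv = _gblup.gblup_predict(K, y_train, train_mask, vc)
        return gebv.values[test_mask]

    if method.name == "bayesb":
        g_train = g.subset_individuals(np.flatnonzero(train_mask))
        opts = dict(method.options)
        opts.setdefault("seed", fold_seed)
        settings = _bayesb.default_settings(g_train, y_train, **opts)
        post = _bayesb.bayesb_fit(g_train, y_train, settings)
        g_test = g.subset_individuals(np.flatnonzero(test_mask))
        return _bayesb.gebv_from_effects(g_test, post.effects).values

    # elastic net
    opts = dict(method.options)
    opts.setdefault("seed", fold_seed)
    spec = _en.PenaltySpec(**opts)
    g_train = g.subset_individuals(np.flatnonzero(train_mask))
    path = _en.en_cv_select(g_train, y_train, spec)
    return g.values[test_mask] @ path.effects.effects


def run_comparison(
    g: GenotypeMatrix,
    y_star: np.ndarray,
    methods: Sequence[MethodSpec],
    plan: ValidationPlan,
    h2: Optional[float] = None,
    trait: str = "trait",
) -> Dict[str, AccuracyReport]:
    """Evaluate every method on identical folds of one dataset.

    Variance components (GBLUP), lambda (EN) and chains (BayesB) are refit on
    each training fold. ``h2`` for realized accuracy defaults to a single
    whole-data REML estimate. A method failing on a fold yields NaN for that
    cell; the comparison continues.
    """
    if not g.is_complete():
        raise InvalidParameterError("genotype matrix has missing entries; run QC first")
    y_star = np.asarray(y_star, dtype=float).ravel()
    if y_star.size != g.n_individuals or plan.n != g.n_individuals:
        raise InvalidParameterError("genotypes, phenotypes and plan are not aligned")

    K = _gblup.build_grm(g)
    if h2 is None:
        from .datatypes import AdjustedPhenotype

        # centered GRM for heritability: the uncentered form folds allele-frequency
        # structure into sigma_g2 and overstates h2 relative to Var(g)/Var(y)
        K_c = _gblup.build_grm(g, center=True)
        vc_all = _gblup.reml_fit(
            K_c, AdjustedPhenotype(ids=g.individual_ids, y_star=y_star - y_star.mean())
        )
        h2 = max(vc_all.h2, 1e-6)

    logger.info("validation plan %s checksum %s", plan.scheme, plan.checksum())
    reports: Dict[str, AccuracyReport] = {}
    for method in methods:
        rs: List[float] = []
        for f, test_mask in plan.folds():
            fold_seed = (plan.seed or 0) * 1000 + f
            try:
                pred = _predict_fold(method, g, K, y_star, test_mask, fold_seed)
                rs.append(accuracy(y_star[test_mask], pred))
            except Exception as exc:  # pragma: no cover - defensive path
                logger.warning("method %s failed on fold %d: %s", method.label, f, exc)
                rs.append(float("nan"))
        reports[method.label] = AccuracyReport(
            method=method.label, fold_r=np.array(rs), h2=h2, trait=trait
        )
    return reports
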