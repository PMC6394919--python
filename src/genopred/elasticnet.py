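"""Elastic-net marker regression by cyclic coordinate descent.

Minimizes, in standardized coordinates,

    (1/2n) * ||y - Z b||^2 + lambda * ( alpha*||b||_1 + (1-alpha)/2 * ||b||_2^2 )

with warm starts down a log-spaced lambda path, and selects lambda by
internal k-fold cross-validation at minimum MSE (or the min+1SE variant).
Genotype columns are standardized internally and coefficients are
back-transformed; the intercept is never penalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._jit import njit
from .datatypes import GenotypeMatrix, MarkerEffects
from .exceptions import DegeneratePanelError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = ["PenaltySpec", "PathResult", "soft_threshold", "en_fit_path", "en_cv_select", "en_predict"]

_MAX_SWEEPS = 100_000


def soft_threshold(z: float, t: float) -> float:
    """L1 proximal operator: sign(z) * max(|z| - t, 0)."""
    if t < 0:
        raise InvalidParameterError("threshold must be nonnegative")
    return float(np.sign(z) * max(abs(z) - t, 0.0))


@dataclass(frozen=True)
class PenaltySpec:
    alpha: float = 1.0
    lambda_grid: Optional[np.ndarray] = None
    n_lambda: int = 100
    lambda_min_ratio: Optional[float] = None
    cv_folds: int = 5
    criterion: str = "minMSE"
    standardize: bool = True
    seed: int = 0
    tol: float = 1e-7

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise InvalidParameterError("alpha must lie in [0, 1]")
        if self.criterion not in ("minMSE", "minMSE_1SE"):
            raise InvalidParameterError(f"unknown criterion {self.criterion!r}")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.ndim != 1 or grid.size == 0:
                raise InvalidParameterError("lambda_grid must be a non-empty 1-D sequence")
            if (grid <= 0).any():
                raise InvalidParameterError("lambda_grid values must be positive")
            if grid.size > 1 and not (np.diff(grid) < 0).all():
                raise InvalidParameterError("lambda_grid must be strictly decreasing")
            object.__setattr__(self, "lambda_grid", grid)
        if self.cv_folds < 2:
            raise InvalidParameterError("cv_folds must be >= 2")


@dataclass
class PathResult:
    """Coefficient path and (optionally) cross-validation summaries per lambda."""

    lambdas: np.ndarray
    coefs: np.ndarray  # (n_lambda, m) on the original genotype scale
    intercepts: np.ndarray
    n_sweeps: np.ndarray
    converged: np.ndarray
    cv_mse: Optional[np.ndarray] = None
    cv_se: Optional[np.ndarray] = None
    chosen_index: Optional[int] = None
    effects: Optional[MarkerEffects] = None

    @property
    def chosen_lambda(self) -> Optional[float]:
        return None if self.chosen_index is None else float(self.lambdas[self.chosen_index])

    def n_nonzero(self) -> np.ndarray:
        return (self.coefs != 0).sum(axis=1)


@njit(cache=False)
def _cd_path_kernel(Zs, yc, alpha, lambdas, tol, max_sweeps):  # pragma: no cover - jitted
    n, m = Zs.shape
    n_lam = lambdas.shape[0]
    coefs = np.zeros((n_lam, m))
    sweeps = np.zeros(n_lam, dtype=np.int64)
    converged = np.zeros(n_lam, dtype=np.bool_)
    beta = np.zeros(m)
    r = yc.copy()
    for li in range(n_lam):
        lam = lambdas[li]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        for sweep in range(max_sweeps):
            max_change = 0.0
            for j in range(m):
                bj = beta[j]
                dot = 0.0
                for i in range(n):
                    dot += Zs[i, j] * r[i]
                rho = dot / n + bj  # columns have unit (1/n) norm
                if rho > l1:
                    bnew = (rho - l1) / (1.0 + l2)
                elif rho < -l1:
                    bnew = (rho + l1) / (1.0 + l2)
                else:
                    bnew = 0.0
                if bnew != bj:
                    diff = bj - bnew
                    for i in range(n):
                        r[i] += Zs[i, j] * diff
                    beta[j] = bnew
                    ad = abs(diff)
                    if ad > max_change:
                        max_change = ad
            if max_change < tol:
                converged[li] = True
                sweeps[li] = sweep + 1
                break
        else:
            sweeps[li] = max_sweeps
        coefs[li] = beta
    return coefs, sweeps, converged


def _standardize(Z: np.ndarray, standardize: bool):
    means = Z.mean(axis=0)
    if standardize:
        sds = Z.std(axis=0)
        if (sds == 0).any():
            raise DegeneratePanelError("constant marker column; cannot standardize (filter MAF first)")
    else:
        sds = np.ones(Z.shape[1])
    return (Z - means) / sds, means, sds


def _lambda_grid(Zs: np.ndarray, yc: np.ndarray, spec: PenaltySpec) -> np.ndarray:
    if spec.lambda_grid is not None:
        return spec.lambda_grid
    if spec.alpha == 0.0:
        raise InvalidParameterError(
            "alpha = 0 has no finite lambda_max; supply an explicit lambda_grid "
            "(pure ridge is experimental here)"
        )
    n, m = Zs.shape
    lam_max = float(np.abs(Zs.T @ yc).max()) / (n * spec.alpha)
    if lam_max <= 0:
        lam_max = 1e-3
    ratio = spec.lambda_min_ratio
    if ratio is None:
        ratio = 1e-2 if m > n else 1e-4
    return np.geomspace(lam_max, lam_max * ratio, spec.n_lambda)


def en_objective(Zs: np.ndarray, yc: np.ndarray, beta: np.ndarray, lam: float, alpha: float) -> float:
    """Standardized-scale objective value (used by monotonicity checks)."""
    n = Zs.shape[0]
    rss = float(np.sum((yc - Zs @ beta) ** 2))
    return rss / (2 * n) + lam * (alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * beta @ beta)


def cd_objective_trace(
    Z: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    n_sweeps: int = 50,
    standardize: bool = True,
) -> np.ndarray:
    """Objective value after each coordinate-descent sweep at one lambda.

    Pure-Python mirror of the path kernel's update rule, used to verify that
    the objective is non-increasing sweep over sweep.
    """
    Zs, _, _ = _standardize(np.asarray(Z, dtype=float), standardize)
    yc = np.asarray(y, dtype=float) - np.mean(y)
    n, m = Zs.shape
    beta = np.zeros(m)
    r = yc.copy()
    l1, l2 = lam * alpha, lam * (1 - alpha)
    trace = [en_objective(Zs, yc, beta, lam, alpha)]
    for _ in range(n_sweeps):
        for j in range(m):
            rho = Zs[:, j] @ r / n + beta[j]
            bnew = soft_threshold(rho, l1) / (1 + l2)
            if bnew != beta[j]:
                r += Zs[:, j] * (beta[j] - bnew)
                beta[j] = bnew
        trace.append(en_objective(Zs, yc, beta, lam, alpha))
    return np.asarray(trace)


def en_fit_path(
    g_train: GenotypeMatrix | np.ndarray,
    y_star_train: np.ndarray,
    spec: PenaltySpec,
    lambdas: Optional[np.ndarray] = None,
) -> PathResult:
    """Fit the coordinate-descent path over a decreasing lambda grid."""
    Z = g_train.values if isinstance(g_train, GenotypeMatrix) else np.asarray(g_train, dtype=float)
    y = np.asarray(y_star_train, dtype=float).ravel()
    if Z.shape[0] != y.size:
        raise InvalidParameterError("genotypes and response are not aligned")
    if np.isnan(Z).any():
        raise InvalidParameterError("genotype matrix has missing entries; impute first")

    Zs, means, sds = _standardize(Z, spec.standardize)
    y_mean = float(y.mean())
    yc = y - y_mean
    if lambdas is None:
        lambdas = _lambda_grid(Zs, yc, spec)
    lambdas = np.asarray(lambdas, dtype=float)

    coefs_std, sweeps, converged = _cd_path_kernel(
        np.ascontiguousarray(Zs), yc, float(spec.alpha), lambdas, float(spec.tol), _MAX_SWEEPS
    )
    if not converged.all():
        logger.warning("coordinate descent hit the sweep cap for %d lambda(s)", int((~converged).sum()))

    coefs = coefs_std / sds[None, :]
    intercepts = y_mean - coefs @ means
    return PathResult(
        lambdas=lambdas,
        coefs=coefs,
        intercepts=intercepts,
        n_sweeps=sweeps,
        converged=converged,
    )


def _fold_indices(n: int, k: int, seed: int) -> np.ndarray:
    order = np.random.default_rng(seed).permutation(n)
    assignment = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(order, k)):
        assignment[chunk] = f
    return assignment


def en_cv_select(
    g_train: GenotypeMatrix | np.ndarray,
    y_star_train: np.ndarray,
    spec: PenaltySpec,
) -> PathResult:
    """Choose lambda by internal k-fold CV on the training set and refit.

    criterion "minMSE" picks the MSE argmin; "minMSE_1SE" picks the largest
    lambda whose mean MSE is within one standard error of the minimum.
    """
    Z = g_train.values if isinstance(g_train, GenotypeMatrix) else np.asarray(g_train, dtype=float)
    y = np.asarray(y_star_train, dtype=float).ravel()
    n = y.size
    if n < spec.cv_folds:
        raise InvalidParameterError("training set smaller than cv_folds")

    # one shared grid from the full training data
    Zs, _, _ = _standardize(Z, spec.standardize)
    yc = y - y.mean()
    lambdas = _lambda_grid(Zs, yc, spec)

    folds = _fold_indices(n, spec.cv_folds, spec.seed)
    errs = np.full((spec.cv_folds, lambdas.size), np.nan)
    for f in range(spec.cv_folds):
        test = folds == f
        y_tr = y[~test]
        if np.ptp(y_tr) == 0:
            logger.warning("fold %d has constant training response; skipped", f)
            continue
        path = en_fit_path(Z[~test], y_tr, spec, lambdas=lambdas)
        pred = Z[test] @ path.coefs.T + path.intercepts[None, :]
        errs[f] = ((pred - y[test, None]) ** 2).mean(axis=0)
    if np.isnan(errs).all(axis=1).all():
        raise InvalidParameterError("all CV folds degenerate")

    cv_mse = np.nanmean(errs, axis=0)
    n_ok = (~np.isnan(errs)).sum(axis=0)
    cv_se = np.nanstd(errs, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1))

    i_min = int(np.nanargmin(cv_mse))
    if spec.criterion == "minMSE_1SE":
        thresh = cv_mse[i_min] + cv_se[i_min]
        # lambdas are decreasing: the largest qualifying lambda has the smallest index
        chosen = int(np.flatnonzero(cv_mse <= thresh)[0])
    else:
        chosen = i_min

    final = en_fit_path(Z, y, spec, lambdas=lambdas)
    final.cv_mse = cv_mse
    final.cv_se = cv_se
    final.chosen_index = chosen
    marker_ids = g_train.marker_ids if isinstance(g_train, GenotypeMatrix) else None
    final.effects = MarkerEffects(
        intercept=float(final.intercepts[chosen]),
        effects=final.coefs[chosen],
        marker_ids=marker_ids,
    )
    return final


def en_predict(Z: np.ndarray, effects: MarkerEffects, include_intercept: bool = True) -> np.ndarray:
    Z = Z.values if isinstance(Z, GenotypeMatrix) else np.asarray(Z, dtype=float)
    out = Z @ effects.effects
    if include_intercept:
        out = out + effects.intercept
    return out
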