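"""Genomic relationship matrix, REML variance components, and (G/RR-)BLUP.

The relationship matrix uses the uncentered coded-genotype construction
K = (1/d) Z Z' with d = tr(Z Z') / n, which forces mean(diag(K)) = 1.
REML is a one-dimensional profile likelihood over h2 on the eigenbasis of K,
so each evaluation is O(n) after a single eigendecomposition. Predictions
solve the mixed-model equations; the marker-space ridge (RR-BLUP) route is an
independent implementation that must agree with GBLUP to numerical precision.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import linalg, optimize

from .datatypes import (
    AdjustedPhenotype,
    GenotypeMatrix,
    GEBVVector,
    KinshipMatrix,
    MarkerEffects,
    VarianceComponents,
)
from .exceptions import (
    DegeneratePanelError,
    DimensionMismatchError,
    InvalidParameterError,
)

logger = logging.getLogger(__name__)

__all__ = ["build_grm", "reml_fit", "profile_reml_loglik", "gblup_predict", "rrblup_predict"]

_H2_LO, _H2_HI = 1e-4, 1.0 - 1e-4
_JITTER = 1e-8


def build_grm(g: GenotypeMatrix, center: bool = False) -> KinshipMatrix:
    """K = (1/d) Z Z' with d = tr(Z Z')/n from a complete coded matrix.

    ``center=True`` subtracts marker means first (off by default: the
    uncentered form is the native construction here).
    """
    if not g.is_complete():
        raise InvalidParameterError("genotype matrix has missing entries; impute first")
    if g.n_markers < 1:
        raise InvalidParameterError("need at least one marker")
    Z = g.values
    if center:
        Z = Z - Z.mean(axis=0, keepdims=True)
    ZZt = Z @ Z.T
    d = float(np.trace(ZZt)) / g.n_individuals
    if d <= 0.0:
        raise DegeneratePanelError("tr(ZZ')/n = 0: coded matrix carries no signal")
    return KinshipMatrix(K=ZZt / d, d=d, individual_ids=g.individual_ids)


def _eigen(K: np.ndarray):
    s, U = np.linalg.eigh(K)
    tol = max(abs(s).max(), 1.0) * 1e-10
    if s.min() < -1e-6 * max(abs(s).max(), 1.0):
        raise InvalidParameterError(f"K is not PSD within tolerance (min eigenvalue {s.min():.3g})")
    return np.clip(s, 0.0, None), U


def profile_reml_loglik(h2: float, s: np.ndarray, x_rot: np.ndarray, y_rot: np.ndarray) -> float:
    """Profile restricted log-likelihood of h2 for y = 1*mu + g + e on K's eigenbasis.

    ``s`` are K's eigenvalues, ``x_rot``/``y_rot`` the rotated intercept and
    response. The total variance is profiled out analytically.
    """
    n = y_rot.size
    w = h2 * s + (1.0 - h2)
    xtvx = float(np.sum(x_rot**2 / w))
    beta = float(np.sum(x_rot * y_rot / w)) / xtvx
    r = y_rot - beta * x_rot
    quad = float(np.sum(r**2 / w))
    sigma2 = quad / (n - 1)
    return -0.5 * ((n - 1) * np.log(sigma2) + np.sum(np.log(w)) + np.log(xtvx) + (n - 1))


def reml_fit(K: KinshipMatrix, y_star: AdjustedPhenotype) -> VarianceComponents:
    """Estimate (sigma_g2, sigma_e2) by bounded 1-D profile REML over h2."""
    if K.n != y_star.n:
        raise DimensionMismatchError("K and y* are not aligned")
    if K.n < 10:
        raise InvalidParameterError("REML needs at least 10 individuals")
    s, U = _eigen(K.K)
    y_rot = U.T @ y_star.y_star
    x_rot = U.T @ np.ones(K.n)

    res = optimize.minimize_scalar(
        lambda h2: -profile_reml_loglik(h2, s, x_rot, y_rot),
        bounds=(_H2_LO, _H2_HI),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    at_boundary = h2 <= _H2_LO * 2 or h2 >= 1.0 - 2 * _H2_LO
    if at_boundary:
        logger.warning("REML h2 estimate at boundary (h2=%.4g)", h2)

    n = K.n
    w = h2 * s + (1.0 - h2)
    xtvx = float(np.sum(x_rot**2 / w))
    beta = float(np.sum(x_rot * y_rot / w)) / xtvx
    quad = float(np.sum((y_rot - beta * x_rot) ** 2 / w))
    sigma2 = quad / (n - 1)

    h2_se = None
    if not at_boundary:
        eps = 1e-4
        ll = lambda h: profile_reml_loglik(h, s, x_rot, y_rot)  # noqa: E731
        curv = (ll(h2 + eps) - 2 * ll(h2) + ll(h2 - eps)) / eps**2
        if curv < 0:
            h2_se = float(1.0 / np.sqrt(-curv))

    return VarianceComponents(
        sigma_g2=h2 * sigma2, sigma_e2=(1.0 - h2) * sigma2, h2_se=h2_se, at_boundary=at_boundary
    )


def _solve_spd(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cholesky solve with an automatic logged jitter on singularity."""
    try:
        c, low = linalg.cho_factor(A, check_finite=False)
        return linalg.cho_solve((c, low), b, check_finite=False)
    except linalg.LinAlgError:
        logger.warning("singular coefficient matrix; applying diagonal ridge %.0e", _JITTER)
        A = A + _JITTER * np.eye(A.shape[0])
        c, low = linalg.cho_factor(A, check_finite=False)
        return linalg.cho_solve((c, low), b, check_finite=False)


def gblup_predict(
    K: KinshipMatrix,
    y_star_train: np.ndarray,
    train_mask: np.ndarray,
    vc: VarianceComponents,
    fit_mean: bool = True,
) -> GEBVVector:
    """Mixed-model-equation GBLUP: fit on training phenotypes, predict all GEBVs.

    Test individuals receive predictions through the K blocks linking them to
    the training set. ``fit_mean=False`` fixes mu at zero.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    y_t = np.asarray(y_star_train, dtype=float).ravel()
    if train_mask.sum() != y_t.size:
        raise DimensionMismatchError("train_mask and training response length differ")
    if y_t.size == 0:
        raise InvalidParameterError("training set is empty")
    if vc.sigma_e2 <= 0:
        raise InvalidParameterError("sigma_e2 must be strictly positive for prediction")

    t_idx = np.flatnonzero(train_mask)
    K_tt = K.K[np.ix_(t_idx, t_idx)]
    V = vc.sigma_g2 * K_tt + vc.sigma_e2 * np.eye(t_idx.size)

    if fit_mean:
        ones = np.ones(t_idx.size)
        Vinv_1 = _solve_spd(V, ones)
        mu = float(ones @ _solve_spd(V, y_t)) / float(ones @ Vinv_1)
    else:
        mu = 0.0
    alpha = _solve_spd(V, y_t - mu)
    gebv = vc.sigma_g2 * (K.K[:, t_idx] @ alpha)
    return GEBVVector(values=gebv, mu=mu, individual_ids=K.individual_ids)


def rrblup_predict(
    g: GenotypeMatrix,
    y_star_train: np.ndarray,
    train_mask: np.ndarray,
    vc: VarianceComponents,
    fit_mean: bool = True,
):
    """Marker-space ridge (RR-BLUP) with per-marker prior variance sigma_g2/d.

    Solves the (1+m)-dimensional mixed-model equations jointly for mu and all
    marker effects; GEBV = Z gamma. Equivalent to :func:`gblup_predict` by the
    GRM duality.
    """
    if not g.is_complete():
        raise InvalidParameterError("genotype matrix has missing entries; impute first")
    train_mask = np.asarray(train_mask, dtype=bool)
    y_t = np.asarray(y_star_train, dtype=float).ravel()
    if train_mask.sum() != y_t.size:
        raise DimensionMismatchError("train_mask and training response length differ")
    if vc.sigma_e2 <= 0 or vc.sigma_g2 <= 0:
        raise InvalidParameterError("variance components must be strictly positive")

    Z = g.values
    Z_t = Z[train_mask]
    d = float(np.trace(Z @ Z.T)) / g.n_individuals
    if d <= 0:
        raise DegeneratePanelError("degenerate coded matrix (d = 0)")
    lam = d * vc.sigma_e2 / vc.sigma_g2

    n_t, m = Z_t.shape
    if fit_mean:
        A = np.empty((m + 1, m + 1))
        A[0, 0] = n_t
        A[0, 1:] = Z_t.sum(axis=0)
        A[1:, 0] = A[0, 1:]
        A[1:, 1:] = Z_t.T @ Z_t + lam * np.eye(m)
        rhs = np.concatenate(([y_t.sum()], Z_t.T @ y_t))
        sol = _solve_spd(A, rhs)
        mu, gamma = float(sol[0]), sol[1:]
    else:
        A = Z_t.T @ Z_t + lam * np.eye(m)
        gamma = _solve_spd(A, Z_t.T @ y_t)
        mu = 0.0

    effects = MarkerEffects(intercept=mu, effects=gamma, marker_ids=g.marker_ids)
    gebv = GEBVVector(values=Z @ gamma, mu=mu, individual_ids=g.individual_ids)
    return effects, gebv
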