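"""BayesB spike-and-slab marker regression by single-site MCMC.

Each marker effect is zero with prior probability pi_null and otherwise
normal with a locus-specific variance carrying a scaled-inverse-chi-square
prior. The indicator/variance pair is updated by a Metropolis-Hastings step
that proposes from the prior with the effect integrated out of the
likelihood; effects, the intercept, locus variances and the residual
variance are Gibbs-sampled. One shared RNG stream makes the chain fully
reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from ._jit import njit
from .datatypes import GenotypeMatrix, GEBVVector, MarkerEffects
from .exceptions import (
    DimensionMismatchError,
    InvalidParameterError,
    McmcDivergenceError,
)

__all__ = ["McmcSettings", "PosteriorSummary", "bayesb_fit", "gebv_from_effects", "default_settings"]


@dataclass(frozen=True)
class McmcSettings:
    n_iter: int = 50_000
    burn_in: int = 2_500
    thin: int = 10
    pi_null: float = 0.9
    seed: int = 0
    nu_g: float = 4.2
    s_g: Optional[float] = None  # None -> calibrated from the data at fit time
    nu_e: float = 4.0
    s_e: Optional[float] = None
    target_h2: float = 0.5  # used only for the S_g calibration

    def __post_init__(self):
        if self.n_iter < 1 or self.burn_in < 0 or self.burn_in >= self.n_iter:
            raise InvalidParameterError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise InvalidParameterError("thin must be >= 1")
        if not (0.0 <= self.pi_null < 1.0):
            raise InvalidParameterError("pi_null must lie in [0, 1)")
        if self.nu_g <= 2 or self.nu_e <= 0:
            raise InvalidParameterError("nu_g must exceed 2 and nu_e be positive")
        if (self.n_iter - self.burn_in) // self.thin < 1:
            raise InvalidParameterError("settings retain zero samples")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSummary:
    mu: float
    effects: MarkerEffects
    inclusion_prob: np.ndarray
    effect_sd: np.ndarray
    n_retained: int
    sigma_e_trace: np.ndarray
    settings: McmcSettings


def default_settings(
    g: GenotypeMatrix, y_star: np.ndarray, pi_null: float = 0.9, **overrides
) -> McmcSettings:
    """Settings with hyperparameters calibrated to the data (Meuwissen-style).

    S_g is solved so the prior-mean genetic variance, spread over the expected
    (1 - pi) * m nonzero loci with genotype variance var(Z_k), matches
    target_h2 * var(y*); S_e comes from the residual share of var(y*).
    """
    s = McmcSettings(pi_null=pi_null, **overrides)
    var_y = float(np.var(np.asarray(y_star, dtype=float)))
    mean_col_var = float(np.mean(np.var(g.values, axis=0)))
    m = g.n_markers
    n_active = max((1.0 - pi_null) * m, 1.0)
    # prior mean of scaled-inv-chi2(nu, S) is S*nu/(nu-2)
    prior_mean_var = s.target_h2 * var_y / (n_active * max(mean_col_var, 1e-12))
    s_g = prior_mean_var * (s.nu_g - 2.0) / s.nu_g
    s_e = (1.0 - s.target_h2) * var_y * (s.nu_e - 2.0) / s.nu_e if s.nu_e > 2 else (1 - s.target_h2) * var_y
    return replace(s, s_g=float(max(s_g, 1e-12)), s_e=float(max(s_e, 1e-12)))


@njit(cache=False)
def _chain_kernel(
    Z, y, pi, nu_g, s_g, nu_e, s_e, n_iter, burn_in, thin, seed
):  # pragma: no cover - jitted
    np.random.seed(seed)
    n, m = Z.shape
    ztz = np.empty(m)
    for j in range(m):
        acc = 0.0
        for i in range(n):
            acc += Z[i, j] * Z[i, j]
        ztz[j] = acc

    gamma = np.zeros(m)
    sig_gk = np.zeros(m)
    included = np.zeros(m, dtype=np.bool_)
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    r = y - mu
    sse0 = 0.0
    for i in range(n):
        sse0 += r[i] * r[i]
    sigma_e2 = sse0 / n if sse0 > 0 else 1.0

    n_saved_max = (n_iter - burn_in) // thin
    sum_gamma = np.zeros(m)
    sum_gamma2 = np.zeros(m)
    sum_incl = np.zeros(m)
    mu_sum = 0.0
    sig_e_trace = np.zeros(n_saved_max)
    saved = 0

    for it in range(n_iter):
        # intercept
        rbar = 0.0
        for i in range(n):
            rbar += r[i]
        rbar = rbar / n + mu
        mu_new = np.random.normal(rbar, np.sqrt(sigma_e2 / n))
        shift = mu_new - mu
        for i in range(n):
            r[i] -= shift
        mu = mu_new

        for k in range(m):
            gk = gamma[k]
            if gk != 0.0:
                for i in range(n):
                    r[i] += Z[i, k] * gk
            zty = 0.0
            for i in range(n):
                zty += Z[i, k] * r[i]

            # marginal log-likelihood ratio vs the null model, effect integrated out
            if included[k]:
                v = sig_gk[k]
                a = 1.0 + v * ztz[k] / sigma_e2
                ll_old = -0.5 * np.log(a) + 0.5 * v * zty * zty / (sigma_e2 * (sigma_e2 + v * ztz[k]))
            else:
                ll_old = 0.0

            if np.random.random() < pi:
                incl_new = False
                ll_new = 0.0
                v_new = 0.0
            else:
                incl_new = True
                v_new = nu_g * s_g / np.random.chisquare(nu_g)
                a = 1.0 + v_new * ztz[k] / sigma_e2
                ll_new = -0.5 * np.log(a) + 0.5 * v_new * zty * zty / (
                    sigma_e2 * (sigma_e2 + v_new * ztz[k])
                )

            if np.log(np.random.random() + 1e-300) < ll_new - ll_old:
                included[k] = incl_new
                sig_gk[k] = v_new

            if included[k]:
                c = ztz[k] + sigma_e2 / sig_gk[k]
                gk = np.random.normal(zty / c, np.sqrt(sigma_e2 / c))
                gamma[k] = gk
                for i in range(n):
                    r[i] -= Z[i, k] * gk
                # Gibbs refresh of the locus variance given the effect
                sig_gk[k] = (nu_g * s_g + gk * gk) / np.random.chisquare(nu_g + 1.0)
            else:
                gamma[k] = 0.0

        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        sigma_e2 = (nu_e * s_e + sse) / np.random.chisquare(nu_e + n)
        if not np.isfinite(sigma_e2) or sigma_e2 <= 0.0:
            return (sum_gamma, sum_gamma2, sum_incl, mu_sum, sig_e_trace, saved, -1)

        if it >= burn_in and (it - burn_in + 1) % thin == 0:
            for k in range(m):
                sum_gamma[k] += gamma[k]
                sum_gamma2[k] += gamma[k] * gamma[k]
                if included[k]:
                    sum_incl[k] += 1.0
            mu_sum += mu
            sig_e_trace[saved] = sigma_e2
            saved += 1

    return (sum_gamma, sum_gamma2, sum_incl, mu_sum, sig_e_trace, saved, 0)


def bayesb_fit(
    g_train: GenotypeMatrix,
    y_star_train: np.ndarray,
    settings: Optional[McmcSettings] = None,
) -> PosteriorSummary:
    """Run the BayesB chain on a complete training panel.

    When ``settings`` is None (or its slab/residual scales are unset) the
    hyperparameters are calibrated from the data via :func:`default_settings`.
    Returns thinned post-burn-in posterior summaries.
    """
    if not g_train.is_complete():
        raise InvalidParameterError("genotype matrix has missing entries; impute first")
    y = np.asarray(y_star_train, dtype=float).ravel()
    if y.size != g_train.n_individuals:
        raise DimensionMismatchError("genotypes and response are not aligned")
    if y.size == 0:
        raise InvalidParameterError("training set is empty")

    if settings is None:
        settings = default_settings(g_train, y)
    elif settings.s_g is None or settings.s_e is None:
        settings = default_settings(
            g_train,
            y,
            pi_null=settings.pi_null,
            n_iter=settings.n_iter,
            burn_in=settings.burn_in,
            thin=settings.thin,
            seed=settings.seed,
            nu_g=settings.nu_g,
            nu_e=settings.nu_e,
            target_h2=settings.target_h2,
        )

    out = _chain_kernel(
        np.ascontiguousarray(g_train.values),
        y,
        float(settings.pi_null),
        float(settings.nu_g),
        float(settings.s_g),
        float(settings.nu_e),
        float(settings.s_e),
        int(settings.n_iter),
        int(settings.burn_in),
        int(settings.thin),
        int(settings.seed) & 0xFFFFFFFF,
    )
    sum_gamma, sum_gamma2, sum_incl, mu_sum, sig_e_trace, saved, status = out
    if status != 0:
        raise McmcDivergenceError(
            "residual variance became non-finite",
            diagnostics={
                "retained_before_failure": int(saved),
                "settings": settings,
                "last_sigma_e": sig_e_trace[max(saved - 1, 0)] if saved else None,
            },
        )

    mean_gamma = sum_gamma / saved
    var_gamma = np.maximum(sum_gamma2 / saved - mean_gamma**2, 0.0)
    return PosteriorSummary(
        mu=mu_sum / saved,
        effects=MarkerEffects(
            intercept=mu_sum / saved, effects=mean_gamma, marker_ids=g_train.marker_ids
        ),
        inclusion_prob=sum_incl / saved,
        effect_sd=np.sqrt(var_gamma),
        n_retained=int(saved),
        sigma_e_trace=sig_e_trace[:saved],
        settings=settings,
    )


def gebv_from_effects(g: GenotypeMatrix, effects: MarkerEffects) -> GEBVVector:
    """GEBV = Z gamma (intercept excluded; it does not affect ranking)."""
    if effects.n_markers != g.n_markers:
        raise DimensionMismatchError(
            f"{effects.n_markers} effects for {g.n_markers} markers"
        )
    return GEBVVector(
        values=g.values @ effects.effects,
        mu=effects.intercept,
        individual_ids=g.individual_ids,
    )
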