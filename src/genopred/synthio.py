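"""Synthetic genotype/phenotype generation.

Produces diploid SNP panels under Hardy-Weinberg proportions at sampled
minor-allele frequencies, additive trait architectures (fully polygenic or
sparse with a null proportion), fixed-effect structure (sex and birth-year
contemporary group plus two continuous covariates), and phenotypes at a
controlled narrow-sense heritability. Every draw is deterministic given the
seed, and the full generative truth is retained for downstream testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, MarkerEffects
from .exceptions import (
    DegenerateArchitectureError,
    DimensionMismatchError,
    InvalidParameterError,
)

__all__ = [
    "TraitArchitecture",
    "FixedEffectsSpec",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotypes",
    "simulate_study",
    "write_study",
]


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive trait architecture.

    kind="polygenic" gives every marker a nonzero effect (pi_null forced 0);
    kind="sparse" zeroes a proportion pi_null of markers exactly.
    """

    kind: str = "polygenic"
    pi_null: float = 0.0
    h2: float = 0.5
    effect_scale: float = 1.0

    def __post_init__(self):
        if self.kind not in ("polygenic", "sparse"):
            raise InvalidParameterError(f"unknown architecture kind {self.kind!r}")
        if self.kind == "polygenic" and self.pi_null != 0.0:
            raise InvalidParameterError("polygenic architecture requires pi_null = 0")
        if not (0.0 <= self.pi_null < 1.0):
            raise InvalidParameterError("pi_null must lie in [0, 1)")
        if not (0.0 < self.h2 <= 1.0):
            raise InvalidParameterError("h2 must lie in (0, 1]")
        if self.effect_scale <= 0:
            raise InvalidParameterError("effect_scale must be positive")


@dataclass(frozen=True)
class FixedEffectsSpec:
    """Fixed-effect structure: two categorical factors and two covariates.

    Factor coefficients are per-level additive shifts; covariates enter with
    global slopes. Covariate distributions (mean, sd) drive generation.
    """

    sex_effects: dict = field(default_factory=lambda: {"M": 0.0, "F": -8.0})
    year_effects: dict = field(
        default_factory=lambda: {y: 1.5 * (y - 2008) for y in range(2008, 2015)}
    )
    fatten_days_slope: float = 0.05
    init_weight_slope: float = 0.30
    fatten_days_dist: Tuple[float, float] = (480.0, 30.0)
    init_weight_dist: Tuple[float, float] = (250.0, 25.0)
    intercept: float = 100.0
    year_probs: Optional[Sequence[float]] = None

    def __post_init__(self):
        if not self.sex_effects or not self.year_effects:
            raise InvalidParameterError("sex_effects and year_effects must be non-empty")
        if self.year_probs is not None and len(self.year_probs) != len(self.year_effects):
            raise InvalidParameterError("year_probs must match year_effects length")


@dataclass
class SimulatedStudy:
    """A full synthetic dataset with its generative truth."""

    genotypes: GenotypeMatrix
    true_effects: MarkerEffects
    true_breeding_values: np.ndarray
    xbeta: np.ndarray
    noise: np.ndarray
    phenotypes: pd.DataFrame
    architecture: TraitArchitecture
    seed: int

    @property
    def realized_h2(self) -> float:
        var_g = float(np.var(self.true_breeding_values))
        var_e = float(np.var(self.noise))
        total = var_g + var_e
        return var_g / total if total > 0 else float("nan")


def _validate_maf_range(maf_range) -> Tuple[float, float]:
    try:
        lo, hi = float(maf_range[0]), float(maf_range[1])
    except (TypeError, ValueError, IndexError) as exc:
        raise InvalidParameterError(f"maf_range must be a (low, high) pair: {maf_range!r}") from exc
    if not (0.0 < lo <= hi <= 0.5):
        raise InvalidParameterError("maf_range must satisfy 0 < low <= high <= 0.5")
    return lo, hi


def simulate_genotypes(
    n: int,
    m: int,
    maf_range=(0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate an n x m SNP panel.

    Each marker's minor-allele frequency is drawn uniformly from ``maf_range``
    and genotypes follow Hardy-Weinberg proportions at that frequency, coded
    1 / 0 / -1 for 0, 1 or 2 copies of the minor allele. Missing calls are
    placed independently per entry at ``missing_rate``.
    """
    if n < 2 or m < 1:
        raise InvalidParameterError("need n >= 2 individuals and m >= 1 markers")
    if not (0.0 <= missing_rate < 1.0):
        raise InvalidParameterError("missing_rate must lie in [0, 1)")
    lo, hi = _validate_maf_range(maf_range)

    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=m)
    minor_counts = rng.binomial(2, mafs[None, :], size=(n, m))
    values = (1 - minor_counts).astype(float)
    if missing_rate > 0:
        values[rng.random(size=(n, m)) < missing_rate] = np.nan

    return GenotypeMatrix(
        values=values,
        individual_ids=np.array([f"ind{i:05d}" for i in range(n)], dtype=object),
        marker_ids=np.array([f"snp{j:06d}" for j in range(m)], dtype=object),
    )


def simulate_effects(m: int, architecture: TraitArchitecture, seed: int = 0) -> MarkerEffects:
    """Draw additive marker effects under the given architecture.

    Sparse traits zero exactly round(pi_null * m) markers; surviving effects
    are N(0, effect_scale) rescaled by sqrt(m / n_nonzero) so the expected
    total genetic variance does not depend on the degree of sparsity.
    """
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    rng = np.random.default_rng(seed)
    if architecture.kind == "sparse":
        n_zero = int(round(architecture.pi_null * m))
        n_nonzero = m - n_zero
        if n_nonzero < 1:
            raise InvalidParameterError(
                f"pi_null={architecture.pi_null} leaves no nonzero marker at m={m}"
            )
        effects = np.zeros(m)
        idx = rng.choice(m, size=n_nonzero, replace=False)
        scale = np.sqrt(architecture.effect_scale) * np.sqrt(m / n_nonzero)
        effects[idx] = rng.normal(0.0, scale, size=n_nonzero)
    else:
        effects = rng.normal(0.0, np.sqrt(architecture.effect_scale), size=m)
    return MarkerEffects(intercept=0.0, effects=effects)


def _impute_mean(values: np.ndarray) -> np.ndarray:
    """Column-mean imputation of NaN entries (local copy; preprocess owns the QC path)."""
    if not np.isnan(values).any():
        return values
    out = values.copy()
    col_means = np.nanmean(out, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(out))
    out[nan_r, nan_c] = col_means[nan_c]
    return out


def _draw_fixed_design(n: int, fixed: FixedEffectsSpec, rng: np.random.Generator):
    sexes = np.array(list(fixed.sex_effects), dtype=object)
    years = np.array(sorted(fixed.year_effects), dtype=object)
    year_probs = None
    if fixed.year_probs is not None:
        p = np.asarray(fixed.year_probs, dtype=float)
        year_probs = p / p.sum()
    sex = rng.choice(sexes, size=n)
    year = rng.choice(years, size=n, p=year_probs)
    fatten = rng.normal(*fixed.fatten_days_dist, size=n)
    init_w = rng.normal(*fixed.init_weight_dist, size=n)
    xbeta = (
        fixed.intercept
        + np.array([fixed.sex_effects[s] for s in sex])
        + np.array([fixed.year_effects[y] for y in year])
        + fixed.fatten_days_slope * fatten
        + fixed.init_weight_slope * init_w
    )
    return sex, year, fatten, init_w, xbeta


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    effects: MarkerEffects,
    architecture: TraitArchitecture,
    fixed: Optional[FixedEffectsSpec] = None,
    seed: int = 0,
    null_noise_var: Optional[float] = None,
) -> SimulatedStudy:
    """Assemble phenotypes y = Xbeta + g + e around true breeding values g = Z gamma.

    The residual variance is set from the *realized* Var(g) as
    Var(g) * (1 - h2) / h2 so the target heritability holds per dataset.
    A zero-variance g with h2 < 1 is an error unless ``null_noise_var`` is
    supplied, in which case the trait is flagged as null and noise has that
    variance (the h2-is-effectively-zero case).
    """
    if effects.n_markers != genotypes.n_markers:
        raise DimensionMismatchError(
            f"{effects.n_markers} effects for {genotypes.n_markers} markers"
        )
    fixed = fixed or FixedEffectsSpec()
    rng = np.random.default_rng(seed)

    Z = _impute_mean(genotypes.values)
    g = Z @ effects.effects
    var_g = float(np.var(g))

    if var_g == 0.0:
        if null_noise_var is None:
            raise DegenerateArchitectureError(
                "Var(g) = 0 with h2 < 1; pass null_noise_var to simulate a null trait"
            )
        sigma_e2 = float(null_noise_var)
    else:
        sigma_e2 = var_g * (1.0 - architecture.h2) / architecture.h2

    sex, year, fatten, init_w, xbeta = _draw_fixed_design(genotypes.n_individuals, fixed, rng)
    noise = rng.normal(0.0, np.sqrt(sigma_e2), size=genotypes.n_individuals) if sigma_e2 > 0 else np.zeros(genotypes.n_individuals)
    y = xbeta + g + noise

    # birth_year rides along on the genotype object for generation validation
    genotypes = GenotypeMatrix(
        values=genotypes.values,
        individual_ids=genotypes.individual_ids,
        marker_ids=genotypes.marker_ids,
        birth_year=np.array([int(v) for v in year]),
        fractional=genotypes.fractional,
    )

    phenotypes = pd.DataFrame(
        {
            "id": genotypes.individual_ids,
            "y": y,
            "sex": sex,
            "birth_year": [int(v) for v in year],
            "fatten_days": fatten,
            "init_weight": init_w,
        }
    )
    return SimulatedStudy(
        genotypes=genotypes,
        true_effects=effects,
        true_breeding_values=g,
        xbeta=xbeta,
        noise=noise,
        phenotypes=phenotypes,
        architecture=architecture,
        seed=seed,
    )


def simulate_study(
    n: int,
    m: int,
    architecture: TraitArchitecture,
    maf_range=(0.05, 0.5),
    missing_rate: float = 0.0,
    fixed: Optional[FixedEffectsSpec] = None,
    seed: int = 0,
) -> SimulatedStudy:
    """Convenience wrapper chaining genotype, effect and phenotype simulation.

    Derives independent child seeds for the three stages from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_geno, s_eff, s_phen = [int(c.generate_state(1)[0]) for c in ss.spawn(3)]
    genotypes = simulate_genotypes(n, m, maf_range=maf_range, missing_rate=missing_rate, seed=s_geno)
    effects = simulate_effects(m, architecture, seed=s_eff)
    return simulate_phenotypes(genotypes, effects, architecture, fixed=fixed, seed=s_phen)


def write_study(study: SimulatedStudy, outdir) -> dict:
    """Write genotype TSV, phenotype CSV and a JSON truth file; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    geno_path = outdir / "genotypes.tsv"
    geno = pd.DataFrame(
        study.genotypes.values,
        index=pd.Index(study.genotypes.individual_ids, name="id"),
        columns=study.genotypes.marker_ids,
    )
    # keep integer look for called genotypes
    geno.to_csv(geno_path, sep="\t", na_rep="NA", float_format="%g")

    pheno_path = outdir / "phenotypes.csv"
    study.phenotypes.to_csv(pheno_path, index=False)

    truth_path = outdir / "truth.json"
    truth = {
        "seed": study.seed,
        "architecture": {
            "kind": study.architecture.kind,
            "pi_null": study.architecture.pi_null,
            "h2": study.architecture.h2,
            "effect_scale": study.architecture.effect_scale,
        },
        "realized_h2": study.realized_h2,
        "intercept": study.true_effects.intercept,
        "effects": study.true_effects.effects.tolist(),
        "breeding_values": study.true_breeding_values.tolist(),
    }
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"genotypes": geno_path, "phenotypes": pheno_path, "truth": truth_path}
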