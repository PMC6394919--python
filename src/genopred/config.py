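"""Run configuration: a strict (unknown keys rejected) nested mapping loaded
from YAML, with CLI overrides applied on top."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .exceptions import ConfigError


def _from_dict(cls, data: dict, context: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        sub = _SECTION_TYPES.get((cls, name))
        kwargs[name] = _from_dict(sub, data[name], f"{context}.{name}") if sub else data[name]
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"{context}: {exc}") from exc


@dataclass
class SimulateConfig:
    enabled: bool = True
    n: int = 200
    m: int = 500
    architecture: str = "polygenic"
    pi_null: float = 0.0
    h2: float = 0.5
    maf_min: float = 0.05
    maf_max: float = 0.5
    missing_rate: float = 0.02


@dataclass
class QCConfig:
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_p_floor: float = 1e-5
    max_sample_missing: float = 0.10


@dataclass
class GblupConfig:
    enabled: bool = True
    center: bool = False


@dataclass
class BayesBConfig:
    enabled: bool = False
    n_iter: int = 2000
    burn_in: int = 500
    thin: int = 5
    pi_null: float = 0.9


@dataclass
class ENConfig:
    enabled: bool = True
    alpha: float = 0.001
    n_lambda: int = 100
    criterion: str = "minMSE"
    cv_folds: int = 5


@dataclass
class ValidationConfig:
    scheme: str = "kfold"
    k: int = 5
    cutoff_year: Optional[int] = None


@dataclass
class RunConfig:
    genotypes: Optional[str] = None
    phenotypes: Optional[str] = None
    genotype_dialect: str = "tsv"
    output_dir: str = "genopred_out"
    seed: int = 0
    log_level: str = "INFO"
    factors: tuple = ("sex", "birth_year")
    covariates: tuple = ("fatten_days", "init_weight")
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    gblup: GblupConfig = field(default_factory=GblupConfig)
    bayesb: BayesBConfig = field(default_factory=BayesBConfig)
    en: ENConfig = field(default_factory=ENConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_dict(cls, data, "config")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["factors"] = list(self.factors)
        d["covariates"] = list(self.covariates)
        return d

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_SECTION_TYPES = {
    (RunConfig, "simulate"): SimulateConfig,
    (RunConfig, "qc"): QCConfig,
    (RunConfig, "gblup"): GblupConfig,
    (RunConfig, "bayesb"): BayesBConfig,
    (RunConfig, "en"): ENConfig,
    (RunConfig, "validation"): ValidationConfig,
}
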