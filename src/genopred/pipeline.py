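"""End-to-end pipeline: (optional) simulation -> QC -> adjustment -> method
comparison, with every artifact written as diffable text plus a MANIFEST."""

from __future__ import annotations

import hashlib
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, preprocess, synthio, validation
from .config import RunConfig
from .exceptions import ConfigError, GenopredError
from .preprocess import QCThresholds

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns the MANIFEST dict.

    On a stage failure the partial artifacts are kept and the MANIFEST records
    the failing stage before the exception propagates.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stages": [],
        "inputs": {},
        "outputs": {},
        "status": "running",
    }
    config.dump(outdir / "resolved_config.yaml")

    def _finish(stage: str, exc: Exception):
        manifest["status"] = f"failed:{stage}"
        manifest["error"] = str(exc)
        io.write_json(manifest, outdir / "MANIFEST.json")

    stage = "inputs"
    try:
        if config.simulate.enabled:
            arch = synthio.TraitArchitecture(
                kind=config.simulate.architecture,
                pi_null=config.simulate.pi_null,
                h2=config.simulate.h2,
            )
            study = synthio.simulate_study(
                n=config.simulate.n,
                m=config.simulate.m,
                architecture=arch,
                maf_range=(config.simulate.maf_min, config.simulate.maf_max),
                missing_rate=config.simulate.missing_rate,
                seed=config.seed,
            )
            paths = synthio.write_study(study, outdir / "simulated")
            manifest["stages"].append("simulate")
            geno, pheno = study.genotypes, study.phenotypes
            for k, p in paths.items():
                manifest["inputs"][k] = {"path": str(p), "sha256": _sha256(Path(p))}
        else:
            if not config.genotypes or not config.phenotypes:
                raise ConfigError("genotypes and phenotypes paths required when simulate.enabled is false")
            geno = io.read_genotypes(config.genotypes, dialect=config.genotype_dialect)
            pheno = io.read_phenotypes(config.phenotypes)
            for k, p in (("genotypes", config.genotypes), ("phenotypes", config.phenotypes)):
                manifest["inputs"][k] = {"path": str(p), "sha256": _sha256(Path(p))}

        stage = "qc"
        thresholds = QCThresholds(
            min_call_rate=config.qc.min_call_rate,
            min_maf=config.qc.min_maf,
            hwe_p_floor=config.qc.hwe_p_floor,
            max_sample_missing=config.qc.max_sample_missing,
        )
        geno_f, qc_report = preprocess.filter_markers(geno, thresholds)
        geno_f = preprocess.filter_samples(geno_f, thresholds)
        geno_c = preprocess.impute_missing(geno_f)
        qc_report.to_csv(outdir / "qc_report.csv", index=False)
        manifest["outputs"]["qc_report"] = str(outdir / "qc_report.csv")
        manifest["stages"].append("qc")

        stage = "adjust"
        keep = pd.Index(pheno["id"].astype(str)).isin([str(i) for i in geno_c.individual_ids])
        pheno = pheno.loc[keep].reset_index(drop=True)
        pheno = pheno.set_index("id").loc[[str(i) for i in geno_c.individual_ids]].reset_index()
        adjusted = preprocess.adjust_phenotype(
            pheno, factors=config.factors, covariates=config.covariates
        )
        io.write_adjusted_phenotype(adjusted, outdir / "adjusted_phenotypes.csv")
        manifest["outputs"]["adjusted_phenotypes"] = str(outdir / "adjusted_phenotypes.csv")
        manifest["stages"].append("adjust")

        stage = "validate"
        if config.validation.scheme == "kfold":
            plan = validation.kfold_split(
                geno_c.individual_ids, k=config.validation.k, seed=config.seed
            )
        else:
            if config.validation.cutoff_year is None:
                raise ConfigError("generation scheme needs validation.cutoff_year")
            if geno_c.birth_year is None:
                years = pheno["birth_year"].to_numpy()
            else:
                years = geno_c.birth_year
            plan = validation.generation_split(years, config.validation.cutoff_year)

        methods = []
        if config.gblup.enabled:
            methods.append(validation.MethodSpec("gblup"))
        if config.bayesb.enabled:
            methods.append(
                validation.MethodSpec(
                    "bayesb",
                    {
                        "n_iter": config.bayesb.n_iter,
                        "burn_in": config.bayesb.burn_in,
                        "thin": config.bayesb.thin,
                        "pi_null": config.bayesb.pi_null,
                        "seed": config.seed,
                    },
                )
            )
        if config.en.enabled:
            methods.append(
                validation.MethodSpec(
                    "en",
                    {
                        "alpha": config.en.alpha,
                        "n_lambda": config.en.n_lambda,
                        "criterion": config.en.criterion,
                        "cv_folds": config.en.cv_folds,
                        "seed": config.seed,
                    },
                )
            )
        if not methods:
            raise ConfigError("no prediction method enabled")

        reports = validation.run_comparison(geno_c, adjusted.y_star, methods, plan)
        io.write_accuracy_reports(reports, outdir / "accuracy_report.csv")
        manifest["outputs"]["accuracy_report"] = str(outdir / "accuracy_report.csv")
        manifest["stages"].append("validate")

        manifest["status"] = "ok"
        io.write_json(manifest, outdir / "MANIFEST.json")
        return manifest
    except GenopredError as exc:
        _finish(stage, exc)
        raise
    except Exception as exc:  # pragma: no cover - unexpected failure path
        _finish(stage, exc)
        raise
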