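# genopred

Genomic prediction toolkit for additive SNP traits: data simulation, SNP and
sample quality control, fixed-effect phenotype adjustment, GBLUP / RR-BLUP
with profile-REML variance components, BayesB spike-and-slab MCMC,
elastic-net coordinate descent with cross-validated lambda selection, and
k-fold / generation validation with Pearson and realized accuracy.

## Layout

| module | purpose |
|---|---|
| `genopred.synthio` | simulate genotype panels (Hardy-Weinberg, uniform MAF), trait architectures (polygenic / sparse with null proportion), fixed effects and phenotypes at target heritability |
| `genopred.preprocess` | marker QC (call rate, MAF, Hardy-Weinberg chi-square), sample missingness filter, marker-mean imputation, OLS fixed-effect adjustment producing `y*` |
| `genopred.gblup` | genomic relationship matrix `K = ZZ'/d` with `d = tr(ZZ')/n`, 1-D profile REML on K's eigenbasis, mixed-model GBLUP and its marker-space RR-BLUP dual |
| `genopred.bayesb` | single-site MCMC with a point mass at zero (prior prob `pi`) and scaled-inverse-chi-square locus variances; posterior-mean effects and inclusion probabilities |
| `genopred.elasticnet` | cyclic coordinate descent over a warm-started lambda path; minMSE and minMSE+1SE selection by internal k-fold CV |
| `genopred.validation` | seeded k-fold and birth-year generation splits, Pearson accuracy, realized accuracy `r / sqrt(h2)`, multi-method comparison on identical folds |
| `genopred.io` / `genopred.config` / `genopred.pipeline` / `genopred.cli` | text-format readers/writers (TSV genotypes, CSV phenotypes/results), strict YAML config, end-to-end pipeline with MANIFEST, `click` CLI |

Genotypes are coded additively as `1 / 0 / -1` (two / one / zero copies of
the major allele) with `NA` for missing; a PLINK-style `0/1/2` dialect is
read by subtracting 1. The numerical kernels (MCMC sweep, coordinate
descent) are jitted with numba when available and fall back to pure Python.

## CLI

```sh
genopred simulate --n 500 --m 1000 --h2 0.5 --seed 1 --out sim/
genopred qc sim/genotypes.tsv --out qc/
genopred adjust sim/phenotypes.csv --out ystar.csv
genopred fit qc/genotypes_qc.tsv ystar.csv --method gblup --out fit/
genopred cv qc/genotypes_qc.tsv ystar.csv --methods gblup,en --alpha 0.001 --out acc.csv
genopred genval qc/genotypes_qc.tsv ystar.csv --cutoff-year 2013 --out gen.csv
genopred run --config configs/smoke.yaml --seed 3 --out run_out/
genopred report acc.csv
```

`genopred run` executes the full configured pipeline
(simulate → QC → adjust → compare) and writes `qc_report.csv`,
`adjusted_phenotypes.csv`, `accuracy_report.csv`, the resolved config and a
`MANIFEST.json` with input checksums. Identical config + seed reproduces
byte-identical reports.

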