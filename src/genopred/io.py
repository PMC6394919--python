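"""Readers and writers for the plain-text data formats.

Genotypes travel as TSV: rows are individuals (first column ``id``), columns
are marker ids, entries -1/0/1 with NA for missing. The PLINK-style additive
dialect codes 0/1/2 and is mapped to the internal coding by subtracting 1.
All result tables are CSV with headers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from .datatypes import AdjustedPhenotype, GenotypeMatrix, GEBVVector, KinshipMatrix
from .exceptions import ParseError

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_adjusted_phenotype",
    "write_kinship",
    "write_gebv",
    "write_accuracy_reports",
    "write_json",
]

_ALPHABETS = {"tsv": (-1.0, 0.0, 1.0), "plink_additive": (0.0, 1.0, 2.0)}


def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype table; ``dialect`` is "tsv" (-1/0/1) or "plink_additive" (0/1/2)."""
    if dialect not in _ALPHABETS:
        raise ParseError(f"unknown genotype dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=str)
    allowed = _ALPHABETS[dialect]
    raw = df.to_numpy(dtype=object)
    missing = pd.isna(raw)
    flat = pd.to_numeric(pd.Series(raw.ravel()), errors="coerce").to_numpy(dtype=float)
    values = flat.reshape(raw.shape)

    bad = (np.isnan(values) & ~missing) | (~np.isnan(values) & ~np.isin(values, allowed))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: genotype {raw[i, j]!r} outside alphabet {allowed} "
            f"at data row {i + 1}, column {df.columns[j]}"
        )
    if dialect == "plink_additive":
        values = values - 1.0
    return GenotypeMatrix(
        values=values,
        individual_ids=df.index.to_numpy(dtype=object),
        marker_ids=df.columns.to_numpy(dtype=object),
    )


def write_genotypes(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        g.values, index=pd.Index(g.individual_ids, name="id"), columns=g.marker_ids
    )
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ParseError(f"{path}: phenotype CSV must contain an 'id' column")
    df["id"] = df["id"].astype(str)
    return df


def write_adjusted_phenotype(adj: AdjustedPhenotype, path) -> None:
    pd.DataFrame({"id": adj.ids, "y_star": adj.y_star}).to_csv(path, index=False)


def write_kinship(K: KinshipMatrix, path) -> None:
    df = pd.DataFrame(K.K, index=pd.Index(K.individual_ids, name="id"), columns=K.individual_ids)
    df.to_csv(path)


def write_gebv(gebv: GEBVVector, path) -> None:
    pd.DataFrame({"id": gebv.individual_ids, "gebv": gebv.values}).to_csv(path, index=False)


def write_accuracy_reports(reports: Dict[str, "object"], path) -> None:
    rows = [r.to_dict() for r in reports.values()]
    for row in rows:
        row["fold_r"] = ";".join(f"{v:.10g}" for v in row["fold_r"])
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
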