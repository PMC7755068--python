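"""Readers and writers for the package's plain-text exchange formats.

Conventions: CSV with header rows, missing-value token ``NA``. Marker
matrices are lines x markers with an index column ``line``; pedigrees are
``line,parent1,parent2`` with empty cells for unknown parents; phenotype
records are long-format ``line,environment,replicate,trait,value``; genetic
maps are ``marker,chromosome,cM,Mb``; kernels are labeled square CSV
matrices. A HapMap-like tab-separated genotype format (``rs#``, ``alleles``,
``chrom``, ``pos``, then one column per line with two-letter genotypes) is
also read and written; the dose counts copies of the second listed allele.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    Kernel,
    MarkerMatrix,
    Pedigree,
    validate_map,
    validate_records,
)
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

NA = "NA"


# -- marker matrices --------------------------------------------------------

def write_marker_matrix(m: MarkerMatrix, path) -> None:
    df = m.to_frame()
    df.index.name = "line"
    df.to_csv(path, na_rep=NA)


def read_marker_matrix(path, fmt: str = "csv") -> MarkerMatrix:
    """Read a marker matrix from CSV (default) or HapMap-like text."""
    if fmt == "csv":
        df = pd.read_csv(path, index_col="line", na_values=[NA])
        return MarkerMatrix(
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
            df.to_numpy(dtype=float),
        )
    if fmt == "hapmap":
        return _read_hapmap(path)
    raise ValidationError(f"unknown marker format {fmt!r}")


def _read_hapmap(path) -> MarkerMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["rs#", "alleles", "chrom", "pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"HapMap-like file missing columns: {missing}")
    line_cols = [c for c in df.columns if c not in required]
    markers, rows = [], []
    for ln, row in df.iterrows():
        alleles = str(row["alleles"]).split("/")
        if len(alleles) != 2 or alleles[0] == alleles[1]:
            logger.warning("row %d (%s): non-biallelic alleles %r skipped",
                           ln + 2, row["rs#"], row["alleles"])
            continue
        a, b = alleles
        doses = []
        for c in line_cols:
            call = row[c]
            if pd.isna(call) or call in (NA, "NN", "--"):
                doses.append(np.nan)
                continue
            call = str(call)
            if len(call) != 2 or any(ch not in (a, b) for ch in call):
                raise ValidationError(
                    f"row {ln + 2} ({row['rs#']}): malformed call {call!r} "
                    f"for alleles {a}/{b}"
                )
            doses.append(float(call.count(b)))
        markers.append(str(row["rs#"]))
        rows.append(doses)
    return MarkerMatrix(
        np.asarray(line_cols, dtype=object),
        np.asarray(markers, dtype=object),
        np.asarray(rows, dtype=float).T if rows else np.empty((len(line_cols), 0)),
    )


def write_hapmap(m: MarkerMatrix, path, alleles: str = "A/G") -> None:
    """Write a HapMap-like file (dose = copies of the second allele)."""
    a, b = alleles.split("/")
    lut = {0.0: a + a, 1.0: a + b, 2.0: b + b}
    with open(path, "w") as fh:
        fh.write("\t".join(["rs#", "alleles", "chrom", "pos",
                            *map(str, m.line_ids)]) + "\n")
        for j, mk in enumerate(m.marker_ids):
            calls = [NA if np.isnan(d) else lut[round(d)]
                     for d in m.doses[:, j]]
            fh.write("\t".join([str(mk), alleles, "1", str(j + 1), *calls]) + "\n")


# -- pedigree, phenotypes, map ----------------------------------------------

def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("line", "parent1", "parent2"):
        if col not in df.columns:
            raise ValidationError(f"pedigree file missing column {col!r}")
    return Pedigree(df["line"], df["parent1"], df["parent2"])


def write_phenotypes(records: pd.DataFrame, path) -> None:
    validate_records(records).to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"line": str, "environment": str,
                                  "replicate": str, "trait": str})
    try:
        return validate_records(df)
    except ValidationError:
        # locate the offending cell for a useful message
        for i, v in enumerate(df.get("value", [])):
            try:
                float(v)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric phenotype value {v!r} at data row {i + 1}"
                ) from None
        raise


def write_map(gmap: pd.DataFrame, path) -> None:
    validate_map(gmap).to_csv(path, index=False)


def read_map(path) -> pd.DataFrame:
    return validate_map(pd.read_csv(path, dtype={"marker": str,
                                                 "chromosome": str}))


# -- kernels -----------------------------------------------------------------

def write_kernel(k: Kernel, path) -> None:
    df = k.to_frame()
    df.index.name = "id"
    df.to_csv(path)


def read_kernel(path, kind: str = "genomic") -> Kernel:
    df = pd.read_csv(path, index_col="id")
    return Kernel(df.index.to_numpy(dtype=object), df.to_numpy(dtype=float),
                  kind=kind)
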