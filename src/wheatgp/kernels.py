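"""Relationship kernels: marker QC, genomic G, pedigree A, incidence and
record-level interaction covariances.

The genomic relationship matrix follows the centered allele-dose
construction: with doses x_im and counted-allele frequency p_m, the centered
matrix X has entries x_im - 2 p_m and

    G = X X' / c,   c = 2 * sum_m 2 p_m (1 - p_m)      (scale="printed")
                    c =     sum_m 2 p_m (1 - p_m)      (scale="vanraden")

The "printed" denominator is the form the source analysis states; the
"vanraden" form is the common scaling under which the mean diagonal is ~1
and variance components attached to G live on the trait scale.

The pedigree additive relationship matrix A uses the tabular method with
unknown parents treated as unrelated, non-inbred founders.

Genotype-by-environment covariance structures are Hadamard products of the
line-level kernel expanded to records with the environment incidence
product: (Z_L K Z_L') o (Z_E Z_E'). The Schur product theorem keeps these
PSD.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import IncidenceMaps, Kernel, MarkerMatrix, Pedigree, validate_map
from .exceptions import (
    DegenerateKernelError,
    MappingError,
    ValidationError,
)

logger = logging.getLogger(__name__)


def filter_markers(m: MarkerMatrix, maf_min: float = 0.05,
                   max_missing: float = 0.5,
                   gmap: pd.DataFrame | None = None) -> MarkerMatrix:
    """Marker quality control.

    Retains markers that are polymorphic (more than one genotype class among
    non-missing calls and a segregating allele), have missing fraction
    <= ``max_missing``, MAF >= ``maf_min`` (frequencies computed on
    non-missing calls; the boundary value is retained because the stated
    rule removes markers strictly below the threshold), and, when a genetic
    map is supplied, appear in the map. Marker order is preserved.
    """
    p = m.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    with np.errstate(invalid="ignore"):
        varying = np.nanmax(
            np.where(np.isnan(m.doses), -np.inf, m.doses), axis=0
        ) > np.nanmin(np.where(np.isnan(m.doses), np.inf, m.doses), axis=0)
        keep = (maf > 0) & varying & (m.missing_fraction() <= max_missing) \
            & (maf >= maf_min)
    keep &= ~np.isnan(p)
    if gmap is not None:
        mapped = set(validate_map(gmap)["marker"])
        keep &= np.array([mk in mapped for mk in m.marker_ids])
    if not keep.any():
        logger.warning("marker QC removed every marker; empty panel returned")
    return m.subset_markers(keep)


def impute_missing(m: MarkerMatrix) -> MarkerMatrix:
    """Replace missing doses by the per-marker mean dose 2 p_m."""
    fully_missing = np.flatnonzero(np.all(m.missing_mask, axis=0))
    if fully_missing.size:
        raise ValidationError(
            f"markers entirely missing: {list(m.marker_ids[fully_missing[:5]])}"
        )
    doses = m.doses.copy()
    mean_dose = 2.0 * m.allele_freq()
    idx = np.where(m.missing_mask)
    doses[idx] = mean_dose[idx[1]]
    return MarkerMatrix(m.line_ids, m.marker_ids, doses)


def genomic_relationship(m: MarkerMatrix, scale: str = "printed") -> Kernel:
    """Genomic relationship matrix from centered allele doses.

    ``scale="printed"`` divides X X' by 2 * sum 2p(1-p); ``"vanraden"`` by
    sum 2p(1-p). Doses must be imputed first.
    """
    if m.missing_mask.any():
        raise ValidationError("impute missing doses before building G")
    p = m.allele_freq()
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise DegenerateKernelError("all markers monomorphic; G undefined")
    X = m.doses[:, poly] - 2.0 * p[poly]
    het = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    if scale == "printed":
        denom = 2.0 * het
    elif scale == "vanraden":
        denom = het
    else:
        raise ValueError(f"unknown scale {scale!r}")
    G = (X @ X.T) / denom
    return Kernel(m.line_ids, (G + G.T) / 2.0, kind="genomic")


def pedigree_additive_matrix(ped: Pedigree) -> Kernel:
    """Numerator relationship matrix A by the tabular method.

    Founders (unknown parents) are unrelated and non-inbred. For line k with
    parents (f, m): A_kj = 0.5 (A_fj + A_mj) for earlier j, and
    A_kk = 1 + 0.5 A_fm; a single unknown parent contributes zero.
    """
    n = len(ped)
    A = np.zeros((n, n))
    for k in range(n):
        f = ped.parent1[k]
        m = ped.parent2[k]
        fi = ped.index_of(f) if f is not None else None
        mi = ped.index_of(m) if m is not None else None
        for j in range(k):
            a = 0.0
            if fi is not None:
                a += 0.5 * A[fi, j]
            if mi is not None:
                a += 0.5 * A[mi, j]
            A[k, j] = A[j, k] = a
        A[k, k] = 1.0 + (0.5 * A[fi, mi] if fi is not None and mi is not None else 0.0)
    return Kernel(np.asarray(ped.lines, dtype=object), A, kind="pedigree")


def incidence_matrices(records: pd.DataFrame, line_ids=None,
                       env_ids=None) -> IncidenceMaps:
    """One-hot record-to-line (Z_L) and record-to-environment (Z_E) maps.

    Column orders default to sorted unique values; pass explicit id lists to
    align columns with a kernel.
    """
    lines = records["line"].to_numpy()
    envs = records["environment"].to_numpy()
    if line_ids is None:
        line_ids = np.array(sorted(set(lines)), dtype=object)
    else:
        line_ids = np.asarray(list(line_ids), dtype=object)
    if env_ids is None:
        env_ids = np.array(sorted(set(envs)), dtype=object)
    else:
        env_ids = np.asarray(list(env_ids), dtype=object)
    lpos = {l: i for i, l in enumerate(line_ids)}
    epos = {e: i for i, e in enumerate(env_ids)}
    unknown = sorted({l for l in lines if l not in lpos})
    if unknown:
        raise MappingError(f"records reference unknown lines: {unknown[:5]}")
    unknown_env = sorted({e for e in envs if e not in epos})
    if unknown_env:
        raise MappingError(f"records reference unknown environments: {unknown_env[:5]}")
    n = len(records)
    Z_L = np.zeros((n, len(line_ids)))
    Z_E = np.zeros((n, len(env_ids)))
    Z_L[np.arange(n), [lpos[l] for l in lines]] = 1.0
    Z_E[np.arange(n), [epos[e] for e in envs]] = 1.0
    return IncidenceMaps(Z_L=Z_L, Z_E=Z_E, line_ids=line_ids, env_ids=env_ids)


def expand_to_records(k: Kernel, inc: IncidenceMaps) -> np.ndarray:
    """Record-level main-effect covariance Z_L K Z_L'."""
    if list(k.ids) != list(inc.line_ids):
        aligned = k.align(inc.line_ids)
    else:
        aligned = k
    return inc.Z_L @ aligned.values @ inc.Z_L.T


def interaction_kernel(k: Kernel, inc: IncidenceMaps) -> Kernel:
    """Record-level interaction covariance (Z_L K Z_L') o (Z_E Z_E').

    Entries between records in different environments are exactly zero.
    """
    main = expand_to_records(k, inc)
    same_env = inc.Z_E @ inc.Z_E.T
    vals = main * same_env
    ids = np.array([f"rec{i}" for i in range(vals.shape[0])], dtype=object)
    return Kernel(ids, (vals + vals.T) / 2.0, kind="record-level")
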