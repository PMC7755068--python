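"""Core in-memory containers.

The package exchanges four kinds of tabular data:

* :class:`MarkerMatrix` — lines × markers allele doses (0/1/2, NaN = missing),
* :class:`Pedigree` — line / parent1 / parent2 records, parents before
  offspring,
* phenotype records — a plain long-format :class:`pandas.DataFrame` with
  columns ``line, environment, replicate, trait, value`` (validated by
  :func:`validate_records`),
* :class:`Kernel` — a labeled symmetric relationship matrix (genomic,
  pedigree, or record-level).

Genetic maps are plain DataFrames with columns
``marker, chromosome, cM, Mb`` (see :func:`validate_map`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DimensionError,
    PedigreeCycleError,
    ValidationError,
)

RECORD_COLUMNS = ["line", "environment", "replicate", "trait", "value"]
MAP_COLUMNS = ["marker", "chromosome", "cM", "Mb"]


@dataclass
class MarkerMatrix:
    """Allele-dose matrix with a missing mask and per-marker frequencies.

    Parameters
    ----------
    line_ids : array of str
        Row labels, one per line.
    marker_ids : array of str
        Column labels, one per marker.
    doses : ndarray of float, shape (n_lines, n_markers)
        Counted-allele doses in {0, 1, 2}; ``NaN`` marks missing calls.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    doses: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.shape != (len(self.line_ids), len(self.marker_ids)):
            raise DimensionError(
                f"doses shape {self.doses.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValidationError("duplicate line identifiers")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("duplicate marker identifiers")
        finite = self.doses[~np.isnan(self.doses)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValidationError("doses must lie in [0, 2]")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.doses)

    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency p_m per marker over non-missing calls.

        Markers that are entirely missing get frequency ``NaN``.
        """
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.doses, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def subset_markers(self, keep: np.ndarray) -> "MarkerMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {m: i for i, m in enumerate(self.marker_ids)}
            idx = np.array([pos[m] for m in keep], dtype=int)
        return MarkerMatrix(self.line_ids, self.marker_ids[idx], self.doses[:, idx])

    def subset_lines(self, lines) -> "MarkerMatrix":
        pos = {l: i for i, l in enumerate(self.line_ids)}
        idx = np.array([pos[l] for l in lines], dtype=int)
        return MarkerMatrix(self.line_ids[idx], self.marker_ids, self.doses[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.doses, index=self.line_ids, columns=self.marker_ids)


class Pedigree:
    """Ordered pedigree; founders first, every parent precedes its offspring.

    Unknown parents are ``None``. Construction validates acyclicity and
    reorders rows topologically, so downstream consumers (tabular A matrix,
    gene dropping) can run a single forward pass.
    """

    def __init__(self, lines, parent1, parent2):
        lines = list(lines)
        parent1 = [None if _is_missing(p) else p for p in parent1]
        parent2 = [None if _is_missing(p) else p for p in parent2]
        if len(set(lines)) != len(lines):
            raise ValidationError("duplicate line identifiers in pedigree")
        known = set(lines)
        bad = sorted(
            {p for p in parent1 + parent2 if p is not None and p not in known}
        )
        if bad:
            raise ValidationError(f"parents not declared as lines: {bad}")
        order = _toposort(lines, parent1, parent2)
        self.lines = [lines[i] for i in order]
        self.parent1 = [parent1[i] for i in order]
        self.parent2 = [parent2[i] for i in order]
        self._index = {l: i for i, l in enumerate(self.lines)}

    def __len__(self) -> int:
        return len(self.lines)

    def index_of(self, line) -> int:
        return self._index[line]

    def is_founder(self, line) -> bool:
        i = self._index[line]
        return self.parent1[i] is None and self.parent2[i] is None

    @property
    def founders(self):
        return [l for l in self.lines if self.is_founder(l)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "line": self.lines,
                "parent1": [p if p is not None else "" for p in self.parent1],
                "parent2": [p if p is not None else "" for p in self.parent2],
            }
        )


def _is_missing(p) -> bool:
    return p is None or (isinstance(p, float) and np.isnan(p)) or p == ""


def _toposort(lines, parent1, parent2):
    """Stable Kahn topological order (original order preserved when the
    input is already topological); raises PedigreeCycleError on a cycle."""
    import heapq

    n = len(lines)
    idx = {l: i for i, l in enumerate(lines)}
    children = [[] for _ in range(n)]
    indeg = [0] * n
    for i in range(n):
        for p in (parent1[i], parent2[i]):
            if p is not None:
                children[idx[p]].append(i)
                indeg[i] += 1
    heap = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        i = heapq.heappop(heap)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    if len(order) != n:
        cycle = [lines[i] for i in range(n) if indeg[i] > 0]
        raise PedigreeCycleError(f"pedigree contains a cycle among: {cycle}")
    return order


@dataclass
class Kernel:
    """Symmetric PSD relationship matrix with row/column labels.

    ``kind`` distinguishes line-level genomic ("genomic") and pedigree
    ("pedigree") kernels from record-level covariance structures
    ("record-level").
    """

    ids: np.ndarray
    values: np.ndarray
    kind: str = "genomic"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DimensionError(
                f"kernel values {self.values.shape} do not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("kernel matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def min_eigenvalue_ratio(self) -> float:
        """Smallest eigenvalue relative to the largest (PSD check)."""
        w = np.linalg.eigvalsh((self.values + self.values.T) / 2.0)
        top = max(w.max(), np.finfo(float).tiny)
        return float(w.min() / top)

    def is_psd(self, rel_tol: float = 1e-8) -> bool:
        return self.min_eigenvalue_ratio() >= -rel_tol

    def align(self, ids) -> "Kernel":
        """Reorder/subset to the given ids (all must be present)."""
        pos = {l: i for i, l in enumerate(self.ids)}
        try:
            idx = np.array([pos[l] for l in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise ValidationError(f"id {e.args[0]!r} absent from kernel") from e
        return Kernel(np.asarray(list(ids), dtype=object),
                      self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class IncidenceMaps:
    """Record-level one-hot incidence matrices Z_L (lines) and Z_E (envs)."""

    Z_L: np.ndarray
    Z_E: np.ndarray
    line_ids: np.ndarray = field(default_factory=lambda: np.array([]))
    env_ids: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        for name, Z in (("Z_L", self.Z_L), ("Z_E", self.Z_E)):
            sums = np.asarray(Z).sum(axis=1)
            if not np.all(sums == 1):
                raise ValidationError(f"{name} rows must contain exactly one 1")


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format phenotype table and return it (copy, typed).

    Required columns: ``line, environment, replicate, trait, value``.
    Duplicate (line, environment, replicate, trait) rows are an error;
    values must be numeric.
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"phenotype records missing columns: {missing}")
    out = records.loc[:, RECORD_COLUMNS].copy()
    try:
        out["value"] = pd.to_numeric(out["value"])
    except (ValueError, TypeError) as e:
        raise ValidationError(f"non-numeric phenotype value: {e}") from e
    key = ["line", "environment", "replicate", "trait"]
    dup = out.duplicated(subset=key)
    if dup.any():
        rows = out.loc[dup, key].head(5).to_dict("records")
        raise ValidationError(f"duplicate phenotype records, e.g. {rows}")
    return out


def validate_map(gmap: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MAP_COLUMNS if c not in gmap.columns]
    if missing:
        raise ValidationError(f"genetic map missing columns: {missing}")
    out = gmap.loc[:, MAP_COLUMNS].copy()
    out["cM"] = pd.to_numeric(out["cM"])
    out["Mb"] = pd.to_numeric(out["Mb"])
    if (out["cM"] < 0).any() or (out["Mb"] < 0).any():
        raise ValidationError("map positions must be non-negative")
    if out["marker"].duplicated().any():
        raise ValidationError("duplicate markers in genetic map")
    return out
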