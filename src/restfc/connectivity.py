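"""Per-subject functional connectivity matrices and the group FC table.

Functional connectivity (FC) between two regions is the Pearson correlation
of their mean time courses over the full scan, mapped through the Fisher
z-transform ``z = atanh(r)`` to stabilise the variance.  With R regions the
R x R symmetric matrix carries R(R-1)/2 informative values; these are
vectorised (upper triangle, row-major) into one row per subject of the
subjects x edges group FC table that the regression stage consumes.

Edge enumeration is fixed here once and keyed on ``(edge_id, i, j)`` with
1-based region indices ``i < j`` so every downstream table is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .parcellation import ParcellationScheme

logger = logging.getLogger(__name__)

#: |r| is clipped to 1 - CLIP_EPS before atanh so perfectly correlated
#: columns yield a large finite z instead of +/-inf.
CLIP_EPS = 1e-12


def n_edges(n_regions: int) -> int:
    """Number of unordered region pairs (off-diagonal upper triangle)."""
    return n_regions * (n_regions - 1) // 2


def edge_index(n_regions: int) -> pd.DataFrame:
    """Enumerate edges as (edge_id, i, j), i < j 1-based, row-major.

    For 116 regions this yields 6670 edges; the full matrix has
    116 * 116 = 13,456 entries of which the upper triangle is kept.
    """
    iu, ju = np.triu_indices(n_regions, k=1)
    return pd.DataFrame(
        {"edge_id": np.arange(iu.size), "i": iu + 1, "j": ju + 1}
    )


def edge_labels(edges: pd.DataFrame, prefix: str = "AAL") -> list[str]:
    """Human-readable pair labels, e.g. ``AAL4—AAL87``."""
    return [f"{prefix}{i}—{prefix}{j}" for i, j in zip(edges["i"], edges["j"])]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two 1-d series (shared kernel for the package)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise ValueError("correlation undefined for a constant series")
    return float((xc @ yc) / denom)


@dataclass
class FCMatrix:
    """Symmetric R x R matrix of Fisher-z connectivity for one subject."""

    subject_id: str
    values: np.ndarray
    n_clipped: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def compute_fc(
    ts: np.ndarray, subject_id: str = "subject", clip_eps: float = CLIP_EPS
) -> FCMatrix:
    """Fisher-z FC matrix from a T x R time-series matrix.

    Entry (a, b) is atanh(r_ab) with r_ab the Pearson correlation of
    columns a and b over all T timepoints.  |r| is clipped to
    ``1 - clip_eps`` before atanh; the number of clipped off-diagonal
    entries is recorded and logged.  The diagonal is set to 0 and is
    never used downstream.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("time series must be T x R with T >= 3")
    sd = ts.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            "correlation undefined for constant region column(s): "
            + ", ".join(str(c + 1) for c in constant)
        )
    r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 0.0)
    over = np.abs(r) > 1 - clip_eps
    n_clipped = int(over.sum() // 2)
    if n_clipped:
        logger.info("clipped %d off-diagonal |r| values at 1 - %g", n_clipped, clip_eps)
    r = np.clip(r, -(1 - clip_eps), 1 - clip_eps)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return FCMatrix(subject_id=subject_id, values=z, n_clipped=n_clipped)


def reorder_and_group(fc: FCMatrix, scheme: ParcellationScheme) -> FCMatrix:
    """Permute rows/columns into the scheme's display order (lobe blocks)."""
    if scheme.n_regions != fc.n_regions:
        raise ValueError("scheme does not cover the FC matrix regions")
    perm = np.asarray(scheme.display_order) - 1
    return FCMatrix(
        subject_id=fc.subject_id,
        values=fc.values[np.ix_(perm, perm)],
        n_clipped=fc.n_clipped,
    )


def vectorize(matrix: np.ndarray) -> np.ndarray:
    """Upper-triangle (i < j, row-major) of a square matrix."""
    matrix = np.asarray(matrix)
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu, ju]


def unvectorize(edge_values: np.ndarray, n_regions: int) -> np.ndarray:
    """Inverse of :func:`vectorize`: rebuild the symmetric matrix, zero diagonal."""
    edge_values = np.asarray(edge_values, dtype=float)
    if edge_values.size != n_edges(n_regions):
        raise ValueError("edge vector length does not match n_regions")
    out = np.zeros((n_regions, n_regions))
    iu, ju = np.triu_indices(n_regions, k=1)
    out[iu, ju] = edge_values
    out[ju, iu] = edge_values
    return out


@dataclass
class GroupFCTable:
    """Subjects x edges matrix of Fisher-z FC plus the edge index map."""

    values: np.ndarray  # n_subjects x n_edges
    edges: pd.DataFrame  # edge_id, i, j
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("group FC table must be 2-d")
        if self.values.shape[1] != len(self.edges):
            raise ValueError("edge index does not match table width")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{k:04d}" for k in range(self.values.shape[0])]
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length does not match table height")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    @property
    def n_regions(self) -> int:
        # invert E = R(R-1)/2
        r = int(round((1 + np.sqrt(1 + 8 * self.n_edges)) / 2))
        if n_edges(r) != self.n_edges:
            raise ValueError("edge count is not R(R-1)/2 for any integer R")
        return r

    def subject_matrix(self, row: int) -> np.ndarray:
        """Rebuild subject ``row``'s symmetric FC matrix from its edge vector."""
        return unvectorize(self.values[row], self.n_regions)

    def to_csv(self, path: str | Path, edge_path: str | Path | None = None) -> None:
        df = pd.DataFrame(self.values, columns=edge_labels(self.edges))
        df.insert(0, "subject_id", self.subject_ids)
        df.to_csv(path, index=False)
        if edge_path is not None:
            self.edges.to_csv(edge_path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupFCTable":
        df = pd.read_csv(path)
        subject_ids = df["subject_id"].astype(str).tolist()
        values = df.drop(columns=["subject_id"]).to_numpy(dtype=float)
        r = int(round((1 + np.sqrt(1 + 8 * values.shape[1])) / 2))
        return cls(values=values, edges=edge_index(r), subject_ids=subject_ids)


def build_group_table(fcs: Sequence[FCMatrix]) -> GroupFCTable:
    """Stack per-subject FC matrices into the subjects x edges group table."""
    if not fcs:
        raise ValueError("no FC matrices supplied")
    r = fcs[0].n_regions
    for fc in fcs:
        if fc.n_regions != r:
            raise ValueError(
                f"inconsistent region count: {fc.subject_id} has {fc.n_regions}, expected {r}"
            )
    values = np.vstack([vectorize(fc.values) for fc in fcs])
    return GroupFCTable(
        values=values, edges=edge_index(r), subject_ids=[fc.subject_id for fc in fcs]
    )
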