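"""Atlas parcellation: label volumes to ROI time series, plus homogeneity QC.

A parcellation scheme assigns each of R brain regions a 1-based index, a
name, one of seven lobe labels (frontal FR, parietal PA, temporal TE,
medial temporal ME, occipital OC, subcortical SU, cerebellar CE) and a
display position, so FC matrices can be reordered into lobe blocks.

`parcellate` reduces a 4D volume to a T x R matrix of unweighted
within-region voxel means.  `roi_homogeneity` reports, per region, the
fraction of member voxels whose series correlates significantly with the
region mean — a check on whether one mean time course can represent an
anatomically defined region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LOBES = ("FR", "PA", "TE", "ME", "OC", "SU", "CE")


@dataclass
class ParcellationScheme:
    """Region indices, names, lobe assignments and display ordering."""

    table: pd.DataFrame  # columns: region_index, name, lobe, display_order

    def __post_init__(self) -> None:
        t = self.table
        required = {"region_index", "name", "lobe"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"scheme table missing columns: {sorted(missing)}")
        idx = np.sort(t["region_index"].to_numpy())
        r = len(t)
        if not np.array_equal(idx, np.arange(1, r + 1)):
            raise ValueError("region indices must be unique and contiguous 1..R")
        bad = set(t["lobe"]) - set(LOBES)
        if bad:
            raise ValueError(f"unknown lobe label(s): {sorted(bad)}")
        if "display_order" not in t.columns:
            t = t.copy()
            t["display_order"] = t["region_index"]
            self.table = t
        order = np.sort(self.table["display_order"].to_numpy())
        if not np.array_equal(order, np.arange(1, r + 1)):
            raise ValueError("display_order must be a permutation of 1..R")
        self.table = self.table.sort_values("region_index").reset_index(drop=True)

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def region_indices(self) -> np.ndarray:
        return self.table["region_index"].to_numpy()

    @property
    def display_order(self) -> np.ndarray:
        """Region indices in display position order (position k holds region display_order^-1(k))."""
        t = self.table.sort_values("display_order")
        return t["region_index"].to_numpy()

    def lobe_of(self, region_index: int) -> str:
        row = self.table.loc[self.table["region_index"] == region_index]
        return str(row["lobe"].iloc[0])

    @property
    def lobes_in_display_order(self) -> np.ndarray:
        t = self.table.set_index("region_index")
        return t.loc[self.display_order, "lobe"].to_numpy()

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParcellationScheme":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def synthetic(cls, n_regions: int) -> "ParcellationScheme":
        """Even lobe blocks in index order; used by the cohort simulator."""
        sizes = np.full(len(LOBES), n_regions // len(LOBES))
        sizes[: n_regions % len(LOBES)] += 1
        lobes = np.repeat(LOBES, sizes)[:n_regions]
        return cls(
            pd.DataFrame(
                {
                    "region_index": np.arange(1, n_regions + 1),
                    "name": [f"region_{k}" for k in range(1, n_regions + 1)],
                    "lobe": lobes,
                    "display_order": np.arange(1, n_regions + 1),
                }
            )
        )


@dataclass
class ROITimeSeries:
    """One subject's T x R matrix of region-mean signals."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("time series must be 2-d (timepoints x regions)")
        if not np.isfinite(v).all():
            raise ValueError("time series contains non-finite values")
        self.values = v

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter="\t")

    @classmethod
    def from_csv(cls, path: str | Path, subject_id: str | None = None) -> "ROITimeSeries":
        return cls(subject_id or Path(path).stem, np.loadtxt(path, delimiter="\t"))


def load_nifti(path: str | Path) -> np.ndarray:
    """Read a NIfTI volume into a float array (4D data or 3D labels)."""
    import nibabel as nib

    return np.asanyarray(nib.load(str(path)).dataobj)


def parcellate(
    volume4d: np.ndarray,
    labels: np.ndarray,
    scheme: ParcellationScheme,
    subject_id: str = "subject",
) -> ROITimeSeries:
    """Average the 4D signal over voxels of each labelled region.

    Column r (in region-index order) is the unweighted mean across voxels
    carrying label r at each timepoint.  Voxels labelled 0 (background) or
    with labels absent from the scheme are ignored with a logged count.
    """
    volume4d = np.asarray(volume4d, dtype=float)
    labels = np.asarray(labels)
    if volume4d.ndim != 4:
        raise ValueError("expected a 4D volume (x, y, z, t)")
    if labels.shape != volume4d.shape[:3]:
        raise ValueError(
            f"label volume shape {labels.shape} does not match data {volume4d.shape[:3]}"
        )
    flat_labels = labels.reshape(-1)
    flat_data = volume4d.reshape(-1, volume4d.shape[3])

    known = set(int(v) for v in scheme.region_indices)
    present = set(int(v) for v in np.unique(flat_labels)) - {0}
    ignored = present - known
    if ignored:
        n_ignored = int(np.isin(flat_labels, sorted(ignored)).sum())
        logger.warning(
            "ignoring %d voxel(s) with label(s) outside the scheme: %s",
            n_ignored,
            sorted(ignored),
        )
    empty = [r for r in sorted(known) if r not in present]
    if empty:
        raise ValueError(f"region(s) with zero voxels: {empty}")

    out = np.empty((volume4d.shape[3], scheme.n_regions))
    for col, region in enumerate(scheme.region_indices):
        mask = flat_labels == region
        out[:, col] = flat_data[mask].mean(axis=0)
    return ROITimeSeries(subject_id=subject_id, values=out)


@dataclass
class HomogeneityReport:
    """Per-region fraction of voxels significantly correlated with the region mean."""

    fractions: pd.DataFrame  # region_index, n_voxels, fraction_significant
    n_regions_majority: int  # regions with fraction > 0.5
    alpha: float

    def summary(self) -> str:
        r = len(self.fractions)
        pct = 100.0 * self.n_regions_majority / r
        return (
            f"{self.n_regions_majority} of {r} regions ({pct:.0f}%) have more than "
            f"50% of voxels significantly correlated (p < {self.alpha:g}) with the region mean"
        )


def roi_homogeneity(
    volume4d: np.ndarray,
    labels: np.ndarray,
    scheme: ParcellationScheme,
    alpha: float = 0.05,
    exclude_self: bool = False,
) -> HomogeneityReport:
    """Test each voxel's correlation with its region-mean time course.

    Two-sided t-test on Pearson r with T-2 degrees of freedom.  By default
    the voxel's own contribution to the mean is kept (`exclude_self=True`
    removes it, a leave-one-out variant).  Constant voxel series have an
    undefined correlation; they are counted as non-significant and logged.
    """
    volume4d = np.asarray(volume4d, dtype=float)
    labels = np.asarray(labels)
    t_len = volume4d.shape[3]
    if t_len < 4:
        raise ValueError("homogeneity test needs at least 4 timepoints")
    flat_labels = labels.reshape(-1)
    flat_data = volume4d.reshape(-1, t_len)

    rows = []
    n_constant = 0
    for region in scheme.region_indices:
        voxels = flat_data[flat_labels == region]
        if voxels.shape[0] == 0:
            raise ValueError(f"region {region} has zero voxels")
        mean_series = voxels.mean(axis=0)
        m = voxels.shape[0]
        n_sig = 0
        for k in range(m):
            series = voxels[k]
            ref = mean_series
            if exclude_self and m > 1:
                ref = (mean_series * m - series) / (m - 1)
            if series.std() == 0 or ref.std() == 0:
                n_constant += 1
                continue
            r = np.corrcoef(series, ref)[0, 1]
            r = float(np.clip(r, -1.0, 1.0))
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((t_len - 2) / (1 - r * r))
                p = 2 * stats.t.sf(abs(t), df=t_len - 2)
            if p < alpha:
                n_sig += 1
        rows.append(
            {
                "region_index": int(region),
                "n_voxels": m,
                "fraction_significant": n_sig / m,
            }
        )
    if n_constant:
        logger.warning("%d constant voxel series counted as non-significant", n_constant)
    fractions = pd.DataFrame(rows)
    majority = int((fractions["fraction_significant"] > 0.5).sum())
    return HomogeneityReport(fractions=fractions, n_regions_majority=majority, alpha=alpha)
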