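"""Male-vs-female comparison of graph measures across the density grid.

Nodal metrics (clustering, local efficiency) are compared per node and
density with two-sample t-tests; only differences passing the nodal
multiple-comparison threshold p < alpha / R enter the signed-significance
stack sign(t) * (-log10 p), summed over densities per node — positive
stacks mean male > female.  Global metrics (largest component size,
normalised C and L, small-worldness) are compared per density.  A
regression variant adjusts the sex contrast for age, and head-motion
checks guard against a frame-displacement confound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import pearson_r
from .regression import fit_ols, sex_indicator

NODAL_METRICS = ("clustering", "local_efficiency")
GLOBAL_METRICS = ("largest_component", "C_norm", "L_norm", "sigma")


def two_sample_t(
    x: np.ndarray, y: np.ndarray, variant: str = "student"
) -> tuple[float, float, float]:
    """Two-sample t-test of x vs y: returns (t, dof, two-sided p).

    ``student`` pools variances; ``welch`` does not.  Zero variance in
    both groups with equal means gives t = 0, p = 1; zero pooled variance
    with unequal means is an error (infinite t).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant: {variant}")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class GroupComparisonTables:
    """Per-cell comparisons plus the per-node stacked summary."""

    cells: pd.DataFrame  # metric, node, density, means, sds, t, p, signed, sig
    stacks: pd.DataFrame  # metric, node, stack (sum of significant signed values)
    alpha: float
    nodal_threshold: float


def _signed_significance(t: float, p: float) -> float:
    p = max(p, 1e-300)
    return float(np.sign(t) * (-np.log10(p)))


def nodal_metric_comparison(
    nodal: pd.DataFrame,
    cohort: pd.DataFrame,
    metric: str,
    alpha: float = 0.05,
    variant: str = "student",
) -> GroupComparisonTables:
    """t-test male vs female per node x density; stack significant signed values.

    The stack for a node sums sign(t) * (-log10 p) over every density where
    p < alpha / R; above zero means male > female.
    """
    if metric not in nodal.columns:
        raise ValueError(f"unknown nodal metric: {metric}")
    sex = dict(zip(cohort["subject_id"].astype(str), sex_indicator(cohort)))
    df = nodal.copy()
    df["male"] = df["subject_id"].astype(str).map(sex)
    if df["male"].isna().any():
        raise ValueError("metrics table contains subjects missing from the cohort")
    nodes = np.sort(df["node"].unique())
    densities = np.sort(df["density"].unique())
    r = nodes.size
    threshold = alpha / r
    rows = []
    for node in nodes:
        sub = df[df["node"] == node]
        for density in densities:
            cell = sub[sub["density"] == density]
            males = cell.loc[cell["male"] == 1, metric].to_numpy()
            females = cell.loc[cell["male"] == 0, metric].to_numpy()
            if males.size < 2 or females.size < 2:
                raise ValueError(
                    f"density {density} lacks both sexes for node {node}"
                )
            t, _, p = two_sample_t(males, females, variant=variant)
            rows.append(
                {
                    "metric": metric,
                    "node": int(node),
                    "density": float(density),
                    "mean_male": males.mean(),
                    "sd_male": males.std(ddof=1),
                    "mean_female": females.mean(),
                    "sd_female": females.std(ddof=1),
                    "t": t,
                    "p": p,
                    "signed_significance": _signed_significance(t, p),
                    "significant": p < threshold,
                }
            )
    cells = pd.DataFrame(rows)
    sig = cells[cells["significant"]]
    stacks = (
        sig.groupby("node")["signed_significance"].sum().reindex(nodes, fill_value=0.0)
    )
    stacks = stacks.rename("stack").reset_index()
    stacks.insert(0, "metric", metric)
    return GroupComparisonTables(
        cells=cells, stacks=stacks, alpha=alpha, nodal_threshold=threshold
    )


def global_metric_comparison(
    global_df: pd.DataFrame,
    cohort: pd.DataFrame,
    metric: str,
    alpha: float = 0.05,
    variant: str = "student",
) -> pd.DataFrame:
    """Male-vs-female t-test of one global metric at each density."""
    if metric not in global_df.columns:
        raise ValueError(f"unknown global metric: {metric}")
    sex = dict(zip(cohort["subject_id"].astype(str), sex_indicator(cohort)))
    df = global_df.copy()
    df["male"] = df["subject_id"].astype(str).map(sex)
    rows = []
    for density in np.sort(df["density"].unique()):
        cell = df[df["density"] == density].dropna(subset=[metric])
        males = cell.loc[cell["male"] == 1, metric].to_numpy()
        females = cell.loc[cell["male"] == 0, metric].to_numpy()
        if males.size < 2 or females.size < 2:
            raise ValueError(f"density {density} lacks both sexes")
        t, dof, p = two_sample_t(males, females, variant=variant)
        rows.append(
            {
                "metric": metric,
                "density": float(density),
                "mean_male": males.mean(),
                "sd_male": males.std(ddof=1),
                "mean_female": females.mean(),
                "sd_female": females.std(ddof=1),
                "t": t,
                "df": dof,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def metric_regression(
    metrics_df: pd.DataFrame,
    cohort: pd.DataFrame,
    metric: str,
    by_node: bool = False,
) -> pd.DataFrame:
    """OLS of a graph metric on sex + age, per density (and node).

    Confirms that two-sample sex contrasts are not driven by age: the sex
    coefficient is the adjusted male-minus-female difference.
    """
    sex = dict(zip(cohort["subject_id"].astype(str), sex_indicator(cohort)))
    age = dict(
        zip(cohort["subject_id"].astype(str), cohort["age_years"].astype(float))
    )
    df = metrics_df.copy()
    ids = df["subject_id"].astype(str)
    df["male"] = ids.map(sex)
    df["age"] = ids.map(age)
    group_cols = ["density", "node"] if by_node else ["density"]
    rows = []
    for keys, cell in df.groupby(group_cols):
        cell = cell.dropna(subset=[metric])
        y = cell[metric].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(cell)), cell["male"].to_numpy(), cell["age"].to_numpy()]
        )
        if np.ptp(y) == 0:
            row = {"metric": metric, "beta_sex": 0.0, "p_sex": 1.0, "beta_age": 0.0, "p_age": 1.0}
        else:
            fit = fit_ols(y, X, ["const", "sex", "age"])
            row = {
                "metric": metric,
                "beta_sex": fit.coef("sex"),
                "p_sex": fit.pvalue("sex"),
                "beta_age": fit.coef("age"),
                "p_age": fit.pvalue("age"),
            }
        for col, key in zip(group_cols, keys if isinstance(keys, tuple) else (keys,)):
            row[col] = key
        rows.append(row)
    return pd.DataFrame(rows)


def motion_checks(cohort: pd.DataFrame, variant: str = "student") -> dict:
    """Frame-displacement confound checks: FD sex t-test and FD-age correlation."""
    if "mean_fd_mm" not in cohort.columns:
        import logging

        logging.getLogger(__name__).warning("mean_fd_mm missing; motion checks skipped")
        return {"skipped": True}
    fd = cohort["mean_fd_mm"].to_numpy(dtype=float)
    sex = sex_indicator(cohort)
    age = cohort["age_years"].to_numpy(dtype=float)
    t, dof, p_t = two_sample_t(fd[sex == 1], fd[sex == 0], variant=variant)
    r = pearson_r(fd, age)
    n = fd.size
    if abs(r) >= 1.0:
        p_r = 0.0
    else:
        tr = r * np.sqrt((n - 2) / (1 - r * r))
        p_r = float(2 * stats.t.sf(abs(tr), df=n - 2))
    return {
        "skipped": False,
        "fd_sex_t": t,
        "fd_sex_df": dof,
        "fd_sex_p": p_t,
        "fd_age_r": r,
        "fd_age_p": p_r,
    }
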