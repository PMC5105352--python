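"""Synthetic cohorts with known sex/age effects on functional connectivity.

The generator emulates a young-adult resting-state cohort (default
203 males / 291 females, ages 22–36, 116 regions, 1200 timepoints) so the
whole pipeline is testable without any imaging data.  Two modes:

* direct-z: each subject's edge vector is drawn straight from the linear
  model z = mu + b_sex*sex + b_age*age + b_int*sex*age + N(0, sigma^2),
  the exact generative inverse of the regression stage, so planted
  coefficients are recovered to machine precision when sigma = 0.
* time-series: each subject gets a T x R multivariate-normal series whose
  target correlation has within-lobe blocks, exercising parcellation and
  FC construction end to end; effects are planted on the correlation
  scale there, so they appear only approximately on the z scale.

Sex is coded female=0 / male=1 throughout, matching the regression module,
so b_sex > 0 means male > female; planted age effects default negative
(FC declines with age).  Every generator is a pure function of its spec
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import GroupFCTable, edge_index, n_edges as edge_count
from .parcellation import ParcellationScheme, ROITimeSeries

#: Default planted effect magnitudes (z-units; z-units/year for age).  The
#: sex effect is calibrated from the noncentral-t power formula to ~93%
#: nominal power at the Bonferroni level for 6670 edges with n=494 and unit
#: noise, leaving margin for best-model selection losses so end-to-end
#: detection stays above 80%.
DEFAULT_B_SEX = 0.55
DEFAULT_B_AGE = -0.06
DEFAULT_B_INT = 0.02
DEFAULT_NOISE_SD = 1.0


@dataclass
class CohortSpec:
    """Cohort dimensions and the master seed."""

    n_male: int = 203
    n_female: int = 291
    age_low: float = 22.0
    age_high: float = 36.0
    n_regions: int = 116
    n_timepoints: int = 1200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_male + self.n_female < 3:
            raise ValueError("cohort must have at least 3 subjects")
        if not self.age_low < self.age_high:
            raise ValueError("age_low must be below age_high")
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions")

    @property
    def n_subjects(self) -> int:
        return self.n_male + self.n_female

    @property
    def n_edges(self) -> int:
        return edge_count(self.n_regions)


@dataclass
class CovariateSpec:
    """Normal covariate with an optional male-minus-female mean shift."""

    name: str
    mean: float
    sd: float
    male_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"covariate {self.name}: sd must be positive")


def default_covariates() -> list[CovariateSpec]:
    """Seven age-adjusted cognition scores (scale 100 +/- 15), intracranial
    volume (mm^3, higher in males) and mean frame displacement (mm)."""
    covs = [CovariateSpec(f"cognition_{k}", 100.0, 15.0) for k in range(1, 8)]
    covs.append(CovariateSpec("icv_mm3", 1.45e6, 1.3e5, male_shift=1.6e5))
    covs.append(CovariateSpec("mean_fd_mm", 0.14, 0.04))
    return covs


def make_cohort(
    spec: CohortSpec, covariates: list[CovariateSpec] | None = None
) -> pd.DataFrame:
    """Subjects table: id, sex {M, F}, uniform ages, optional covariates."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    sex = np.array(["M"] * spec.n_male + ["F"] * spec.n_female)
    rng.shuffle(sex)
    age = rng.uniform(spec.age_low, spec.age_high, size=n)
    df = pd.DataFrame(
        {
            "subject_id": [f"sub-{k:04d}" for k in range(n)],
            "sex": sex,
            "age_years": age,
        }
    )
    male = (sex == "M").astype(float)
    for cov in covariates or []:
        df[cov.name] = rng.normal(cov.mean, cov.sd, size=n) + cov.male_shift * male
    return df


@dataclass
class EffectMap:
    """Per-edge generative coefficients and the truly-nonnull edge sets."""

    mu: np.ndarray
    b_sex: np.ndarray
    b_age: np.ndarray
    b_int: np.ndarray
    sigma: np.ndarray
    sex_edges: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    age_edges: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    int_edges: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        arrays = [self.mu, self.b_sex, self.b_age, self.b_int, self.sigma]
        sizes = {a.size for a in arrays}
        if len(sizes) != 1:
            raise ValueError("effect-map arrays must share one length")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive for every edge")

    @property
    def n_edges(self) -> int:
        return self.mu.size

    def to_frame(self, n_regions: int | None = None) -> pd.DataFrame:
        if n_regions is None:
            n_regions = int(round((1 + np.sqrt(1 + 8 * self.n_edges)) / 2))
        edges = edge_index(n_regions)
        return edges.assign(
            mu=self.mu, b_sex=self.b_sex, b_age=self.b_age, b_int=self.b_int, sigma=self.sigma
        )

    def to_csv(self, path: str | Path, n_regions: int | None = None) -> None:
        self.to_frame(n_regions).to_csv(path, index=False)


def make_effect_map(
    n_edges: int,
    n_sex_edges: int = 0,
    n_age_edges: int = 0,
    n_int_edges: int = 0,
    b_sex: float = DEFAULT_B_SEX,
    b_age: float = DEFAULT_B_AGE,
    b_int: float = DEFAULT_B_INT,
    noise_sd: float = DEFAULT_NOISE_SD,
    mu_mean: float = 0.3,
    mu_sd: float = 0.1,
    seed: int = 0,
) -> EffectMap:
    """Plant effects on disjoint random edge subsets; all other edges null.

    Sex effects are positive (male > female) and age effects negative
    (higher FC in younger subjects) by default.
    """
    total = n_sex_edges + n_age_edges + n_int_edges
    if total > n_edges:
        raise ValueError(
            f"cannot allocate {total} nonnull edges among {n_edges} edges"
        )
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_edges, size=total, replace=False)
    sex_edges = np.sort(chosen[:n_sex_edges])
    age_edges = np.sort(chosen[n_sex_edges : n_sex_edges + n_age_edges])
    int_edges = np.sort(chosen[n_sex_edges + n_age_edges :])
    mu = rng.normal(mu_mean, mu_sd, size=n_edges)
    bs = np.zeros(n_edges)
    ba = np.zeros(n_edges)
    bi = np.zeros(n_edges)
    bs[sex_edges] = b_sex
    ba[age_edges] = b_age
    bi[int_edges] = b_int
    return EffectMap(
        mu=mu,
        b_sex=bs,
        b_age=ba,
        b_int=bi,
        sigma=np.full(n_edges, float(noise_sd)),
        sex_edges=sex_edges,
        age_edges=age_edges,
        int_edges=int_edges,
    )


def simulate_direct_z(
    cohort: pd.DataFrame, effects: EffectMap, seed: int = 0
) -> GroupFCTable:
    """Draw the subjects x edges Fisher-z table from the planted linear model."""
    from .regression import sex_indicator

    sex = sex_indicator(cohort)
    age = cohort["age_years"].to_numpy(dtype=float)
    n = len(cohort)
    rng = np.random.default_rng(seed)
    mean = (
        effects.mu[None, :]
        + np.outer(sex, effects.b_sex)
        + np.outer(age, effects.b_age)
        + np.outer(sex * age, effects.b_int)
    )
    noise = rng.standard_normal((n, effects.n_edges)) * effects.sigma[None, :]
    r = int(round((1 + np.sqrt(1 + 8 * effects.n_edges)) / 2))
    if edge_count(r) != effects.n_edges:
        raise ValueError("effect map edge count is not R(R-1)/2 for any integer R")
    return GroupFCTable(
        values=mean + noise,
        edges=edge_index(r),
        subject_ids=cohort["subject_id"].astype(str).tolist(),
    )


def _shrink_to_pd(
    corr: np.ndarray, min_eig: float = 1e-8, factor: float = 0.95, max_iter: int = 200
) -> np.ndarray:
    """Linear shrinkage toward identity until the smallest eigenvalue clears."""
    c = corr.copy()
    eye = np.eye(c.shape[0])
    for _ in range(max_iter):
        if np.linalg.eigvalsh(c).min() > min_eig:
            return c
        c = factor * c + (1 - factor) * eye
    if np.linalg.eigvalsh(c).min() > min_eig:
        return c
    raise ValueError("target correlation not positive definite after maximum shrinkage")


def lobe_block_correlation(
    scheme: ParcellationScheme, block_r: float, base_r: float
) -> np.ndarray:
    """Correlation target with within-lobe blocks on a between-lobe floor."""
    lobes = scheme.table.sort_values("region_index")["lobe"].to_numpy()
    same_lobe = lobes[:, None] == lobes[None, :]
    corr = np.where(same_lobe, block_r, base_r).astype(float)
    np.fill_diagonal(corr, 1.0)
    return corr


def simulate_timeseries(
    cohort: pd.DataFrame,
    scheme: ParcellationScheme,
    block_r: float = 0.3,
    base_r: float = 0.05,
    sex_delta_r: float = 0.0,
    delta_edges: list[tuple[int, int]] | None = None,
    n_timepoints: int = 1200,
    seed: int = 0,
) -> list[ROITimeSeries]:
    """Zero-mean multivariate-normal series per subject.

    The subject-specific target correlation is the lobe-block structure,
    plus ``sex_delta_r`` on the designated (1-based i, j) edges for male
    subjects.  Each target is shrunk toward the identity until positive
    definite; sample FC of the output has the target as its expectation.
    """
    from .regression import sex_indicator

    r = scheme.n_regions
    if n_timepoints < r + 2:
        raise ValueError("need n_timepoints >= n_regions + 2")
    base = lobe_block_correlation(scheme, block_r, base_r)
    sex = sex_indicator(cohort)
    rng = np.random.default_rng(seed)

    male_target = base.copy()
    for i, j in delta_edges or []:
        male_target[i - 1, j - 1] += sex_delta_r
        male_target[j - 1, i - 1] += sex_delta_r
    chols = {
        0.0: np.linalg.cholesky(_shrink_to_pd(base)),
        1.0: np.linalg.cholesky(_shrink_to_pd(male_target)),
    }
    out = []
    for k, row in cohort.reset_index(drop=True).iterrows():
        chol = chols[float(sex[k])]
        x = rng.standard_normal((n_timepoints, r)) @ chol.T
        out.append(ROITimeSeries(subject_id=str(row["subject_id"]), values=x))
    return out


@dataclass
class SyntheticCohort:
    """Bundle of cohort table, generated data and the effect map used."""

    cohort: pd.DataFrame
    effects: EffectMap | None
    table: GroupFCTable | None = None
    timeseries: list[ROITimeSeries] | None = None
    seed: int = 0


def simulate_cohort(
    spec: CohortSpec,
    n_sex_edges: int = 0,
    n_age_edges: int = 0,
    n_int_edges: int = 0,
    b_sex: float = DEFAULT_B_SEX,
    b_age: float = DEFAULT_B_AGE,
    b_int: float = DEFAULT_B_INT,
    noise_sd: float = DEFAULT_NOISE_SD,
    covariates: list[CovariateSpec] | None = None,
    mode: str = "direct_z",
) -> SyntheticCohort:
    """One-call generator: cohort + effect map + data, all from spec.seed."""
    cohort = make_cohort(spec, covariates=covariates)
    if mode == "direct_z":
        effects = make_effect_map(
            spec.n_edges,
            n_sex_edges,
            n_age_edges,
            n_int_edges,
            b_sex=b_sex,
            b_age=b_age,
            b_int=b_int,
            noise_sd=noise_sd,
            seed=spec.seed + 1,
        )
        table = simulate_direct_z(cohort, effects, seed=spec.seed + 2)
        return SyntheticCohort(cohort=cohort, effects=effects, table=table, seed=spec.seed)
    if mode == "timeseries":
        scheme = ParcellationScheme.synthetic(spec.n_regions)
        ts = simulate_timeseries(
            cohort, scheme, n_timepoints=spec.n_timepoints, seed=spec.seed + 2
        )
        return SyntheticCohort(cohort=cohort, effects=None, timeseries=ts, seed=spec.seed)
    raise ValueError(f"unknown mode: {mode}")
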