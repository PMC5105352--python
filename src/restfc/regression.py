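"""Edge-wise OLS with backward stepwise selection over the five-model family.

Each edge's Fisher-z FC vector F (one value per subject) is modelled as

    F = b0 + bs*sex + ba*age + bi*sex*age + e

with sex coded female=0 / male=1 and age in raw years (optionally
mean-centred).  Backward elimination starts from the full model and
repeatedly drops the least significant removable term (single-term partial
F, which equals the squared coefficient t) while its removal p-value is
>= alpha_remove, under the marginality rule that the sex*age interaction
must leave before either main effect can.  The reachable models are

    M1: intercept only   M2: sex   M3: age   M4: sex + age
    M5: sex + age + sex*age

Significance is controlled family-wise over all edges (Bonferroni at
alpha / n_edges by default; Benjamini–Hochberg FDR available).  The module
also provides covariate-augmented refits, sex-stratified age slopes, and
direct FC–cognition correlations.

All edges share one design matrix, so the mass-univariate path batches
every candidate model's least-squares fit across edges at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import GroupFCTable, edge_labels

TERM_ORDER = ("sex", "age", "sexage")

MODEL_IDS = {
    frozenset(): "M1",
    frozenset({"sex"}): "M2",
    frozenset({"age"}): "M3",
    frozenset({"sex", "age"}): "M4",
    frozenset({"sex", "age", "sexage"}): "M5",
}
MODEL_TERMS = {v: k for k, v in MODEL_IDS.items()}

_DEGENERATE_RTOL = 1e-10  # rss below this fraction of tss => exact fit
_BETA_ATOL = 1e-8  # coefficient magnitude treated as zero in exact fits


def sex_indicator(cohort: pd.DataFrame) -> np.ndarray:
    """Female=0 / male=1 coding from a cohort table (accepts M/F or 0/1)."""
    s = cohort["sex"]
    if s.dtype.kind in "iufb":
        vals = s.to_numpy(dtype=float)
        if not set(np.unique(vals)) <= {0.0, 1.0}:
            raise ValueError("numeric sex column must be 0/1 (female/male)")
        return vals
    mapping = {"M": 1.0, "F": 0.0, "male": 1.0, "female": 0.0}
    try:
        return s.map(mapping).to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:  # unmapped level -> NaN -> cast fails
        raise ValueError(f"unrecognised sex labels: {sorted(set(s) - set(mapping))}") from exc


@dataclass
class OLSFit:
    """Closed-form least-squares fit with per-coefficient inference."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    rss: float
    tss: float
    df_resid: int
    f_stat: float
    p_f: float

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.p[self.names.index(name)])


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[k] for k in np.flatnonzero(diag <= tol)]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")


def fit_ols(y: np.ndarray, X: np.ndarray, names: list[str] | None = None) -> OLSFit:
    """OLS of y on X (X must include its own intercept column).

    p-values are two-sided t with n - p degrees of freedom; the model F
    compares against the intercept-only model.  Exact fits (zero residual)
    get p = 0 for nonzero coefficients and p = 1 for null ones so that
    noise-free planted signals select cleanly.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{k}" for k in range(p)]
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")
    _check_rank(X, list(names))

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    dof = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    dvar = np.diag(xtx_inv)

    scale = max(1.0, float(np.abs(y).max()))
    degenerate = rss <= _DEGENERATE_RTOL * max(tss, scale**2)
    if degenerate:
        se = np.zeros(p)
        t = np.where(np.abs(beta) > _BETA_ATOL * scale, np.inf, 0.0) * np.sign(beta + 0.0)
        pvals = np.where(np.abs(beta) > _BETA_ATOL * scale, 0.0, 1.0)
        beta = np.where(np.abs(beta) > _BETA_ATOL * scale, beta, 0.0)
        if tss <= _BETA_ATOL:
            f_stat, p_f = 0.0, 1.0
        else:
            f_stat, p_f = np.inf, 0.0
    else:
        sigma2 = rss / dof
        se = np.sqrt(dvar * sigma2)
        t = beta / se
        pvals = 2 * stats.t.sf(np.abs(t), df=dof)
        q = p - 1
        if q == 0:
            f_stat, p_f = np.nan, 1.0
        else:
            f_stat = ((tss - rss) / q) / sigma2
            p_f = float(stats.f.sf(f_stat, q, dof))
    return OLSFit(
        names=list(names),
        beta=np.asarray(beta, dtype=float),
        se=se,
        t=np.asarray(t, dtype=float),
        p=np.asarray(pvals, dtype=float),
        rss=rss,
        tss=tss,
        df_resid=dof,
        f_stat=float(f_stat),
        p_f=float(p_f),
    )


@dataclass
class DesignSpec:
    """Covariate coding for the edge-wise regressions."""

    center_age: bool = False
    extra_covariates: tuple[str, ...] = ()

    def columns(self, cohort: pd.DataFrame) -> dict[str, np.ndarray]:
        sex = sex_indicator(cohort)
        age = cohort["age_years"].to_numpy(dtype=float)
        if self.center_age:
            age = age - age.mean()
        cols = {"sex": sex, "age": age, "sexage": sex * age}
        for name in self.extra_covariates:
            if name not in cohort.columns:
                raise ValueError(f"covariate column missing from cohort: {name}")
            col = cohort[name].to_numpy(dtype=float)
            if col.std() == 0:
                raise ValueError(f"covariate has zero variance: {name}")
            cols[name] = col
        return cols


def _design(cols: dict[str, np.ndarray], terms: tuple[str, ...], n: int) -> np.ndarray:
    return np.column_stack([np.ones(n)] + [cols[t] for t in terms])


@dataclass
class SelectionResult:
    model: str
    terms: tuple[str, ...]
    fit: OLSFit


def backward_select(
    y: np.ndarray,
    cohort: pd.DataFrame,
    alpha_remove: float = 0.05,
    design: DesignSpec | None = None,
) -> SelectionResult:
    """Backward stepwise elimination from the full model.

    The interaction is removable at any time; a main effect only once the
    interaction is gone; extra covariates at any time.  The term with the
    largest removal p-value is dropped while that p-value is
    >= ``alpha_remove``.  Exact ties drop the interaction first, then the
    later-declared term, so repeated runs agree bit-for-bit.
    """
    design = design or DesignSpec()
    cols = design.columns(cohort)
    order = list(TERM_ORDER) + list(design.extra_covariates)
    terms = list(order)
    n = len(cohort)

    while True:
        fit = fit_ols(y, _design(cols, tuple(terms), n), ["const"] + terms)
        removable = [
            t
            for t in terms
            if t == "sexage"
            or t in design.extra_covariates
            or (t in ("sex", "age") and "sexage" not in terms)
        ]
        if not removable:
            break
        # sort: largest p first; ties prefer interaction, then later-declared
        removable.sort(key=lambda t: (-fit.pvalue(t), t != "sexage", -order.index(t)))
        worst = removable[0]
        if fit.pvalue(worst) < alpha_remove:
            break
        terms.remove(worst)
        if not terms:
            fit = fit_ols(y, _design(cols, (), n), ["const"])
            break
    surviving = frozenset(t for t in terms if t in TERM_ORDER)
    return SelectionResult(model=MODEL_IDS[surviving], terms=tuple(terms), fit=fit)


# ---------------------------------------------------------------------------
# batched mass-univariate path


def _batch_ols(X: np.ndarray, Y: np.ndarray) -> dict[str, np.ndarray]:
    """Least squares of every column of Y on the shared design X."""
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    tss = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    dof = n - p
    dvar = np.diag(np.linalg.inv(X.T @ X))[:, None]
    scale2 = np.maximum(1.0, np.abs(Y).max(axis=0)) ** 2
    degenerate = rss <= _DEGENERATE_RTOL * np.maximum(tss, scale2)
    sigma2 = np.where(degenerate, np.nan, rss) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(dvar * sigma2[None, :])
        t = beta / se
        pvals = 2 * stats.t.sf(np.abs(t), df=dof)
        q = p - 1
        if q == 0:
            f_stat = np.full(Y.shape[1], np.nan)
            p_f = np.ones(Y.shape[1])
        else:
            f_stat = ((tss - rss) / q) / sigma2
            p_f = stats.f.sf(f_stat, q, dof)
    if degenerate.any():
        scale = np.maximum(1.0, np.abs(Y).max(axis=0))
        nz = np.abs(beta) > _BETA_ATOL * scale[None, :]
        pvals[:, degenerate] = np.where(nz, 0.0, 1.0)[:, degenerate]
        exact_null = degenerate & (tss <= _BETA_ATOL)
        p_f = np.where(degenerate, 0.0, p_f)
        p_f = np.where(exact_null, 1.0, p_f)
        f_stat = np.where(degenerate, np.inf, f_stat)
        f_stat = np.where(exact_null, 0.0, f_stat)
    return {"beta": beta, "p": pvals, "f": f_stat, "p_f": p_f, "rss": rss, "dof": dof}


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def format_bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Threshold alpha/n in 1e-6 units, truncated to two decimals (7.49 for 0.05/6670)."""
    return float(np.floor(alpha / n_tests * 1e8) / 100.0)


@dataclass
class MassUnivariateReport:
    """Per-edge selected models, coefficients and corrected significance flags."""

    results: pd.DataFrame
    alpha: float
    alpha_remove: float
    correction: str
    threshold: float  # per-test threshold actually applied (bonferroni) or alpha (fdr)
    n_tests: int
    summary: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.results.to_csv(path, index=False)


def _selection_paths(p_tables: dict[str, np.ndarray], alpha_remove: float) -> np.ndarray:
    """Vectorised backward elimination over sex/age/sexage for every edge.

    ``p_tables[model]`` holds coefficient p-value rows ordered as the
    model's terms (const first).  Returns the selected model id per edge.
    """
    n_e = p_tables["M5"].shape[1]
    model = np.empty(n_e, dtype="<U2")
    p_int5 = p_tables["M5"][3]
    keep5 = p_int5 < alpha_remove
    model[keep5] = "M5"

    at4 = ~keep5
    p_sex4, p_age4 = p_tables["M4"][1], p_tables["M4"][2]
    done4 = at4 & (p_sex4 < alpha_remove) & (p_age4 < alpha_remove)
    model[done4] = "M4"
    reduce4 = at4 & ~done4
    # drop the larger p; exact tie drops the later-declared term (age)
    drop_age = reduce4 & (p_age4 >= p_sex4)
    drop_sex = reduce4 & ~drop_age

    p_sex2 = p_tables["M2"][1]
    to_m2 = drop_age & (p_sex2 < alpha_remove)
    model[to_m2] = "M2"
    model[drop_age & ~to_m2] = "M1"

    p_age3 = p_tables["M3"][1]
    to_m3 = drop_sex & (p_age3 < alpha_remove)
    model[to_m3] = "M3"
    model[drop_sex & ~to_m3] = "M1"
    return model


def run_mass_univariate(
    table: GroupFCTable,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    alpha_remove: float = 0.05,
    center_age: bool = False,
    n_tests: int | None = None,
) -> MassUnivariateReport:
    """Backward-stepwise OLS on every edge of the group FC table.

    Model-level significance gates on the selected model's F-test p-value
    at the family-wise threshold; term-level flags additionally require the
    term's own coefficient p-value to pass the same threshold.  Direction
    flags read male>female from beta_sex > 0 and age-related decline from
    beta_age < 0.
    """
    if table.n_subjects != len(cohort):
        raise ValueError(
            f"group table has {table.n_subjects} subjects but cohort has {len(cohort)}"
        )
    if correction not in ("bonferroni", "bh_fdr"):
        raise ValueError(f"unknown correction: {correction}")
    n_tests = n_tests or table.n_edges
    design = DesignSpec(center_age=center_age)
    cols = design.columns(cohort)
    n = len(cohort)
    Y = table.values

    model_terms = {m: tuple(sorted(MODEL_TERMS[m], key=TERM_ORDER.index)) for m in MODEL_IDS.values()}
    fits = {
        m: _batch_ols(_design(cols, terms, n), Y) for m, terms in model_terms.items()
    }
    p_tables = {m: fits[m]["p"] for m in ("M5", "M4", "M3", "M2")}
    selected = _selection_paths(p_tables, alpha_remove)

    n_e = table.n_edges
    beta_sex = np.full(n_e, np.nan)
    beta_age = np.full(n_e, np.nan)
    beta_int = np.full(n_e, np.nan)
    p_sex = np.full(n_e, np.nan)
    p_age = np.full(n_e, np.nan)
    p_int = np.full(n_e, np.nan)
    f_stat = np.full(n_e, np.nan)
    p_f = np.ones(n_e)
    for m, terms in model_terms.items():
        mask = selected == m
        if not mask.any():
            continue
        fit = fits[m]
        f_stat[mask] = fit["f"][mask]
        p_f[mask] = fit["p_f"][mask]
        for k, term in enumerate(terms, start=1):
            if term == "sex":
                beta_sex[mask] = fit["beta"][k, mask]
                p_sex[mask] = fit["p"][k, mask]
            elif term == "age":
                beta_age[mask] = fit["beta"][k, mask]
                p_age[mask] = fit["p"][k, mask]
            elif term == "sexage":
                beta_int[mask] = fit["beta"][k, mask]
                p_int[mask] = fit["p"][k, mask]

    if correction == "bonferroni":
        threshold = alpha / n_tests
        sig_model = p_f < threshold
        sig = lambda p: sig_model & np.where(np.isnan(p), False, p < threshold)
    else:
        threshold = alpha
        sig_model = bh_fdr(p_f) < alpha
        sig = lambda p: sig_model & (
            bh_fdr(np.where(np.isnan(p), 1.0, p)) < alpha
        ) & ~np.isnan(p)
    sig_sex = sig(p_sex)
    sig_age = sig(p_age)
    sig_int = sig(p_int)

    results = pd.DataFrame(
        {
            "edge_id": table.edges["edge_id"],
            "i": table.edges["i"],
            "j": table.edges["j"],
            "pair": edge_labels(table.edges),
            "model": selected,
            "beta_sex": beta_sex,
            "beta_age": beta_age,
            "beta_int": beta_int,
            "p_sex": p_sex,
            "p_age": p_age,
            "p_int": p_int,
            "F": f_stat,
            "p_F": p_f,
            "sig_model_bonf": sig_model,
            "sig_sex_bonf": sig_sex,
            "sig_age_bonf": sig_age,
            "sig_int_bonf": sig_int,
            "dir_sex": np.where(np.isnan(beta_sex), "", np.where(beta_sex > 0, "M>F", "F>M")),
            "dir_age": np.where(np.isnan(beta_age), "", np.where(beta_age < 0, "older<younger", "older>younger")),
        }
    )

    with_sex = ~np.isnan(beta_sex)
    with_age = ~np.isnan(beta_age)
    summary = {
        "n_edges": int(n_e),
        "n_subjects": int(n),
        "alpha": alpha,
        "correction": correction,
        "bonferroni_threshold": alpha / n_tests,
        "bonferroni_threshold_1e6_truncated": format_bonferroni_threshold(alpha, n_tests),
        "n_sig_models": int(sig_model.sum()),
        "model_counts": {m: int((selected == m).sum()) for m in MODEL_IDS.values()},
        "model_counts_significant": {
            m: int(((selected == m) & sig_model).sum()) for m in MODEL_IDS.values()
        },
        "n_male_gt_female_uncorrected": int((with_sex & (beta_sex > 0) & sig_model).sum()),
        "n_female_gt_male_uncorrected": int((with_sex & (beta_sex < 0) & sig_model).sum()),
        "n_male_gt_female_corrected": int((sig_sex & (beta_sex > 0)).sum()),
        "n_female_gt_male_corrected": int((sig_sex & (beta_sex < 0)).sum()),
        "n_age_decline_corrected": int((sig_age & (beta_age < 0)).sum()),
        "n_age_increase_corrected": int((sig_age & (beta_age > 0)).sum()),
        "n_sig_interaction": int(sig_int.sum()),
    }
    return MassUnivariateReport(
        results=results,
        alpha=alpha,
        alpha_remove=alpha_remove,
        correction=correction,
        threshold=threshold,
        n_tests=n_tests,
        summary=summary,
    )


def augment_with_covariates(
    report: MassUnivariateReport,
    table: GroupFCTable,
    cohort: pd.DataFrame,
    covariates: list[str],
) -> MassUnivariateReport:
    """Refit each edge's selected model with extra covariates appended.

    The sex/age/interaction term set is kept as selected (no re-selection);
    the covariates change the residual variance and degrees of freedom, and
    the report shows which previously significant effects survive.
    """
    for name in covariates:
        if name not in cohort.columns:
            raise ValueError(f"covariate column missing from cohort: {name}")
    design = DesignSpec(extra_covariates=tuple(covariates))
    cols = design.columns(cohort)
    n = len(cohort)
    Y = table.values
    selected = report.results["model"].to_numpy()

    cov_cols = tuple(covariates)
    out = report.results.copy()
    for m in MODEL_IDS.values():
        mask = selected == m
        if not mask.any():
            continue
        terms = tuple(sorted(MODEL_TERMS[m], key=TERM_ORDER.index)) + cov_cols
        X = _design(cols, terms, n)
        _check_rank(X, ["const"] + list(terms))
        fit = _batch_ols(X, Y[:, mask])
        for k, term in enumerate(terms, start=1):
            if term in TERM_ORDER:
                key = {"sex": "sex", "age": "age", "sexage": "int"}[term]
                out.loc[mask, f"beta_{key}"] = fit["beta"][k]
                out.loc[mask, f"p_{key}"] = fit["p"][k]
        out.loc[mask, "F"] = fit["f"]
        out.loc[mask, "p_F"] = fit["p_f"]

    threshold = report.alpha / report.n_tests
    sig_model = out["p_F"].to_numpy() < threshold
    out["sig_model_bonf"] = sig_model
    for key in ("sex", "age", "int"):
        p = out[f"p_{key}"].to_numpy()
        out[f"sig_{key}_bonf"] = sig_model & np.where(np.isnan(p), False, p < threshold)

    before_sex = report.results["sig_sex_bonf"].to_numpy()
    after_sex = out["sig_sex_bonf"].to_numpy()
    before_age = report.results["sig_age_bonf"].to_numpy()
    after_age = out["sig_age_bonf"].to_numpy()
    summary = dict(report.summary)
    summary.update(
        {
            "covariates": list(covariates),
            "n_sex_sig_before": int(before_sex.sum()),
            "n_sex_sig_surviving": int((before_sex & after_sex).sum()),
            "n_sex_sig_new": int((~before_sex & after_sex).sum()),
            "n_age_sig_before": int(before_age.sum()),
            "n_age_sig_surviving": int((before_age & after_age).sum()),
            "n_age_sig_new": int((~before_age & after_age).sum()),
        }
    )
    return MassUnivariateReport(
        results=out,
        alpha=report.alpha,
        alpha_remove=report.alpha_remove,
        correction=report.correction,
        threshold=threshold,
        n_tests=report.n_tests,
        summary=summary,
    )


def stratified_age_slopes(
    table: GroupFCTable, cohort: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Simple OLS of z on age within each sex, per edge.

    Returns per-edge male/female slopes with p-values and Bonferroni flags
    (threshold alpha / n_edges within each group), plus a ``both_negative_female_steeper``
    flag marking edges where both slopes are negative and the female slope
    has the larger magnitude.
    """
    sex = sex_indicator(cohort)
    age = cohort["age_years"].to_numpy(dtype=float)
    n_e = table.n_edges
    out = {"edge_id": table.edges["edge_id"], "i": table.edges["i"], "j": table.edges["j"]}
    threshold = alpha / n_e
    for label, mask in (("male", sex == 1), ("female", sex == 0)):
        if mask.sum() < 3:
            raise ValueError(f"{label} group has fewer than 3 subjects")
        a = age[mask]
        Y = table.values[mask]
        ac = a - a.mean()
        sxx = float(ac @ ac)
        if sxx == 0:
            raise ValueError(f"{label} group has constant age")
        slope = (ac @ Y) / sxx
        fitted = np.outer(a - a.mean(), slope) + Y.mean(axis=0)
        rss = np.sum((Y - fitted) ** 2, axis=0)
        dof = mask.sum() - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(rss / dof / sxx)
            t = slope / se
            p = 2 * stats.t.sf(np.abs(t), df=dof)
        p = np.where(rss <= _DEGENERATE_RTOL * np.maximum(np.sum((Y - Y.mean(0)) ** 2, 0), 1e-300),
                     np.where(np.abs(slope) > _BETA_ATOL, 0.0, 1.0), p)
        out[f"slope_{label}"] = slope
        out[f"p_{label}"] = p
        out[f"sig_{label}_bonf"] = p < threshold
    df = pd.DataFrame(out)
    df["both_negative_female_steeper"] = (
        (df["slope_male"] < 0)
        & (df["slope_female"] < 0)
        & (df["slope_female"].abs() > df["slope_male"].abs())
    )
    return df


def edge_cognition_correlation(
    table: GroupFCTable,
    cohort: pd.DataFrame,
    score: str,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Direct Pearson correlation of every edge with one cognitive score."""
    if score not in cohort.columns:
        raise ValueError(f"score column missing from cohort: {score}")
    s = cohort[score].to_numpy(dtype=float)
    if s.std() == 0:
        raise ValueError(f"score has zero variance: {score}")
    n = len(s)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    n_tests = n_tests or table.n_edges
    sc = s - s.mean()
    Y = table.values - table.values.mean(axis=0)
    denom = np.sqrt((sc @ sc) * np.einsum("ij,ij->j", Y, Y))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (sc @ Y) / denom
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    df = pd.DataFrame(
        {
            "edge_id": table.edges["edge_id"],
            "i": table.edges["i"],
            "j": table.edges["j"],
            "score": score,
            "r": r,
            "p": p,
            "sig_bonf": p < alpha / n_tests,
        }
    )
    return df
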