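"""Covariate-adjusted weighted regressions of scores and aging outcomes.

Two model families mirror the study design:

* score models — each composite score regressed on all socio-behavioral
  variables jointly (age group, sex, race/ethnicity, education, BMI class,
  smoking, drinking, insomnia) plus batch-plate dummies, weighted OLS with
  standardized coefficients;
* outcome models — each aging outcome (epigenetic pace, clock age
  acceleration, biological-age acceleration, cognition, multimorbidity
  linear; 6-year mortality logistic) regressed on each score plus the same
  covariates, optionally further adjusted for the pace-of-aging covariate
  and/or measured immune-cell proportions.

"Standardized coefficients" means: the continuous outcome (linear family)
and all continuous predictors are z-scored on the analysis sample; dummy
indicators stay binary.  Survey weights enter as analytic weights with
heteroskedasticity-robust (HC1) standard errors, an approximation to
design-based survey variance estimation.  Mortality models report odds
ratios per SD of the standardized score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "AssociationError",
    "ModelSpec",
    "AssociationResult",
    "CVMetrics",
    "GridConfig",
    "GridResults",
    "DEFAULT_REFERENCE_LEVELS",
    "build_analysis_sample",
    "standardize_variables",
    "build_design",
    "fit_linear_weighted",
    "fit_logistic_weighted",
    "age_acceleration_residuals",
    "bh_fdr",
    "kfold_cv",
    "run_model_grid",
]


class AssociationError(ValueError):
    """A model cannot be fit as specified."""


DEFAULT_REFERENCE_LEVELS = {
    "age_group": "55-64",
    "race_ethnicity": "NH White",
    "education": "<HS",
    "bmi_class": "Normal",
}
DEFAULT_COVARIATES = (
    "age_group", "female", "race_ethnicity", "education", "bmi_class",
    "pack_years", "weekly_drinks", "insomnia",
)
DEFAULT_OUTCOME_FAMILIES = {
    "pace": "linear",
    "clock_aa": "linear",
    "bioage_aa": "linear",
    "cognition": "linear",
    "multimorbidity": "linear",
    "mortality": "logistic",
}


@dataclass
class ModelSpec:
    """One regression model of the grid."""

    outcome: str
    family: str = "linear"  # "linear" | "logistic"
    focal: str | None = None
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    batch_dummies: bool = True
    batch_col: str = "batch"
    weight_col: str | None = "weight"
    extra_covariates: tuple[str, ...] = ()
    presumed_alive_exclusion: bool = False
    reference_levels: dict = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_LEVELS))

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise AssociationError(f"unknown family {self.family!r}")
        preds = set(self.covariates) | set(self.extra_covariates)
        if self.focal is not None:
            preds.add(self.focal)
        if self.outcome in preds:
            raise AssociationError(
                f"outcome {self.outcome!r} appears among the predictors")

    @property
    def model_columns(self) -> list[str]:
        cols = [self.outcome]
        if self.focal:
            cols.append(self.focal)
        cols += list(self.covariates) + list(self.extra_covariates)
        if self.batch_dummies:
            cols.append(self.batch_col)
        if self.weight_col:
            cols.append(self.weight_col)
        return cols


@dataclass
class AssociationResult:
    """Per-term estimates of one fitted model.

    ``terms`` is indexed by design-matrix term with columns
    estimate / se / stat / p / ci_low / ci_high (log-odds scale for
    logistic; ``odds_ratio`` columns added there).
    """

    family: str
    outcome: str
    focal: str | None
    terms: pd.DataFrame
    n: int
    r2: float | None = None
    converged: bool = True
    dropped_terms: tuple[str, ...] = ()

    def focal_row(self) -> pd.Series:
        if self.focal is None:
            raise AssociationError("model has no focal predictor")
        return self.terms.loc[self.focal]


@dataclass
class CVMetrics:
    """K-fold cross-validation summary for one model."""

    k: int
    seed: int
    fold_r2: list[float]
    fold_rmse: list[float]
    fold_mae: list[float]
    mean_cv_r2: float
    full_r2: float
    rmse: float
    mae: float


def _mortality_from_status(status: pd.Series) -> pd.Series:
    """Deceased iff vital status 3 or 4; statuses 1 and 2 are alive."""
    bad = status.dropna()[~status.dropna().isin([1, 2, 3, 4])]
    if len(bad):
        raise AssociationError(
            f"unknown vital-status codes: {sorted(bad.unique())}")
    out = pd.Series(np.nan, index=status.index, name="mortality")
    out[status.isin([3, 4])] = 1.0
    out[status.isin([1, 2])] = 0.0
    return out


def build_analysis_sample(phenotypes: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Complete cases on all model variables, with mortality recoding.

    If the outcome is ``mortality`` it is (re)derived from ``vital_status``
    when that column is present; with ``presumed_alive_exclusion`` on,
    status-2 (presumed alive) rows are dropped before the complete-case
    filter.
    """
    table = phenotypes.copy()
    if spec.outcome == "mortality" and "vital_status" in table.columns:
        if spec.presumed_alive_exclusion:
            table = table[table["vital_status"].isna()
                          | (table["vital_status"] != 2)]
        table["mortality"] = _mortality_from_status(table["vital_status"])
    missing = [c for c in spec.model_columns if c not in table.columns]
    if missing:
        raise AssociationError(f"model columns not in phenotype table: {missing}")
    out = table.dropna(subset=spec.model_columns)
    if out.empty:
        raise AssociationError(
            f"analysis sample for outcome {spec.outcome!r} is empty after "
            "complete-case filtering")
    return out


def _is_binary(col: pd.Series) -> bool:
    vals = pd.unique(col.dropna())
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def _dummies(col: pd.Series, name: str, reference: str | None) -> pd.DataFrame:
    levels = list(pd.unique(col))
    if reference is None:
        reference = sorted(map(str, levels))[0]
    if reference not in set(map(str, levels)):
        raise AssociationError(
            f"reference level {reference!r} absent from column {name!r}")
    others = [lv for lv in sorted(map(str, levels)) if lv != str(reference)]
    out = pd.DataFrame(index=col.index)
    as_str = col.astype(str)
    for lv in others:
        out[f"{name}[{lv}]"] = (as_str == lv).astype(float)
    return out


def standardize_variables(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.Series, pd.DataFrame, np.ndarray]:
    """Build (y, X, weights) with the standardization convention applied.

    Continuous variables (numeric, more than two distinct values) are
    z-scored on the analysis sample with the n-1 SD; binary numerics stay
    0/1; categoricals expand to dummies against the declared reference
    level; batch expands to dummies when flagged.  The linear-family outcome
    is z-scored; the logistic outcome stays binary.
    """
    y = table[spec.outcome].astype(float)
    if spec.family == "linear":
        sd = y.std(ddof=1)
        if not sd > 0:
            raise AssociationError(f"outcome {spec.outcome!r} has zero variance")
        y = (y - y.mean()) / sd
    else:
        classes = set(pd.unique(y))
        if not classes <= {0.0, 1.0}:
            raise AssociationError(
                f"logistic outcome {spec.outcome!r} must be 0/1, got {sorted(classes)}")
        if len(classes) < 2:
            raise AssociationError(
                f"logistic outcome {spec.outcome!r} has a single class")

    X = pd.DataFrame(index=table.index)
    X["const"] = 1.0
    predictors = ([spec.focal] if spec.focal else []) + \
        list(spec.covariates) + list(spec.extra_covariates)
    for name in predictors:
        col = table[name]
        if pd.api.types.is_numeric_dtype(col):
            if _is_binary(col):
                X[name] = col.astype(float)
            else:
                sd = col.std(ddof=1)
                if not sd > 0:
                    raise AssociationError(f"predictor {name!r} has zero variance")
                X[name] = (col - col.mean()) / sd
        else:
            ref = spec.reference_levels.get(name)
            d = _dummies(col, name, ref)
            for c in d.columns:
                X[c] = d[c]
    if spec.batch_dummies:
        ref = spec.reference_levels.get(spec.batch_col)
        if ref is None:
            ref = sorted(map(str, pd.unique(table[spec.batch_col])))[0]
        d = _dummies(table[spec.batch_col], spec.batch_col, ref)
        for c in d.columns:
            X[c] = d[c]
    if spec.weight_col:
        w = table[spec.weight_col].astype(float).to_numpy()
        if np.any(w <= 0):
            raise AssociationError("survey weights must be positive")
    else:
        w = np.ones(len(table))
    return y, X, w


def build_design(
    phenotypes: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.Series, pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Filter to the analysis sample and build the standardized design."""
    sample = build_analysis_sample(phenotypes, spec)
    y, X, w = standardize_variables(sample, spec)
    return y, X, w, sample


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.argsort(diag)[: arr.shape[1] - rank]]
        raise AssociationError(
            f"design matrix is rank deficient ({rank}/{arr.shape[1]}); "
            f"collinear columns include {bad}")


def _weighted(w: np.ndarray) -> bool:
    return not np.allclose(w, w[0])


def fit_linear_weighted(
    y, X: pd.DataFrame, weights=None,
    outcome: str = "y", focal: str | None = None,
) -> AssociationResult:
    """Weighted least squares with robust (HC1) SEs under non-unit weights.

    With standardized inputs the coefficients are the reported standardized
    betas.  Classical SEs are used for unit weights.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    _check_rank(X)
    model = sm.WLS(y, X.astype(float), weights=w)
    fit = model.fit(cov_type="HC1") if _weighted(w) else model.fit()
    ci = fit.conf_int()
    terms = pd.DataFrame({
        "estimate": fit.params,
        "se": fit.bse,
        "stat": fit.tvalues,
        "p": fit.pvalues,
        "ci_low": ci[0],
        "ci_high": ci[1],
    })
    return AssociationResult(
        family="linear", outcome=outcome, focal=focal, terms=terms,
        n=len(X), r2=float(fit.rsquared))


def _drop_separating_dummies(
    y: pd.Series, X: pd.DataFrame, protect: set[str]
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Drop 0/1 nuisance indicators whose active group has a constant outcome.

    A dummy cell with no events (or only events) quasi-separates the
    likelihood and its coefficient diverges; standard practice for nuisance
    strata (e.g. batch plates) is to omit the perfectly predicting
    indicator.  Substantive terms in ``protect`` are never dropped.
    """
    dropped = []
    for col in X.columns:
        if col == "const" or col in protect:
            continue
        v = X[col]
        if not _is_binary(v):
            continue
        active = y[v == 1.0]
        if len(active) and active.nunique() == 1:
            dropped.append(col)
    return X.drop(columns=dropped), tuple(dropped)


def fit_logistic_weighted(
    y, X: pd.DataFrame, weights=None,
    outcome: str = "y", focal: str | None = None,
) -> AssociationResult:
    """Weighted binomial GLM; reports log-odds terms and odds ratios.

    With a standardized focal predictor, ``exp(estimate)`` is the odds ratio
    per SD.  Raises on a single-class outcome and on apparent separation
    (non-convergence or runaway coefficients).  Nuisance 0/1 indicators that
    perfectly predict the outcome within their active group (e.g. a batch
    plate with no deaths) are dropped before fitting and reported in
    ``dropped_terms``.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    classes = set(pd.unique(y))
    if len(classes) < 2:
        raise AssociationError("logistic outcome has a single class")
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    protect = {focal} if focal else set()
    X, dropped = _drop_separating_dummies(y, X, protect)
    _check_rank(X)
    model = sm.GLM(y, X.astype(float), family=sm.families.Binomial(), var_weights=w)
    try:
        fit = (model.fit(cov_type="HC1", maxiter=100) if _weighted(w)
               else model.fit(maxiter=100))
    except Exception as exc:  # perfect separation raises inside IRLS
        raise AssociationError(f"logistic fit failed (separation?): {exc}") from exc
    if not fit.converged:
        raise AssociationError("logistic fit did not converge")
    max_abs = float(np.max(np.abs(fit.params)))
    if max_abs > 15:
        raise AssociationError(
            f"suspected separation: |coefficient| up to {max_abs:.1f} on the "
            "log-odds scale")
    ci = fit.conf_int()
    terms = pd.DataFrame({
        "estimate": fit.params,
        "se": fit.bse,
        "stat": fit.tvalues,
        "p": fit.pvalues,
        "ci_low": ci[0],
        "ci_high": ci[1],
    })
    terms["odds_ratio"] = np.exp(terms["estimate"])
    terms["or_ci_low"] = np.exp(terms["ci_low"])
    terms["or_ci_high"] = np.exp(terms["ci_high"])
    mu = np.asarray(fit.fittedvalues, dtype=float)
    pseudo_r2 = float(1.0 - np.sum((y - mu) ** 2) / np.sum((y - y.mean()) ** 2))
    return AssociationResult(
        family="logistic", outcome=outcome, focal=focal, terms=terms,
        n=len(X), r2=pseudo_r2, converged=bool(fit.converged),
        dropped_terms=dropped)


def age_acceleration_residuals(bioage, chronage) -> pd.Series:
    """Residuals of biological age regressed on chronological age (years).

    Least squares with an intercept, so the residual mean is exactly 0; a
    positive residual means older biology than chronology.
    """
    b = pd.Series(np.asarray(bioage, dtype=float))
    a = np.asarray(chronage, dtype=float)
    if len(b) != len(a):
        raise AssociationError("bioage and chronage lengths differ")
    if len(b) < 3:
        raise AssociationError("need at least 3 samples for the residual")
    if np.ptp(a) == 0:
        raise AssociationError("chronological age is constant; residual undefined")
    X = np.column_stack([np.ones(len(a)), a])
    beta, *_ = np.linalg.lstsq(X, b.to_numpy(), rcond=None)
    resid = b.to_numpy() - X @ beta
    if isinstance(bioage, pd.Series):
        return pd.Series(resid, index=bioage.index, name="bioage_aa")
    return pd.Series(resid, name="bioage_aa")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending; adjusted p at rank i (1-based) is
    ``min_{j >= i} p_(j) * m / j`` capped at 1, mapped back to input order.
    Order-preserving and never smaller than the raw p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise AssociationError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise AssociationError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def kfold_cv(
    y, X: pd.DataFrame, weights=None, family: str = "linear",
    k: int = 5, seed: int = 0,
) -> CVMetrics:
    """Seeded k-fold CV with held-out R^2 (1 - SSE/SST, SST from the fold).

    Logistic folds are stratified on the outcome; metrics for the logistic
    family are computed on predicted probabilities against the 0/1 outcome.
    The full-sample R^2 uses the same prediction-based definition on the
    full fit, so linear full-sample R^2 matches OLS R^2 when unweighted.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    n = len(y)
    if k < 2:
        raise AssociationError("k must be >= 2")
    if n < k:
        raise AssociationError(f"n={n} smaller than k={k}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    def _fit_predict(train: np.ndarray, test: np.ndarray) -> np.ndarray:
        Xtr, Xte = X.iloc[train], X.iloc[test]
        if family == "linear":
            fit = sm.WLS(y.iloc[train], Xtr.astype(float), weights=w[train]).fit()
            return np.asarray(fit.predict(Xte.astype(float)), dtype=float)
        ytr = y.iloc[train]
        if len(set(pd.unique(ytr))) < 2:
            raise AssociationError("a training fold has a single outcome class")
        Xtr2, dropped = _drop_separating_dummies(ytr, Xtr, set())
        fit = sm.GLM(ytr, Xtr2.astype(float),
                     family=sm.families.Binomial(), var_weights=w[train]).fit()
        return np.asarray(
            fit.predict(Xte.drop(columns=list(dropped)).astype(float)), dtype=float)

    if family == "logistic":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X, y.astype(int))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X)

    fold_r2, fold_rmse, fold_mae = [], [], []
    for train, test in splits:
        pred = _fit_predict(train, test)
        yte = y.iloc[test].to_numpy()
        sst = np.sum((yte - yte.mean()) ** 2)
        sse = np.sum((yte - pred) ** 2)
        fold_r2.append(float(1.0 - sse / sst) if sst > 0 else float("nan"))
        fold_rmse.append(float(np.sqrt(np.mean((yte - pred) ** 2))))
        fold_mae.append(float(np.mean(np.abs(yte - pred))))

    full_pred = _fit_predict(np.arange(n), np.arange(n))
    sst = np.sum((y.to_numpy() - y.mean()) ** 2)
    full_r2 = float(1.0 - np.sum((y.to_numpy() - full_pred) ** 2) / sst)
    return CVMetrics(
        k=k, seed=seed, fold_r2=fold_r2, fold_rmse=fold_rmse, fold_mae=fold_mae,
        mean_cv_r2=float(np.nanmean(fold_r2)), full_r2=full_r2,
        rmse=float(np.sqrt(np.mean((y.to_numpy() - full_pred) ** 2))),
        mae=float(np.mean(np.abs(y.to_numpy() - full_pred))))


@dataclass
class GridConfig:
    """Configuration of the full model grid."""

    scores: tuple[str, ...] | None = None
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    outcome_families: dict = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_FAMILIES))
    score_models: bool = True
    outcome_models: bool = True
    pace_adjusted: bool = True
    cell_adjusted: bool = False
    cell_columns: tuple[str, ...] = (
        "prop_granulocytes", "prop_nk_cells", "prop_b_cells",
        "prop_cd4_t", "prop_cd8_t", "prop_monocytes")
    pace_col: str = "pace"
    batch_dummies: bool = True
    weight_col: str | None = "weight"
    presumed_alive_exclusion: bool = False
    apply_fdr: bool = True
    run_cv: bool = False
    cv_k: int = 5
    cv_seed: int = 0
    reference_levels: dict = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_LEVELS))


@dataclass
class GridResults:
    """Tidy per-term results plus optional CV metrics and failure log."""

    results: pd.DataFrame
    cv: pd.DataFrame | None = None
    failures: list = field(default_factory=list)


def _tidy(res: AssociationResult, family_label: str, score: str | None) -> pd.DataFrame:
    t = res.terms.reset_index(names="term")
    t.insert(0, "family", family_label)
    t.insert(1, "outcome", res.outcome)
    t.insert(2, "score", score if score is not None else "")
    t["estimate_type"] = "log_or" if res.family == "logistic" else "beta"
    t["n"] = res.n
    t["r2"] = res.r2
    return t


def run_model_grid(
    phenotypes: pd.DataFrame,
    scores: pd.DataFrame,
    grid: GridConfig | None = None,
) -> GridResults:
    """Execute the full association grid.

    Families produced (column ``family`` of the tidy results):

    * ``score_on_factors`` — score ~ socio-behavioral + batch (linear);
    * ``outcome_on_score`` — outcome ~ score + covariates + batch;
    * ``outcome_on_score_pace`` — the above plus the pace covariate;
    * ``outcome_on_score_cells`` — the above plus cell-type proportions.

    FDR adjustment (column ``p_fdr``): for score models, across the models
    with different dependent scores within each predictor term; for outcome
    models, across scores within each (family, outcome), focal term only.
    Failed models are recorded in ``failures`` and the run continues.
    """
    if grid is None:
        grid = GridConfig()
    score_names = tuple(grid.scores) if grid.scores else tuple(scores.columns)
    unknown = [s for s in score_names if s not in scores.columns]
    if unknown:
        raise AssociationError(f"unknown score column(s): {unknown}")
    table = phenotypes.join(scores[list(score_names)], how="inner")
    if len(table) != len(phenotypes):
        raise AssociationError(
            "phenotype table and score table sample ids do not fully align")
    if ("bioage_aa" in grid.outcome_families and "bioage_aa" not in table.columns
            and {"bioage", "age_years"} <= set(table.columns)):
        ok = table["bioage"].notna() & table["age_years"].notna()
        aa = age_acceleration_residuals(
            table.loc[ok, "bioage"], table.loc[ok, "age_years"])
        table["bioage_aa"] = aa.reindex(table.index)

    rows: list[pd.DataFrame] = []
    cv_rows: list[dict] = []
    failures: list[dict] = []

    def _run(spec: ModelSpec, family_label: str, score: str | None) -> None:
        try:
            y, X, w, _ = build_design(table, spec)
            if spec.family == "linear":
                res = fit_linear_weighted(y, X, w, outcome=spec.outcome,
                                          focal=spec.focal)
            else:
                res = fit_logistic_weighted(y, X, w, outcome=spec.outcome,
                                            focal=spec.focal)
            rows.append(_tidy(res, family_label, score))
            if grid.run_cv and family_label != "score_on_factors":
                cm = kfold_cv(y, X, w, family=spec.family, k=grid.cv_k,
                              seed=grid.cv_seed)
                cv_rows.append({
                    "family": family_label, "outcome": spec.outcome,
                    "score": score, "k": cm.k, "mean_cv_r2": cm.mean_cv_r2,
                    "full_r2": cm.full_r2, "rmse": cm.rmse, "mae": cm.mae,
                })
        except AssociationError as exc:
            failures.append({"family": family_label, "outcome": spec.outcome,
                             "score": score, "error": str(exc)})

    if grid.score_models:
        for s in score_names:
            spec = ModelSpec(
                outcome=s, family="linear", focal=None,
                covariates=grid.covariates, batch_dummies=grid.batch_dummies,
                weight_col=grid.weight_col,
                reference_levels=grid.reference_levels)
            _run(spec, "score_on_factors", s)

    if grid.outcome_models:
        variants: list[tuple[str, tuple[str, ...]]] = [("outcome_on_score", ())]
        if grid.pace_adjusted:
            variants.append(("outcome_on_score_pace", (grid.pace_col,)))
        if grid.cell_adjusted:
            variants.append(("outcome_on_score_cells", tuple(grid.cell_columns)))
        for outcome, family in grid.outcome_families.items():
            for label, extra in variants:
                if outcome == grid.pace_col and extra == (grid.pace_col,):
                    continue
                for s in score_names:
                    spec = ModelSpec(
                        outcome=outcome, family=family, focal=s,
                        covariates=grid.covariates,
                        batch_dummies=grid.batch_dummies,
                        weight_col=grid.weight_col, extra_covariates=extra,
                        presumed_alive_exclusion=grid.presumed_alive_exclusion,
                        reference_levels=grid.reference_levels)
                    _run(spec, label, s)

    if not rows:
        raise AssociationError("no model in the grid could be fit")
    results = pd.concat(rows, ignore_index=True)
    results["p_fdr"] = np.nan
    if grid.apply_fdr:
        mask_a = results["family"] == "score_on_factors"
        for term in results.loc[mask_a, "term"].unique():
            if term == "const" or term.startswith("batch["):
                continue
            idx = results.index[mask_a & (results["term"] == term)]
            if len(idx):
                results.loc[idx, "p_fdr"] = bh_fdr(results.loc[idx, "p"].to_numpy())
        mask_b = ~mask_a & (results["term"] == results["score"])
        for (fam, outcome), sub in results[mask_b].groupby(["family", "outcome"]):
            results.loc[sub.index, "p_fdr"] = bh_fdr(sub["p"].to_numpy())
    cv = pd.DataFrame(cv_rows) if cv_rows else None
    return GridResults(results=results, cv=cv, failures=failures)
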