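"""Case-level risk-factor modelling.

The univariate signal screen yields candidate drugs; this module builds a
case-level design matrix (sex and age as factors with explicit ``missing``
levels, one binary indicator per candidate drug), runs L1-penalised logistic
regression (LASSO) over a descending penalty path with cross-validated
deviance to select drugs, then fits an unpenalised multivariate logistic
regression reporting per-covariate odds ratios with Wald 95% CIs and
p-values, and assesses discrimination with ROC/AUC.

Conventions
-----------
* Reference levels (female; age <36) carry no column.
* Age strata: [36,53), [53,66), [66,80), [80,120]; out-of-range or absent
  ages map to the explicit ``missing`` level rather than being dropped.
* Only drug indicators are subject to LASSO selection; demographic factors
  are always carried into the multivariate fit.
* CV folds are assigned by hashing case ids, so fold membership — and hence
  the selection — is invariant to row order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "AGE_EDGES",
    "DesignMatrix",
    "LassoSelection",
    "RiskModelResult",
    "build_design_matrix",
    "lasso_select",
    "logistic_fit",
    "roc_auc",
    "forest_table",
]

logger = logging.getLogger(__name__)

#: Default age-stratum edges; reference stratum is <36.
AGE_EDGES = (36.0, 53.0, 66.0, 80.0, 120.0)

_Z975 = 1.959963984540054

SEX_COLS = ("sex_male", "sex_missing")


def _age_columns(edges: Sequence[float]) -> list[str]:
    labels = []
    lo = edges[0]
    for hi in edges[1:]:
        labels.append(f"age_{lo:g}_{hi:g}")
        lo = hi
    labels.append("age_missing")
    return labels


@dataclass
class DesignMatrix:
    """Outcome, covariates and bookkeeping for the case-level models."""

    X: pd.DataFrame              # float64, one row per case
    y: np.ndarray                # boolean outcome
    case_ids: np.ndarray
    demographic_cols: list[str]
    drug_cols: list[str]

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


def build_design_matrix(cases: pd.DataFrame, event: pd.Series,
                        exposures: pd.DataFrame,
                        candidate_drugs: Sequence[str],
                        age_edges: Sequence[float] = AGE_EDGES
                        ) -> DesignMatrix:
    """Assemble the design matrix.

    ``cases``: per-case frame indexed by caseid with ``sex`` (female/male/
    missing) and ``age_years``; ``event``: boolean Series on the same index;
    ``exposures``: boolean case x drug frame covering ``candidate_drugs``.
    """
    if not list(candidate_drugs):
        raise ValueError("candidate_drugs must be non-empty")
    if len(cases) == 0:
        raise ValueError("case list is empty")
    idx = cases.index
    X = pd.DataFrame(index=idx)
    sex = cases["sex"]
    X["sex_male"] = (sex == "male").astype(float)
    X["sex_missing"] = (sex == "missing").astype(float)

    age = cases["age_years"].to_numpy(dtype=float)
    edges = tuple(age_edges)
    in_range = (age >= 0) & (age <= edges[-1]) & ~np.isnan(age)
    cols = _age_columns(edges)
    lo = edges[0]
    for label, hi in zip(cols[:-1], edges[1:]):
        inside = in_range & (age >= lo) & ((age < hi) | (hi == edges[-1]) & (age <= hi))
        X[label] = inside.astype(float)
        lo = hi
    X[cols[-1]] = (~in_range).astype(float)

    demo_cols = list(X.columns)
    for name in candidate_drugs:
        X[f"drug:{name}"] = exposures[name].reindex(idx).fillna(False) \
            .to_numpy(dtype=float)
    drug_cols = [f"drug:{name}" for name in candidate_drugs]
    return DesignMatrix(
        X=X, y=event.reindex(idx).to_numpy(dtype=bool),
        case_ids=np.asarray(idx), demographic_cols=demo_cols,
        drug_cols=drug_cols)


@dataclass
class LassoSelection:
    """Outcome of the penalised-path variable selection."""

    selected: list[str]          # demographics + drugs with nonzero coefs
    selected_drugs: list[str]
    lambdas: np.ndarray
    path: pd.DataFrame           # covariate x lambda coefficient path
    cv_deviance: pd.DataFrame    # lambda, mean_deviance, se_deviance, n_nonzero
    lambda_min: float
    lambda_1se: float
    rule: str
    n_folds: int
    seed: int


def _fold_of(case_ids: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Stable fold assignment keyed to case id (row-order invariant)."""
    return np.asarray(
        [zlib.crc32(f"{seed}:{cid}".encode()) % n_folds for cid in case_ids],
        dtype=np.int64)


def _l1_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
             seed: int) -> np.ndarray:
    """Coefficient path (n_lambda x n_features) for the L1 logistic model
    with per-observation average loss (glmnet's lambda scale)."""
    n = X.shape[0]
    coefs = np.zeros((lambdas.size, X.shape[1]))
    for i, lam in enumerate(lambdas):
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear",
            intercept_scaling=100.0, max_iter=2000, tol=1e-6,
            random_state=seed % (2 ** 31 - 1))
        clf.fit(X, y)
        coefs[i] = clf.coef_[0]
    return coefs


def _deviance(model_X: np.ndarray, y: np.ndarray, clf) -> float:
    p = np.clip(clf.predict_proba(model_X)[:, 1], 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_select(design: DesignMatrix, cv_folds: int = 5, seed: int = 0,
                 rule: str = "min", n_lambda: int = 30,
                 lambda_min_ratio: float = 1e-3,
                 standardize: bool = False) -> LassoSelection:
    """LASSO drug selection with cross-validated deviance.

    The penalty grid descends geometrically from the smallest lambda that
    zeroes every coefficient.  ``rule='min'`` picks the lambda minimising
    mean CV deviance; ``rule='1se'`` the largest lambda within one standard
    error of that minimum.  Selected set = all demographic columns plus the
    drugs with nonzero coefficients at the chosen lambda.  Binary drug
    indicators share a scale, so standardisation is off by default.
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    y = design.y.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; cannot fit")

    # canonical row order: sorted by case id, so selection is row-order free
    order = np.argsort(design.case_ids, kind="stable")
    X = design.X.to_numpy(dtype=float)[order]
    y = y[order]
    case_ids = design.case_ids[order]
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd

    n = X.shape[0]
    ybar = y.mean()
    lambda_max = np.max(np.abs(X.T @ (y - ybar))) / n
    lambdas = np.geomspace(lambda_max, lambda_max * lambda_min_ratio, n_lambda)

    path = _l1_path(X, y, lambdas, seed)

    folds = _fold_of(case_ids, cv_folds, seed)
    dev = np.full((cv_folds, lambdas.size), np.nan)
    for k in range(cv_folds):
        train, test = folds != k, folds == k
        if y[train].min() == y[train].max() or test.sum() == 0:
            logger.warning("lasso_select: fold %d degenerate; skipped", k)
            continue
        n_train = int(train.sum())
        for i, lam in enumerate(lambdas):
            clf = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (n_train * lam), solver="liblinear",
                intercept_scaling=100.0, max_iter=2000, tol=1e-6,
                random_state=seed % (2 ** 31 - 1))
            try:
                clf.fit(X[train], y[train])
            except Exception:  # pragma: no cover - solver failure is rare
                logger.warning("lasso_select: fold %d lambda %.4g failed",
                               k, lam)
                continue
            dev[k, i] = _deviance(X[test], y[test], clf)

    mean_dev = np.nanmean(dev, axis=0)
    with np.errstate(invalid="ignore"):
        se_dev = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(
            np.sum(~np.isnan(dev), axis=0))
    i_min = int(np.nanargmin(mean_dev))
    lambda_min = float(lambdas[i_min])
    within = mean_dev <= mean_dev[i_min] + se_dev[i_min]
    i_1se = int(np.flatnonzero(within)[0])  # largest lambda (grid descends)
    lambda_1se = float(lambdas[i_1se])

    chosen = i_min if rule == "min" else i_1se
    cols = design.columns
    nz = np.abs(path[chosen]) > 0
    selected_drugs = [c for c, keep in zip(cols, nz)
                      if keep and c in design.drug_cols]
    selected = design.demographic_cols + selected_drugs

    path_df = pd.DataFrame(path.T, index=cols,
                           columns=[f"{lam:.6g}" for lam in lambdas])
    cv_df = pd.DataFrame({
        "lambda": lambdas,
        "mean_deviance": mean_dev,
        "se_deviance": se_dev,
        "n_nonzero": (np.abs(path) > 0).sum(axis=1),
    })
    return LassoSelection(
        selected=selected, selected_drugs=selected_drugs, lambdas=lambdas,
        path=path_df, cv_deviance=cv_df, lambda_min=lambda_min,
        lambda_1se=lambda_1se, rule=rule, n_folds=cv_folds, seed=seed)


@dataclass
class RiskModelResult:
    """Multivariate logistic fit: per-covariate ORs and model discrimination."""

    table: pd.DataFrame          # covariate, odds_ratio, ci bounds, p_value, significant
    auc: float
    converged: bool
    separation_suspected: bool
    n_used: int
    dropped: list[str] = field(default_factory=list)
    fitted_probabilities: np.ndarray | None = None
    llf: float = float("nan")


def logistic_fit(design: DesignMatrix, columns: Sequence[str] | None = None,
                 alpha: float = 0.01) -> RiskModelResult:
    """Maximum-likelihood logistic regression on the selected covariates.

    OR = exp(beta); 95% CI = exp(beta ± 1.96·se) from observed-information
    standard errors; Wald p-values; covariates with p < ``alpha`` flagged
    significant.  Constant columns are dropped with a warning.  Suspected
    (quasi-)separation is reported, never silently repaired.
    """
    cols = list(columns) if columns is not None else design.columns
    y = design.y.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; cannot fit")
    X = design.X[cols]
    dropped = [c for c in cols if X[c].nunique() <= 1]
    if dropped:
        logger.warning("logistic_fit: dropping constant covariate(s): %s",
                       dropped)
        X = X.drop(columns=dropped)
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    try:
        res = model.fit(disp=0, maxiter=200, method="lbfgs")
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:  # pragma: no cover
        logger.warning("logistic_fit: optimisation failed (%s)", exc)
        raise
    params = res.params
    se = res.bse
    separation = bool((np.abs(params.drop("const", errors="ignore")) > 15).any()
                      or (se > 100).any())
    if separation:
        logger.warning("logistic_fit: quasi-separation suspected "
                       "(extreme coefficient or standard error)")
    keep = [c for c in params.index if c != "const"]
    beta = params[keep]
    sd = se[keep]
    z = beta / sd
    p = 2 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({
        "covariate": keep,
        "coef": beta.to_numpy(),
        "se": sd.to_numpy(),
        "odds_ratio": np.exp(beta.to_numpy()),
        "ci_lower": np.exp(beta.to_numpy() - _Z975 * sd.to_numpy()),
        "ci_upper": np.exp(beta.to_numpy() + _Z975 * sd.to_numpy()),
        "p_value": p,
    })
    table["significant"] = table["p_value"] < alpha
    probs = np.asarray(res.predict(Xc))
    auc, _ = roc_auc(probs, design.y)
    return RiskModelResult(
        table=table.reset_index(drop=True), auc=auc, converged=converged,
        separation_suspected=separation, n_used=len(y), dropped=dropped,
        fitted_probabilities=probs, llf=float(res.llf))


def roc_auc(scores: Sequence[float], outcomes: Sequence[bool]
            ) -> tuple[float, pd.DataFrame]:
    """AUC by the Mann–Whitney rank formulation (ties count 0.5) plus the
    ROC curve points at every distinct threshold."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    n1 = int(outcomes.sum())
    n0 = outcomes.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(scores)
    auc = (ranks[outcomes].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, thresholds = _sk_roc_curve(outcomes.astype(int), scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return float(auc), curve


def forest_table(result: RiskModelResult,
                 reference_rows: Sequence[tuple[str, str]] = (
                     ("sex", "female"), ("age", "<36")),
                 alpha: float = 0.01) -> pd.DataFrame:
    """Export rows for a forest plot: reference levels (OR 1, no CI) first,
    fitted demographics next, then drugs by descending OR."""
    tbl = result.table
    is_drug = tbl["covariate"].str.startswith("drug:")
    demo = tbl[~is_drug]
    drugs = tbl[is_drug].sort_values(
        ["odds_ratio", "covariate"], ascending=[False, True],
        kind="mergesort")
    rows = [{
        "covariate": f"{factor}={level} (reference)",
        "odds_ratio": 1.0, "ci_lower": np.nan, "ci_upper": np.nan,
        "p_value": np.nan, "significant": False,
    } for factor, level in reference_rows]
    cols = ["covariate", "odds_ratio", "ci_lower", "ci_upper",
            "p_value", "significant"]
    out = pd.concat([pd.DataFrame(rows, columns=cols),
                     demo[cols], drugs[cols]], ignore_index=True)
    out["significant"] = out["p_value"] < alpha
    out.loc[out["p_value"].isna(), "significant"] = False
    return out
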