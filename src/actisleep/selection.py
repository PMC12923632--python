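"""Elastic-net logistic feature selection with split-sample validation.

The selector asks which of the per-person actigraphy features carry
case/control signal. The model is a penalized logistic regression whose
penalty mixes L1 and L2 through the mixing parameter alpha (0 = ridge,
1 = lasso). alpha is tuned by repeated participant-level k-fold
cross-validation: for each alpha on a 0-1 grid, many random re-partitions
of participants into folds are scored by out-of-fold AUC (at the
deviance-minimizing penalty strength along the regularization path), and
the alpha with the highest median AUC wins. The final model is fitted on
the odd-day feature table and validated on the even-day table; a
participant-level holdout can additionally be carved off before any
tuning. Selected features (nonzero coefficients) are then reduced by
hierarchical clustering of their correlation matrix, keeping one "lead"
feature (largest absolute coefficient) per cluster.

Imputation (column medians) and standardization statistics are always
learned on the training table and frozen for any evaluation table, so the
even-day validation never leaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

__all__ = [
    "SelectionConfig",
    "SelectionReport",
    "ClusterReduction",
    "ElasticNetSelector",
    "prepare_xy",
    "tune_alpha",
    "fit_select",
    "evaluate_auc",
    "auc_with_ci",
    "correlation_cluster_leads",
    "split_holdout",
]

#: scale factor applied to unpenalized covariate columns so their effective
#: penalty is negligible (coefficients are rescaled back after fitting)
_UNPEN_SCALE = 100.0


@dataclass
class SelectionConfig:
    """Tuning protocol for the elastic-net selection stage."""

    alpha_grid: tuple = tuple(round(0.05 * i, 2) for i in range(21))
    n_iterations: int = 1000
    n_folds: int = 10
    include_age_sex: bool = False
    feature_subset: str = "all"  # all | means_only | sds_only | medians_sds
    holdout_fraction: float = 0.15
    n_lambda: int = 10
    lambda_rule: str = "min"  # min = deviance-minimizing; 1se = sparser
    seed: int = 0

    def __post_init__(self) -> None:
        g = list(self.alpha_grid)
        if any(not 0.0 <= a <= 1.0 for a in g) or g != sorted(g):
            raise ValueError("alpha_grid must be sorted within [0, 1]")
        if self.feature_subset not in ("all", "means_only", "sds_only", "medians_sds"):
            raise ValueError("unknown feature_subset")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


@dataclass
class SelectionReport:
    variant: str
    best_alpha: float
    alpha_aucs: dict  # alpha -> dict(median=..., q25=..., q75=...)
    coefficients: pd.Series
    selected: list
    C_: float
    auc_train: dict | None = None
    auc_test: dict | None = None
    deviance_path: dict = field(default_factory=dict)


@dataclass
class ClusterReduction:
    corr: pd.DataFrame
    assignments: pd.Series  # feature -> cluster id
    leads: pd.Series  # cluster id -> lead feature
    lead_coefficients: pd.Series


def _subset_columns(cols: list[str], subset: str) -> list[str]:
    if subset == "all":
        return cols
    if subset == "means_only":
        return [c for c in cols if c.endswith("_mean")]
    if subset == "sds_only":
        return [c for c in cols if c.endswith("_sd")]
    return [c for c in cols if c.endswith("_sd") or c.endswith("_median")]


def prepare_xy(
    table: pd.DataFrame,
    config: SelectionConfig,
    label_col: str = "group",
    positive: str = "case",
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Split a cohort table into features, binary labels and covariates.

    Feature columns are the numeric trait aggregates (filtered by the
    configured subset); ``age``/``sex`` become unpenalized covariates when
    requested. Returns ``(X, y, unpenalized_cols)``.
    """
    meta = {label_col, "family_id", "parity_source", "n_days_used", "age", "sex"}
    feat_cols = [
        c for c in table.columns
        if c not in meta and pd.api.types.is_numeric_dtype(table[c])
    ]
    feat_cols = _subset_columns(feat_cols, config.feature_subset)
    X = table[feat_cols].copy()
    unpen: list[str] = []
    if config.include_age_sex:
        X["age"] = pd.to_numeric(table["age"])
        X["sex"] = (table["sex"].astype(str) == "M").astype(float)
        unpen = ["age", "sex"]
    y = (table[label_col].astype(str) == positive).to_numpy(dtype=int)
    return X, y, unpen


class ElasticNetSelector(BaseEstimator, ClassifierMixin):
    """Penalized logistic regression with frozen impute/standardize stats.

    Parameters follow the glmnet convention: ``alpha`` mixes L1 (alpha=1)
    and L2 (alpha=0); ``C`` is the inverse penalty strength (small C =
    strong penalty). ``unpenalized`` names columns (e.g. age, sex) whose
    coefficients should escape the penalty.

    Fitted attributes: ``coef_`` (Series on the standardized scale),
    ``intercept_``, ``medians_``, ``center_``, ``scale_``,
    ``selected_features_`` (penalized columns with nonzero coefficient).
    """

    def __init__(self, alpha: float = 0.5, C: float = 1.0,
                 unpenalized: tuple = (), max_iter: int = 5000, tol: float = 1e-4):
        self.alpha = alpha
        self.C = C
        self.unpenalized = unpenalized
        self.max_iter = max_iter
        self.tol = tol

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        Z = X[self.feature_names_in_].copy()
        Z = Z.fillna(self.medians_)
        Z = (Z - self.center_) / self.scale_
        M = Z.to_numpy(dtype=float)
        M[:, self._unpen_idx] *= _UNPEN_SCALE
        return M

    def fit(self, X: pd.DataFrame, y) -> "ElasticNetSelector":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        self.feature_names_in_ = list(X.columns)
        self.medians_ = X.median(skipna=True)
        Z = X.fillna(self.medians_)
        if not np.isfinite(Z.to_numpy(dtype=float)).all():
            raise ValueError("non-finite feature values after imputation")
        self.center_ = Z.mean()
        scale = Z.std(ddof=0)
        self.scale_ = scale.where(scale > 0, 1.0)
        self._unpen_idx = np.array(
            [i for i, c in enumerate(self.feature_names_in_) if c in set(self.unpenalized)],
            dtype=int,
        )
        M = self._design(X)
        est = LogisticRegression(
            solver="saga", l1_ratio=float(self.alpha),
            C=self.C, max_iter=self.max_iter, tol=self.tol, random_state=0,
        )
        est.fit(M, y)
        coef = est.coef_[0].copy()
        coef[self._unpen_idx] *= _UNPEN_SCALE  # back to standardized scale
        self.coef_ = pd.Series(coef, index=self.feature_names_in_)
        self.intercept_ = float(est.intercept_[0])
        self.classes_ = est.classes_
        pen = [c for c in self.feature_names_in_ if c not in set(self.unpenalized)]
        self.selected_features_ = [c for c in pen if self.coef_[c] != 0.0]
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.feature_names_in_].fillna(self.medians_) - self.center_) / self.scale_
        return Z.to_numpy(dtype=float) @ self.coef_.to_numpy() + self.intercept_

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


def _default_C_grid(n_lambda: int) -> np.ndarray:
    return np.logspace(-2.5, 1.5, n_lambda)


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fold_assignments(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.tile(np.arange(k), n // k + 1)[:n]
    rng.shuffle(folds)
    return folds


def _cv_path(
    X: pd.DataFrame, y: np.ndarray, alpha: float, C_grid: np.ndarray,
    folds: np.ndarray, unpenalized: tuple, rule: str = "min",
) -> tuple[np.ndarray, float, np.ndarray]:
    """One k-fold CV over the penalty path at fixed alpha.

    Returns ``(mean out-of-fold deviance per C, chosen C, out-of-fold
    scores at the chosen C)``. ``rule='min'`` picks the
    deviance-minimizing penalty; ``'1se'`` the strongest penalty within
    one standard error of that minimum (a sparser model).
    """
    k = folds.max() + 1
    n = len(y)
    oof = np.full((len(C_grid), n), np.nan)
    fold_dev = np.full((len(C_grid), k), np.nan)
    unpen_set = set(unpenalized)
    unpen_idx = np.array([i for i, c in enumerate(X.columns) if c in unpen_set], dtype=int)
    for f in range(k):
        tr, te = folds != f, folds == f
        if len(np.unique(y[tr])) < 2:
            continue
        # impute/standardize on the training fold only
        med = X.iloc[tr].median(skipna=True)
        Ztr = X.iloc[tr].fillna(med)
        mu, sd = Ztr.mean(), Ztr.std(ddof=0).replace(0.0, 1.0)
        Mtr = ((Ztr - mu) / sd).to_numpy(dtype=float)
        Mte = ((X.iloc[te].fillna(med) - mu) / sd).to_numpy(dtype=float)
        Mtr[:, unpen_idx] *= _UNPEN_SCALE
        Mte[:, unpen_idx] *= _UNPEN_SCALE
        # looser tolerance than the final fit: only the deviance curve and
        # out-of-fold scores matter along the scanning path
        est = LogisticRegression(
            solver="saga", l1_ratio=float(alpha), warm_start=True,
            max_iter=3000, tol=1e-3, random_state=0,
        )
        for ci, C in enumerate(C_grid):  # ascending C: strongest penalty first
            est.C = float(C)
            est.fit(Mtr, y[tr])
            p = est.predict_proba(Mte)[:, 1]
            oof[ci, te] = p
            fold_dev[ci, f] = _binomial_deviance(y[te], p)
    dev = np.array([
        _binomial_deviance(y[np.isfinite(row)], row[np.isfinite(row)]) if np.isfinite(row).any() else np.inf
        for row in oof
    ])
    best = int(np.argmin(dev))
    if rule == "1se":
        with np.errstate(invalid="ignore"):
            se = np.nanstd(fold_dev[best], ddof=1) / np.sqrt(np.isfinite(fold_dev[best]).sum())
        within = np.nonzero(dev <= dev[best] + se)[0]
        best = int(within.min())  # C_grid ascends: smallest C = strongest penalty
    return dev, float(C_grid[best]), oof[best]


def _rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC with 0.5 credit for ties (Mann-Whitney)."""
    r = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("single-class evaluation set")
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def auc_with_ci(y: np.ndarray, scores: np.ndarray, level: float = 0.95) -> dict:
    """AUC with an asymptotic rank-variance (DeLong-style) CI."""
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    auc = _rank_auc(y, scores)
    x, v = scores[y == 1], scores[y == 0]
    m, n = len(x), len(v)
    # placement values
    v10 = np.array([(np.sum(xi > v) + 0.5 * np.sum(xi == v)) / n for xi in x])
    v01 = np.array([(np.sum(x > vi) + 0.5 * np.sum(x == vi)) / m for vi in v])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return {
        "auc": float(auc),
        "ci_low": float(max(auc - half, 0.0)),
        "ci_high": float(min(auc + half, 1.0)),
        "n": int(m + n),
    }


def evaluate_auc(model: ElasticNetSelector, table: pd.DataFrame, config: SelectionConfig,
                 label_col: str = "group") -> dict:
    """Out-of-sample AUC (with CI) of a fitted selector on a cohort table."""
    X, y, _ = prepare_xy(table, config, label_col=label_col)
    return auc_with_ci(y, model.decision_function(X))


def split_holdout(table: pd.DataFrame, fraction: float, seed: int):
    """Participant-level holdout split (by table index)."""
    rng = np.random.default_rng(seed)
    ids = np.array(table.index)
    n_hold = int(round(len(ids) * fraction))
    hold = rng.choice(ids, size=n_hold, replace=False)
    hold_set = set(hold)
    main = table.loc[[i for i in ids if i not in hold_set]]
    return main, table.loc[list(hold)]


def tune_alpha(
    table: pd.DataFrame, config: SelectionConfig, label_col: str = "group"
) -> tuple[float, dict]:
    """Pick the elastic-net mixing parameter by repeated cross-validation.

    For each alpha on the grid, ``n_iterations`` random re-partitions of
    participants into ``n_folds`` folds are run; each iteration records
    the out-of-fold AUC at the deviance-minimizing penalty strength. The
    best alpha maximizes the median AUC; ties go to the smaller alpha
    (which tends sparser together with its stronger-L1 neighbours).
    """
    X, y, unpen = prepare_xy(table, config, label_col=label_col)
    if len(X) < 20:
        raise ValueError("need at least 20 participants to tune alpha")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(X) < config.n_folds:
        raise ValueError("fewer participants than folds")
    rng = np.random.default_rng(config.seed)
    C_grid = _default_C_grid(config.n_lambda)
    dist: dict[float, dict] = {}
    # same fold sequence for every alpha: paired comparisons across the grid
    fold_seeds = rng.integers(0, 2**31 - 1, size=config.n_iterations)
    for a in config.alpha_grid:
        aucs = []
        for it in range(config.n_iterations):
            it_rng = np.random.default_rng(fold_seeds[it])
            folds = _fold_assignments(len(y), config.n_folds, it_rng)
            _, _, oof = _cv_path(X, y, a, C_grid, folds, tuple(unpen))
            ok = np.isfinite(oof)
            aucs.append(_rank_auc(y[ok], oof[ok]))
        aucs = np.asarray(aucs)
        dist[a] = {
            "median": float(np.median(aucs)),
            "q25": float(np.quantile(aucs, 0.25)),
            "q75": float(np.quantile(aucs, 0.75)),
        }
    best = max(dist, key=lambda a: (dist[a]["median"], -a))
    return float(best), dist


def fit_select(
    table: pd.DataFrame,
    alpha: float,
    config: SelectionConfig,
    label_col: str = "group",
    variant: str | None = None,
    alpha_aucs: dict | None = None,
) -> tuple[SelectionReport, ElasticNetSelector]:
    """Fit the final elastic-net model at a chosen alpha.

    The penalty strength is chosen as the value minimizing mean
    out-of-fold binomial deviance in one seeded k-fold CV, then the model
    is refitted on the whole table at that strength. Features with
    nonzero coefficients form the selected set.
    """
    X, y, unpen = prepare_xy(table, config, label_col=label_col)
    rng = np.random.default_rng(config.seed + 1)
    folds = _fold_assignments(len(y), min(config.n_folds, len(y)), rng)
    C_grid = _default_C_grid(config.n_lambda)
    dev, best_C, _ = _cv_path(X, y, alpha, C_grid, folds, tuple(unpen),
                              rule=config.lambda_rule)
    sel = ElasticNetSelector(alpha=alpha, C=best_C, unpenalized=tuple(unpen))
    sel.fit(X, y)
    report = SelectionReport(
        variant=variant or config.feature_subset,
        best_alpha=alpha,
        alpha_aucs=alpha_aucs or {},
        coefficients=sel.coef_[sel.coef_ != 0.0],
        selected=sel.selected_features_,
        C_=best_C,
        deviance_path={float(c): float(d) for c, d in zip(C_grid, dev)},
        auc_train=evaluate_auc(sel, table, config, label_col=label_col),
    )
    return report, sel


def correlation_cluster_leads(
    table: pd.DataFrame,
    selected: list[str],
    coefficients: pd.Series,
    cut_height: float = 0.5,
) -> ClusterReduction:
    """Reduce selected features to cluster leads.

    Pearson correlations among the selected features are clustered
    agglomeratively with distance ``1 - |r|`` and complete linkage; the
    tree is cut at ``cut_height``. Within each cluster the feature with
    the largest absolute coefficient is the lead (ties break to column
    order).
    """
    if len(selected) < 2:
        raise ValueError("need at least 2 selected features to cluster")
    sub = table[selected]
    if (sub.std(ddof=0) == 0).any():
        bad = list(sub.columns[sub.std(ddof=0) == 0])
        raise ValueError(f"constant feature columns: {bad}")
    corr = sub.corr()
    d = 1.0 - corr.abs()
    np.fill_diagonal(d.values, 0.0)
    if cut_height <= 0:
        clusters = np.arange(1, len(selected) + 1)
    else:
        Z = linkage(squareform(d.to_numpy(), checks=False), method="complete")
        clusters = fcluster(Z, t=cut_height, criterion="distance")
    assignments = pd.Series(clusters, index=selected, name="cluster")
    leads = {}
    for cid in sorted(set(clusters)):
        members = [f for f in selected if assignments[f] == cid]
        leads[cid] = max(members, key=lambda f: (abs(coefficients.get(f, 0.0)), -selected.index(f)))
    leads_s = pd.Series(leads, name="lead")
    return ClusterReduction(
        corr=corr,
        assignments=assignments,
        leads=leads_s,
        lead_coefficients=pd.Series({c: coefficients.get(f, 0.0) for c, f in leads.items()}),
    )
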