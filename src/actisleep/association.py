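"""Day-level mixed-effects models and cohort association statistics.

The central model asks whether case status modulates the within-person
coupling between daytime physical activity and the following night's
sleep. For a sleep outcome y (e.g. total sleep minutes) and an activity
exposure x (e.g. sedentary hours) measured per participant-day:

    y ~ x + group + age + age^2 + sex + (group x interaction)
        + (1 | family) + (1 | participant nested in family)

Variance components are estimated by REML; likelihood-ratio tests of the
exposure main effect and of the group-by-exposure interaction refit the
nested models by maximum likelihood. The group-specific slopes obey the
exact identity: case slope = control slope + interaction coefficient.

The module also provides Benjamini-Hochberg FDR conversion, stepwise-AIC
trait regressions, a seasonal-confounding scan, covariate-adjusted group
comparisons and Spearman rank-correlation matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "fit_day_level_model",
    "lrt",
    "bh_fdr",
    "stepwise_aic",
    "seasonal_scan",
    "group_compare",
    "spearman_matrix",
]


@dataclass
class AssociationResult:
    outcome: str
    exposure: str
    params: pd.Series
    bse: pd.Series
    slope_control: float
    slope_case: float
    interaction: float
    lrt_exposure: dict = field(default_factory=dict)
    lrt_interaction: dict = field(default_factory=dict)
    converged: bool = True
    singular: bool = False
    method: str = "mixedlm"
    vc: dict = field(default_factory=dict)


def _formula(outcome: str, exposure: str, adjust: bool, interaction: bool) -> str:
    rhs = [exposure, "C(group, Treatment('control'))"]
    if interaction:
        rhs.append(f"{exposure}:C(group, Treatment('control'))")
    if adjust:
        rhs += ["age", "I(age**2)", "C(sex)"]
    return f"{outcome} ~ " + " + ".join(rhs)


def _fit_mixed(formula: str, df: pd.DataFrame, reml: bool):
    model = smf.mixedlm(
        formula,
        data=df,
        groups=df["family_id"],
        re_formula="1",
        vc_formula={"participant": "0 + C(participant_id)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml, method=["lbfgs", "powell"])
    return res


def fit_day_level_model(
    df: pd.DataFrame,
    outcome: str = "total_sleep_min",
    exposure: str = "sedentary_hours",
    adjust: bool = True,
    do_lrt: bool = True,
) -> AssociationResult:
    """Fit the day-level sleep-activity interaction model.

    ``df`` needs columns ``participant_id``, ``family_id``, ``group``
    ('case'/'control'), ``age``, ``sex`` and the outcome/exposure. The
    interaction model yields group-specific slopes; main-effect LRTs come
    from the model without the interaction, the interaction LRT from
    comparing the two (both by ML refits). With ``adjust=False`` the
    covariates age, age^2 and sex are omitted (unadjusted slopes).

    Rows with one participant mapping to several families are rejected;
    a (near-)zero residual variance falls back to an exact OLS fit,
    flagged ``singular``.
    """
    fam_per_ind = df.groupby("participant_id")["family_id"].nunique()
    if (fam_per_ind > 1).any():
        raise ValueError("participant IDs must nest within a single family")
    if df[outcome].nunique() <= 1:
        raise ValueError("outcome is constant")

    f_full = _formula(outcome, exposure, adjust, interaction=True)
    f_main = _formula(outcome, exposure, adjust, interaction=False)

    ols_full = smf.ols(f_full, data=df).fit()
    if ols_full.mse_resid < 1e-10 * max(df[outcome].var(), 1.0):
        # deterministic data: random effects are unidentifiable, OLS exact
        params, bse = ols_full.params, ols_full.bse
        res = None
        singular, method = True, "ols"
    else:
        res = _fit_mixed(f_full, df, reml=True)
        params, bse = res.fe_params, res.bse.loc[res.fe_params.index]
        rel = 1e-6 * float(res.scale)
        singular = bool(
            float(res.cov_re.values[0, 0]) < rel
            or (len(res.vcomp) and float(res.vcomp[0]) < rel)
        )
        method = "mixedlm"

    inter_name = [i for i in params.index if ":" in i and exposure in i]
    interaction = float(params[inter_name[0]]) if inter_name else 0.0
    slope_control = float(params[exposure])
    slope_case = slope_control + interaction

    out = AssociationResult(
        outcome=outcome,
        exposure=exposure,
        params=params,
        bse=bse,
        slope_control=slope_control,
        slope_case=slope_case,
        interaction=interaction,
        converged=bool(getattr(res, "converged", True)) if res is not None else True,
        singular=singular,
        method=method,
        vc={
            "family_var": float(res.cov_re.values[0, 0]) if res is not None else 0.0,
            "participant_var": float(res.vcomp[0]) if res is not None and len(res.vcomp) else 0.0,
            "resid_var": float(res.scale) if res is not None else float(ols_full.mse_resid),
        },
    )

    if do_lrt and method == "mixedlm":
        f_noexp = _formula(outcome, "1", adjust, interaction=False)
        ml_full = _fit_mixed(f_full, df, reml=False)
        ml_main = _fit_mixed(f_main, df, reml=False)
        ml_noexp = _fit_mixed(f_noexp, df, reml=False)
        out.lrt_exposure = lrt(ml_noexp, ml_main)
        out.lrt_interaction = lrt(ml_main, ml_full)
    return out


def lrt(res_reduced, res_full) -> dict:
    """Likelihood-ratio test of nested fixed-effect specifications.

    Both results must be maximum-likelihood fits on the same rows. The
    statistic 2*(llf_full - llf_reduced) is referred to chi-square with
    df equal to the fixed-parameter difference.
    """
    k_full = len(getattr(res_full, "fe_params", res_full.params))
    k_red = len(getattr(res_reduced, "fe_params", res_reduced.params))
    if k_full < k_red:
        raise ValueError("models are not nested (full has fewer parameters)")
    if res_full.nobs != res_reduced.nobs:
        raise ValueError("models fitted on different rows")
    stat = max(2.0 * (res_full.llf - res_reduced.llf), 0.0)
    df = k_full - k_red
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    if df == 0 and stat == 0.0:
        p = 1.0
    return {"statistic": float(stat), "df": int(df), "p_value": p}


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def stepwise_aic(
    y: pd.Series,
    candidates: pd.DataFrame,
    direction: str = "both",
    max_steps: int = 100,
) -> dict:
    """Stepwise linear-model selection guided by AIC.

    Starting from the intercept-only model, variables are added (and, for
    ``direction='both'``, removed) one at a time, taking the move that
    most lowers AIC, until no move improves it. Perfectly collinear
    candidate pairs (|r| = 1) are resolved by dropping the later column
    before the search.

    Returns selected names, the fitted OLS results, R^2 and adjusted R^2.
    """
    if direction not in ("forward", "both"):
        raise ValueError("direction must be 'forward' or 'both'")
    X = candidates.copy()
    dropped = []
    corr = X.corr().abs()
    cols = list(X.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if b not in dropped and a not in dropped and corr.loc[a, b] >= 1.0 - 1e-12:
                dropped.append(b)
    X = X.drop(columns=dropped)
    if len(y) < 5 * max(len(X.columns), 1):
        warnings.warn("fewer than 5 rows per candidate; stepwise may overfit")

    def fit(cols: list[str]):
        design = sm.add_constant(X[cols]) if cols else pd.DataFrame(
            {"const": np.ones(len(y))}, index=X.index
        )
        return sm.OLS(np.asarray(y, dtype=float), design).fit()

    selected: list[str] = []
    current = fit(selected)
    for _ in range(max_steps):
        moves = []
        for c in X.columns:
            if c not in selected:
                moves.append(("add", c, fit(selected + [c]).aic))
        if direction == "both":
            for c in selected:
                remaining = [s for s in selected if s != c]
                moves.append(("drop", c, fit(remaining).aic))
        if not moves:
            break
        op, c, aic = min(moves, key=lambda m: m[2])
        if aic >= current.aic - 1e-9:
            break
        selected = selected + [c] if op == "add" else [s for s in selected if s != c]
        current = fit(selected)
    return {
        "selected": selected,
        "model": current,
        "r2": float(current.rsquared),
        "adj_r2": float(current.rsquared_adj),
        "dropped_collinear": dropped,
        "aic": float(current.aic),
    }


def _season_of(dates: pd.Series) -> pd.Series:
    m = pd.DatetimeIndex(dates).month
    return pd.Series(
        np.select(
            [np.isin(m, [12, 1, 2]), np.isin(m, [3, 4, 5]), np.isin(m, [6, 7, 8])],
            ["winter", "spring", "summer"],
            default="autumn",
        ),
        index=dates.index,
    )


def seasonal_scan(
    day_table: pd.DataFrame,
    trait_cols: list[str],
    date_col: str = "date",
    alpha: float = 0.05,
) -> dict:
    """Test each trait for seasonal structure, with BH and post hoc pairs.

    Season is the meteorological quarter (northern hemisphere) of each
    day's start date. Per trait, a mixed model with a season fixed factor
    and a participant random intercept is compared against the
    intercept-only model by ML likelihood ratio (omnibus p); the omnibus
    p-values are BH-corrected across traits, and BH-significant traits
    get all pairwise season contrasts (Wald, BH within trait). Seasons
    with zero days are omitted from the contrasts.
    """
    df = day_table.copy()
    df["season"] = _season_of(df[date_col])
    results = {}
    omnibus_p = []
    for trait in trait_cols:
        sub = df.dropna(subset=[trait]).copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = smf.mixedlm(
                f"{trait} ~ C(season)", data=sub, groups=sub["participant_id"]
            ).fit(reml=False)
            null = smf.mixedlm(f"{trait} ~ 1", data=sub, groups=sub["participant_id"]).fit(
                reml=False
            )
        test = lrt(null, full)
        results[trait] = {"omnibus": test, "fit": full}
        omnibus_p.append(test["p_value"])
    qs = bh_fdr(omnibus_p)
    seasons_present = sorted(df["season"].unique())
    for trait, q in zip(trait_cols, qs):
        results[trait]["q_value"] = float(q)
        results[trait]["pairwise"] = None
        if q < alpha:
            full = results[trait]["fit"]
            names = full.fe_params.index
            cov = full.cov_params().loc[names, names]

            def coef_of(season: str):
                hits = [nm for nm in names if f"[T.{season}]" in nm]
                return hits[0] if hits else None

            pairs, ps = [], []
            for i, a in enumerate(seasons_present):
                for b in seasons_present[i + 1:]:
                    ca, cb = coef_of(a), coef_of(b)
                    vec = pd.Series(0.0, index=names)
                    if ca:
                        vec[ca] = 1.0
                    if cb:
                        vec[cb] = -1.0
                    est = float(vec @ full.fe_params)
                    se = float(np.sqrt(vec @ cov @ vec))
                    z = est / se if se > 0 else 0.0
                    p = 2 * stats.norm.sf(abs(z))
                    pairs.append({"pair": (a, b), "estimate": est, "se": se, "p_value": p})
                    ps.append(p)
            qpair = bh_fdr(ps)
            for rec, qv in zip(pairs, qpair):
                rec["q_value"] = float(qv)
            results[trait]["pairwise"] = pairs
        results[trait].pop("fit", None)
    return results


def group_compare(
    feature_table: pd.DataFrame,
    feature_cols: list[str],
    contrast: tuple[str, str],
    group_col: str = "group",
    method: str = "lm",
) -> pd.DataFrame:
    """Covariate-adjusted group contrasts per feature, with BH q-values.

    Fits ``feature ~ group + age + age^2 + sex`` per feature and reports
    the ``contrast[0] - contrast[1]`` adjusted difference with p and BH q
    across features. ``method='ranksum'`` swaps in a Wilcoxon rank-sum
    test (unadjusted). Groups with fewer than 3 members flag the
    contrast unstable; a group contrasted against itself gives 0 exactly.
    """
    df = feature_table
    groups = df[group_col].astype(str)
    if groups.nunique() < 2 and contrast[0] != contrast[1]:
        raise ValueError("need at least 2 non-empty groups")
    rows = []
    for feat in feature_cols:
        if contrast[0] == contrast[1]:
            rows.append({"feature": feat, "estimate": 0.0, "p_value": 1.0, "unstable": False})
            continue
        counts = groups.value_counts()
        unstable = any(counts.get(g, 0) < 3 for g in contrast)
        sub = df.dropna(subset=[feat])
        if method == "ranksum":
            a = sub.loc[sub[group_col] == contrast[0], feat]
            b = sub.loc[sub[group_col] == contrast[1], feat]
            stat, p = stats.ranksums(a, b)
            est = float(a.median() - b.median())
        else:
            fit = smf.ols(
                f"Q('{feat}') ~ C({group_col}) + age + I(age**2) + C(sex)", data=sub
            ).fit()
            names = fit.params.index
            vec = pd.Series(0.0, index=names)
            for g, sign in zip(contrast, (1.0, -1.0)):
                hits = [nm for nm in names if nm.startswith(f"C({group_col})[T.{g}]")]
                if hits:
                    vec[hits[0]] += sign
            tt = fit.t_test(vec.to_numpy())
            est, p = float(np.atleast_1d(tt.effect)[0]), float(np.atleast_1d(tt.pvalue).ravel()[0])
        rows.append({"feature": feat, "estimate": est, "p_value": p, "unstable": unstable})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out


def spearman_matrix(activity_means: pd.DataFrame, sleep_means: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlations of activity traits against sleep traits.

    Rows index the activity columns, columns the sleep columns. Constant
    columns yield missing entries. Requires at least 3 participants.
    """
    if len(activity_means) < 3:
        raise ValueError("need at least 3 participants")
    out = pd.DataFrame(index=activity_means.columns, columns=sleep_means.columns, dtype=float)
    for a in activity_means.columns:
        for s in sleep_means.columns:
            x, y = activity_means[a], sleep_means[s]
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].nunique() <= 1 or y[ok].nunique() <= 1:
                out.loc[a, s] = np.nan
                continue
            rho, _ = stats.spearmanr(x[ok], y[ok])
            out.loc[a, s] = rho
    return out
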