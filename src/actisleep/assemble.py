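"""Per-participant aggregation and cohort-wide z-scoring of daily traits.

Each base trait measured per participant-day is reduced to its
within-individual mean, median and SD across valid days — separately for
odd days, even days, or all days — and the resulting per-person feature
columns are z-scored against the whole assembled sample (cases and
relatives together). Clock-time traits (sleep onset, wake time, window
onsets) are aggregated on the circle: a linear average of onsets around
midnight would be off by twelve hours.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CIRCULAR_TRAITS",
    "aggregate_participant",
    "aggregate_cohort",
    "zscore_table",
    "assemble_parity_tables",
    "CohortZScorer",
]

#: clock-hour traits aggregated with circular statistics (period 24 h)
CIRCULAR_TRAITS = frozenset(
    {"onset_time", "wake_time", "onset_clock", "m10_onset", "m5_onset", "l10_onset", "l5_onset"}
)


def _circular_mean_sd(hours: np.ndarray, period: float = 24.0) -> tuple[float, float]:
    """Resultant-vector mean and circular SD of clock-hour values."""
    ang = 2 * np.pi * hours / period
    c, s = np.cos(ang).mean(), np.sin(ang).mean()
    r = float(np.hypot(c, s))
    mean = float((np.arctan2(s, c) * period / (2 * np.pi)) % period)
    if mean >= period:  # float fold-over of a tiny negative angle
        mean -= period
    sd = float(np.sqrt(max(-2.0 * np.log(max(r, 1e-300)), 0.0)) * period / (2 * np.pi))
    return mean, sd


def _circular_median(hours: np.ndarray, period: float = 24.0) -> float:
    """Value minimizing total circular distance (evaluated at the data)."""
    h = hours % period
    best, best_cost = float("nan"), np.inf
    for cand in h:
        d = np.abs(h - cand)
        d = np.minimum(d, period - d)
        cost = d.sum()
        if cost < best_cost:
            best_cost, best = cost, float(cand)
    return best


def aggregate_participant(
    day_rows: pd.DataFrame,
    parity: str = "all",
    trait_cols: list[str] | None = None,
) -> pd.Series:
    """Aggregate one participant's day rows to mean/median/SD features.

    ``parity`` filters to odd days, even days (by ``day_index``) or all.
    Statistics use non-missing day values only; SDs use ddof=1 and are 0
    for a single day. Traits listed in :data:`CIRCULAR_TRAITS` use
    circular statistics.
    """
    df = day_rows
    if parity not in ("odd", "even", "all"):
        raise ValueError("parity must be odd|even|all")
    if parity != "all":
        want = 1 if parity == "odd" else 0
        df = df[df["day_index"] % 2 == want]
    if len(df) == 0:
        raise ValueError("zero valid days after parity filtering")
    if trait_cols is None:
        skip = {"participant_id", "family_id", "day_index", "group", "age", "sex", "date"}
        trait_cols = [c for c in df.columns if c not in skip and pd.api.types.is_numeric_dtype(df[c])]

    out: dict[str, float] = {}
    for c in trait_cols:
        vals = df[c].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            out[f"{c}_mean"] = out[f"{c}_median"] = out[f"{c}_sd"] = np.nan
            continue
        if c in CIRCULAR_TRAITS:
            mean, sd = _circular_mean_sd(vals)
            med = _circular_median(vals)
        else:
            mean, med = float(np.mean(vals)), float(np.median(vals))
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out[f"{c}_mean"], out[f"{c}_median"], out[f"{c}_sd"] = mean, med, sd
    out["n_days_used"] = float(len(df))
    return pd.Series(out)


def aggregate_cohort(
    day_table: pd.DataFrame,
    parity: str = "all",
    trait_cols: list[str] | None = None,
    meta_cols: tuple[str, ...] = ("family_id", "group", "age", "sex"),
) -> pd.DataFrame:
    """Aggregate every participant in a stacked day-level table."""
    rows = []
    for pid, grp in day_table.groupby("participant_id", sort=True):
        row = aggregate_participant(grp, parity=parity, trait_cols=trait_cols)
        row["participant_id"] = pid
        for mc in meta_cols:
            if mc in grp.columns:
                row[mc] = grp[mc].iloc[0]
        rows.append(row)
    out = pd.DataFrame(rows).set_index("participant_id")
    out["parity_source"] = parity
    return out


class CohortZScorer(BaseEstimator, TransformerMixin):
    """Column-wise z-scoring against the whole assembled cohort.

    scikit-learn style transformer: :meth:`fit` learns per-column mean and
    SD (population SD, ddof=0) over non-missing entries; :meth:`transform`
    standardizes, leaving missing cells missing. Constant columns are
    dropped with a warning (their z-score is undefined).
    """

    def __init__(self, drop_constant: bool = True):
        self.drop_constant = drop_constant

    def fit(self, X: pd.DataFrame, y=None) -> "CohortZScorer":
        if len(X) < 2:
            raise ValueError("need at least 2 rows to z-score")
        num = X.select_dtypes(include=[np.number])
        self.mean_ = num.mean(skipna=True)
        self.scale_ = num.std(skipna=True, ddof=0)
        keep = self.scale_ > 0
        self.dropped_ = list(num.columns[~keep])
        if self.dropped_:
            import warnings

            warnings.warn(f"dropping constant columns: {self.dropped_}")
        self.columns_ = list(num.columns[keep]) if self.drop_constant else list(num.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = (X[self.columns_] - self.mean_[self.columns_]) / self.scale_[self.columns_]
        return out


def assemble_parity_tables(
    day_table: pd.DataFrame, trait_cols: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build z-scored odd-day and even-day feature tables.

    Columns constant (or all-missing) in either parity table are dropped
    from both, so the two tables always share an identical column set in
    identical order.
    """
    tables = {
        p: aggregate_cohort(day_table, parity=p, trait_cols=trait_cols)
        for p in ("odd", "even")
    }
    bad: set[str] = set()
    for t in tables.values():
        num = t.select_dtypes(include=[np.number])
        sd = num.std(skipna=True, ddof=0)
        bad |= set(num.columns[(sd == 0) | sd.isna()])
    bad -= {"n_days_used"}
    out = []
    import warnings

    if bad:
        warnings.warn(f"dropping degenerate columns from both parities: {sorted(bad)}")
    for p in ("odd", "even"):
        t = tables[p].drop(columns=sorted(bad))
        out.append(zscore_table(t))
    return out[0], out[1]


def zscore_table(rows: pd.DataFrame, exclude: tuple[str, ...] = ("n_days_used",)) -> pd.DataFrame:
    """Z-score feature columns using the full sample as the distribution.

    Metadata columns (non-numeric, plus ``exclude``) pass through
    unchanged; each standardized column has mean 0 and SD 1 (ddof=0) over
    its non-missing entries.
    """
    num_cols = [
        c for c in rows.columns
        if pd.api.types.is_numeric_dtype(rows[c]) and c not in exclude
    ]
    scorer = CohortZScorer().fit(rows[num_cols])
    z = scorer.transform(rows[num_cols])
    passthrough = [
        c for c in rows.columns if c not in scorer.columns_ and c not in scorer.dropped_
    ]
    return pd.concat([z, rows[passthrough]], axis=1)
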