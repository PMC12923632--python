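"""Non-wear detection, day segmentation, QC exclusion and odd/even split.

The rules implemented here mirror standard multi-day wrist-actigraphy QC:
non-wear is a continuous stretch of exactly-zero activity lasting more than
100 min; days are noon-anchored so each night's sleep lies within one
window; participants are excluded with fewer than 5 valid days (a valid day
has at least 20 h of wear) or an average of 3 h of sleep or less per day;
and recording days are numbered from 1 and partitioned into odd and even
days for split-sample validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import EpochSeries

__all__ = [
    "DayWindow",
    "QCReport",
    "detect_nonwear",
    "segment_days",
    "apply_qc",
    "split_odd_even",
]

NONWEAR_MIN_MINUTES = 100.0  # runs strictly longer than this are non-wear
QC_MIN_VALID_DAYS = 5
QC_MIN_HOURS_PER_DAY = 20.0
QC_MAX_SHORT_SLEEP = 3.0  # mean sleep <= 3 h excludes


@dataclass
class DayWindow:
    """One noon-to-noon recording day, half-open ``[start, end)``."""

    day_index: int  # 1-based, first recorded day = 1
    start: pd.Timestamp
    end: pd.Timestamp
    hours_valid: float
    is_weekend: bool

    @property
    def parity(self) -> str:
        return "odd" if self.day_index % 2 == 1 else "even"


@dataclass
class QCReport:
    participant_id: str
    n_valid_days: int
    mean_hours_per_day: float
    mean_sleep_hours: float
    exclusion_reasons: list = field(default_factory=list)

    @property
    def included(self) -> bool:
        return not self.exclusion_reasons


def _zero_runs(activity: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of exact zeros as half-open index intervals."""
    z = np.round(activity, 3) == 0.0
    if not z.any():
        return []
    padded = np.concatenate([[False], z, [False]])
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts, ends))


def detect_nonwear(
    series: EpochSeries,
    exempt_windows: list[tuple[pd.Timestamp, pd.Timestamp]] | None = None,
    threshold_min: float = NONWEAR_MIN_MINUTES,
) -> EpochSeries:
    """Flag non-wear epochs on a copy of ``series``.

    A maximal run of exactly-zero activity strictly longer than
    ``threshold_min`` minutes (default 100) is flagged ``wear=False``.
    Zero runs overlapping any interval in ``exempt_windows`` (candidate
    sleep spans, where long stillness is expected) are left as wear.

    Activity is compared against zero after rounding to 3 decimals, so
    float dust cannot break run detection.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    data = series.data.copy()
    epm = series.epoch_len / 60.0
    wear = np.ones(len(data), dtype=bool)
    ts = data["timestamp"].to_numpy()
    for s, e in _zero_runs(data["activity"].to_numpy()):
        if (e - s) * epm <= threshold_min:
            continue
        if exempt_windows:
            run_start, run_end = ts[s], ts[e - 1]
            if any(run_start <= pd.Timestamp(b) and pd.Timestamp(a) <= run_end
                   for a, b in exempt_windows):
                continue
        wear[s:e] = False
    data["wear"] = wear
    return EpochSeries(participant_id=series.participant_id, data=data)


def segment_days(series: EpochSeries) -> list[DayWindow]:
    """Cut a recording into consecutive noon-anchored day windows.

    Day 1 is the window containing the first epoch; partial first/last
    windows are kept with ``hours_valid < 24``. Weekend status comes from
    the civil date of the window's start (Saturday/Sunday).
    """
    data = series.data
    if len(data) == 0 or (data["timestamp"].iloc[-1] - data["timestamp"].iloc[0]) < pd.Timedelta(hours=24):
        import warnings

        warnings.warn("series shorter than one day window; no days segmented")
        return []
    epm = series.epoch_len / 60.0
    first = data["timestamp"].iloc[0]
    anchor = first.normalize() + pd.Timedelta(hours=12)
    if anchor > first:
        anchor -= pd.Timedelta(days=1)
    last = data["timestamp"].iloc[-1]
    out = []
    idx = 1
    start = anchor
    ts = data["timestamp"]
    while start <= last:
        end = start + pd.Timedelta(days=1)
        mask = (ts >= start) & (ts < end)
        hours_valid = float(data.loc[mask, "wear"].sum()) * epm / 60.0
        out.append(
            DayWindow(
                day_index=idx,
                start=start,
                end=end,
                hours_valid=hours_valid,
                is_weekend=start.dayofweek >= 5,
            )
        )
        idx += 1
        start = end
    return out


def apply_qc(
    days: list[DayWindow],
    sleep_hours_by_day: dict[int, float],
    participant_id: str = "",
    min_valid_days: int = QC_MIN_VALID_DAYS,
    min_hours_per_day: float = QC_MIN_HOURS_PER_DAY,
    short_sleep_hours: float = QC_MAX_SHORT_SLEEP,
) -> QCReport:
    """Apply the participant-level exclusion rules.

    A day is valid when it has at least ``min_hours_per_day`` (20) hours of
    wear. A participant is excluded with fewer than ``min_valid_days`` (5)
    valid days (reason ``insufficient_days``) or with mean nightly sleep of
    ``short_sleep_hours`` (3) hours or less (reason ``short_sleep``).
    """
    valid = [d for d in days if d.hours_valid >= min_hours_per_day]
    sleep_vals = [sleep_hours_by_day[d.day_index] for d in valid if d.day_index in sleep_hours_by_day]
    mean_sleep = float(np.mean(sleep_vals)) if sleep_vals else 0.0
    mean_hours = float(np.mean([d.hours_valid for d in valid])) if valid else 0.0
    reasons = []
    if len(valid) < min_valid_days:
        reasons.append("insufficient_days")
    if mean_sleep <= short_sleep_hours:
        reasons.append("short_sleep")
    return QCReport(
        participant_id=participant_id,
        n_valid_days=len(valid),
        mean_hours_per_day=mean_hours,
        mean_sleep_hours=mean_sleep,
        exclusion_reasons=reasons,
    )


def split_odd_even(days: list[DayWindow]):
    """Partition day windows by the parity of their day index.

    Returns ``(odd_days, even_days, balance)`` where ``balance`` reports a
    Fisher exact test of weekend/weekday counts between the two partitions
    (the split-sample design requires weekend balance). When all days share
    one parity the test is undefined and flagged.
    """
    if len(days) < 2:
        raise ValueError("need at least 2 days to split")
    odd = [d for d in days if d.parity == "odd"]
    even = [d for d in days if d.parity == "even"]
    if not odd or not even:
        return odd, even, {"statistic": np.nan, "p_value": np.nan, "defined": False}
    table = np.array(
        [
            [sum(d.is_weekend for d in odd), sum(not d.is_weekend for d in odd)],
            [sum(d.is_weekend for d in even), sum(not d.is_weekend for d in even)],
        ]
    )
    odds, p = stats.fisher_exact(table)
    return odd, even, {"statistic": float(odds), "p_value": float(p), "defined": True, "table": table}
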