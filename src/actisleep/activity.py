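"""Intensity classification, bout/block detection and daily activity traits.

Per-epoch activity is classified into inactivity / light / moderate /
vigorous by mg cutoffs (defaults 40/100/400, the conventional wrist
thresholds; configurable). Two aggregation concepts are distinguished:

* a **bout** is a window of at least a prescribed duration in which 80% or
  more of the time is spent at the target level (e.g. an inactivity bout of
  30 min needs 24 of 30 min inactive);
* a **block** is a maximal run of consecutive epochs all at one level.

Daily circadian-window traits (M10/M5 most-active and L10 least-active
windows, with co-registered light) and the day-level activity summary
(sedentary time outside the sleep period, mixed activity, sitting/standing,
unbouted durations, context-specific mean acceleration) complete the
per-day trait set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import DayWindow
from .simulate import EpochSeries

__all__ = [
    "IntensityCutoffs",
    "BoutRecord",
    "CircadianWindowTraits",
    "DayActivitySummary",
    "classify_intensity",
    "detect_bouts",
    "detect_blocks",
    "rolling_window_traits",
    "day_activity_summary",
]

LEVELS = ("inactive", "light", "moderate", "vigorous")
#: default duration bins, minutes (lower-inclusive, upper-exclusive)
INACTIVE_BINS = ((10, 20), (20, 30), (30, None))
MVPA_BINS = ((1, 5), (5, 10), (10, None))


@dataclass(frozen=True)
class IntensityCutoffs:
    """Contiguous half-open partition of [0, inf) mg into intensity classes.

    inactive [0, light_at); light [light_at, moderate_at);
    moderate [moderate_at, vigorous_at); vigorous [vigorous_at, inf).
    """

    light_at: float = 40.0
    moderate_at: float = 100.0
    vigorous_at: float = 400.0

    def __post_init__(self) -> None:
        if not 0 < self.light_at < self.moderate_at < self.vigorous_at:
            raise ValueError("cutoffs must be strictly increasing and positive")

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.light_at, self.moderate_at, self.vigorous_at])


@dataclass
class BoutRecord:
    level: str
    start_idx: int
    end_idx: int  # half-open
    duration_min: float
    frac_at_level: float
    duration_bin: str


@dataclass
class CircadianWindowTraits:
    m10_onset: float  # clock hours of window start
    m10_mean: float
    m10_mean_light: float
    m10_max_light: float
    m5_onset: float
    m5_mean: float
    m5_max_light: float
    l10_onset: float
    l10_mean: float
    l5_onset: float
    l5_mean: float


@dataclass
class DayActivitySummary:
    time_sedentary: float  # hours, inactive wear time outside sleep period
    time_mixed_activity: float  # hours
    time_sit_stand: float  # hours
    unbouted_light_dur: float  # minutes
    unbouted_moderate_dur: float  # minutes
    n_blocks_by_level_and_bin: dict = field(default_factory=dict)
    n_bouts_mvpa_5_10: int = 0
    mean_accel_by_context: dict = field(default_factory=dict)
    weartime: float = 0.0  # hours
    sedentary_flagged_no_sleep: bool = False


def classify_intensity(
    series: EpochSeries, cutoffs: IntensityCutoffs = IntensityCutoffs()
) -> np.ndarray:
    """Label each epoch with its intensity class.

    Returns an object array with one of :data:`LEVELS` per wear-valid epoch
    and ``None`` for non-wear epochs, so labeled time always equals wear
    time. Boundary values belong to the upper class (half-open intervals).
    """
    act = series.data["activity"].to_numpy(dtype=float)
    wear = series.data["wear"].to_numpy(dtype=bool)
    idx = np.searchsorted(cutoffs.edges, act, side="right")
    labels = np.array(LEVELS, dtype=object)[idx]
    labels[~wear] = None
    return labels


def _bin_label(duration_min: float, bins: Sequence[tuple[float, float | None]]) -> str:
    for lo, hi in bins:
        if duration_min >= lo and (hi is None or duration_min < hi):
            return f">={lo}" if hi is None else f"{lo}-{hi}"
    return "unbinned"


def _at_level(labels: np.ndarray, level) -> np.ndarray:
    lv = {level} if isinstance(level, str) else set(level)
    return np.array([l in lv for l in labels], dtype=bool)


def detect_bouts(
    labels: np.ndarray,
    level,
    min_duration_min: float,
    frac: float = 0.8,
    epoch_min: float = 1.0,
    bins: Sequence[tuple[float, float | None]] | None = None,
) -> list[BoutRecord]:
    """Greedy left-to-right bout detection under the 80% rule.

    A bout starts at an at-level epoch. The minimum window of
    ``min_duration_min`` starting there qualifies when its at-level
    fraction is at least ``frac``; the window is then extended while the
    fraction stays at or above ``frac`` and trimmed back so it ends on an
    at-level epoch (never below the minimum window). Bouts of the same
    level do not overlap; scanning resumes after each bout.

    ``level`` may be one level name or a set (e.g. moderate+vigorous for
    MVPA bouts).
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    at = _at_level(labels, level)
    n = len(at)
    min_ep = max(int(round(min_duration_min / epoch_min)), 1)
    if bins is None:
        bins = INACTIVE_BINS if level == "inactive" else MVPA_BINS
    csum = np.concatenate([[0], np.cumsum(at)])

    out: list[BoutRecord] = []
    i = 0
    while i < n:
        if not at[i]:
            i += 1
            continue
        if i + min_ep > n:
            break
        base_frac = (csum[i + min_ep] - csum[i]) / min_ep
        if base_frac < frac - 1e-12:
            i += 1
            continue
        j = i + min_ep
        while j < n and (csum[j + 1] - csum[i]) / (j + 1 - i) >= frac - 1e-12:
            j += 1
        # end on an at-level epoch, but never shrink below the minimum window
        while j > i + min_ep and not at[j - 1]:
            j -= 1
        dur = (j - i) * epoch_min
        bfrac = (csum[j] - csum[i]) / (j - i)
        name = level if isinstance(level, str) else "+".join(sorted(level))
        out.append(
            BoutRecord(
                level=name,
                start_idx=i,
                end_idx=j,
                duration_min=dur,
                frac_at_level=bfrac,
                duration_bin=_bin_label(dur, bins),
            )
        )
        i = j
    return out


def detect_blocks(
    labels: np.ndarray,
    level,
    bins: Sequence[tuple[float, float | None]] | None = None,
    epoch_min: float = 1.0,
):
    """Maximal consecutive at-level runs, binned by duration.

    Returns ``(blocks, counts)`` where ``blocks`` is a list of
    ``(start, end, duration_min, bin)`` tuples and ``counts`` maps bin
    label to block count.
    """
    if bins is not None and len(bins) == 0:
        raise ValueError("bins spec must be non-empty")
    if bins is None:
        bins = INACTIVE_BINS if level == "inactive" else MVPA_BINS
    at = _at_level(labels, level)
    padded = np.concatenate([[False], at, [False]])
    d = np.diff(padded.astype(int))
    starts, ends = np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]
    blocks = []
    counts: dict[str, int] = {}
    for s, e in zip(starts, ends):
        dur = (e - s) * epoch_min
        lab = _bin_label(dur, bins)
        blocks.append((int(s), int(e), dur, lab))
        counts[lab] = counts.get(lab, 0) + 1
    return blocks, counts


def unbouted_duration(
    labels: np.ndarray, level, bouts: list[BoutRecord], epoch_min: float = 1.0
) -> float:
    """Minutes at ``level`` falling outside every detected bout of it."""
    at = _at_level(labels, level)
    covered = np.zeros(len(at), dtype=bool)
    for b in bouts:
        covered[b.start_idx : b.end_idx] = True
    return float(np.sum(at & ~covered) * epoch_min)


def rolling_window_traits(
    series: EpochSeries,
    day: DayWindow,
    min_valid_hours: float = 20.0,
) -> CircadianWindowTraits | None:
    """M10/M5 most-active and L10/L5 least-active window traits for a day.

    Searches every contiguous window (1-epoch step, fully inside the day)
    of width 10 h and 5 h for the maximum (M) and minimum (L) mean
    activity; ties break to the earliest onset. Light statistics are taken
    over the activity-defined M windows. Returns ``None`` when the day has
    less than ``min_valid_hours`` of wear.
    """
    data = series.data
    m = (data["timestamp"] >= day.start) & (data["timestamp"] < day.end)
    data = data.loc[m]
    epm = series.epoch_len / 60.0
    if data["wear"].sum() * epm / 60.0 < min_valid_hours:
        return None
    act = data["activity"].to_numpy(dtype=float)
    light = data["light"].to_numpy(dtype=float)
    ts = data["timestamp"].reset_index(drop=True)

    def window_stats(width_h: float):
        w = int(round(width_h * 60 / epm))
        if w > len(act):
            return None
        csum = np.concatenate([[0.0], np.cumsum(act)])
        means = (csum[w:] - csum[:-w]) / w
        i_max = int(np.argmax(means))  # argmax/argmin return first = earliest
        i_min = int(np.argmin(means))
        return w, i_max, float(means[i_max]), i_min, float(means[i_min])

    r10 = window_stats(10.0)
    r5 = window_stats(5.0)
    if r10 is None or r5 is None:
        return None
    w10, i10, m10_mean, j10, l10_mean = r10
    w5, i5, m5_mean, j5, l5_mean = r5

    def clock(i: int) -> float:
        t = ts.iloc[i]
        return t.hour + t.minute / 60.0 + t.second / 3600.0

    return CircadianWindowTraits(
        m10_onset=clock(i10),
        m10_mean=m10_mean,
        m10_mean_light=float(light[i10 : i10 + w10].mean()),
        m10_max_light=float(light[i10 : i10 + w10].max()),
        m5_onset=clock(i5),
        m5_mean=m5_mean,
        m5_max_light=float(light[i5 : i5 + w5].max()),
        l10_onset=clock(j10),
        l10_mean=l10_mean,
        l5_onset=clock(j5),
        l5_mean=l5_mean,
    )


def day_activity_summary(
    labels: np.ndarray,
    series_day: pd.DataFrame,
    sleep_window: tuple[pd.Timestamp, pd.Timestamp] | None,
    cutoffs: IntensityCutoffs = IntensityCutoffs(),
    epoch_min: float = 1.0,
) -> DayActivitySummary:
    """Daily activity summary over one day's epochs.

    Sedentary time is inactive wear time outside the sleep period (the
    whole day, flagged, when no sleep window was found). "Mixed activity"
    and "sitting/standing" are surrogate label-grouping definitions:
    mixed = wake epochs whose centred 5-min window contains both light and
    moderate epochs and a light+moderate majority; sitting/standing =
    inactive wake epochs with nonzero activity below the light cutoff.
    """
    act = series_day["activity"].to_numpy(dtype=float)
    wear = series_day["wear"].to_numpy(dtype=bool)
    ts = series_day["timestamp"]

    in_sleep = np.zeros(len(act), dtype=bool)
    flagged = False
    if sleep_window is not None:
        onset, offset = sleep_window
        in_sleep = ((ts >= onset) & (ts < offset)).to_numpy()
    else:
        flagged = True

    inactive = _at_level(labels, "inactive")
    light_lv = _at_level(labels, "light")
    moderate = _at_level(labels, "moderate")
    vigorous = _at_level(labels, "vigorous")

    sed_h = float(np.sum(inactive & wear & ~in_sleep) * epoch_min / 60.0)

    # mixed activity: centred 5-min majority window with both levels present
    k = max(int(round(5.0 / epoch_min)), 1)
    lm = (light_lv | moderate).astype(float)
    kernel = np.ones(k)
    lm_count = np.convolve(lm, kernel, mode="same")
    l_count = np.convolve(light_lv.astype(float), kernel, mode="same")
    m_count = np.convolve(moderate.astype(float), kernel, mode="same")
    mixed = (lm_count > k / 2.0) & (l_count > 0) & (m_count > 0) & wear & ~in_sleep
    mixed_h = float(np.sum(mixed) * epoch_min / 60.0)

    sit_stand = inactive & (act > 0) & wear & ~in_sleep
    sit_stand_h = float(np.sum(sit_stand) * epoch_min / 60.0)

    wake_labels = labels.copy()
    wake_labels[in_sleep] = None
    inactive_bouts = detect_bouts(wake_labels, "inactive", 30.0, epoch_min=epoch_min)
    light_bouts = detect_bouts(wake_labels, "light", 10.0, epoch_min=epoch_min)
    moderate_bouts = detect_bouts(wake_labels, "moderate", 10.0, epoch_min=epoch_min)
    mvpa_bouts = detect_bouts(
        wake_labels, {"moderate", "vigorous"}, 5.0, epoch_min=epoch_min, bins=MVPA_BINS
    )

    n_blocks: dict[str, dict[str, int]] = {}
    for lv in LEVELS:
        _, counts = detect_blocks(wake_labels, lv, epoch_min=epoch_min)
        n_blocks[lv] = counts

    def ctx_mean(mask: np.ndarray) -> float:
        return float(act[mask].mean()) if mask.any() else float("nan")

    in_long_inactive = np.zeros(len(act), dtype=bool)
    for b in inactive_bouts:
        if b.duration_min >= 30:
            in_long_inactive[b.start_idx : b.end_idx] = True
    unbouted_light_mask = light_lv.copy()
    for b in light_bouts:
        unbouted_light_mask[b.start_idx : b.end_idx] = False

    return DayActivitySummary(
        time_sedentary=sed_h,
        time_mixed_activity=mixed_h,
        time_sit_stand=sit_stand_h,
        unbouted_light_dur=unbouted_duration(wake_labels, "light", light_bouts, epoch_min),
        unbouted_moderate_dur=unbouted_duration(wake_labels, "moderate", moderate_bouts, epoch_min),
        n_blocks_by_level_and_bin=n_blocks,
        n_bouts_mvpa_5_10=sum(1 for b in mvpa_bouts if b.duration_bin == "5-10"),
        mean_accel_by_context={
            "inactivity_bouts_30min": ctx_mean(in_long_inactive),
            "unbouted_light": ctx_mean(unbouted_light_mask & wear),
            "vigorous": ctx_mean(vigorous & wear),
            "sleep_period": ctx_mean(in_sleep & wear),
        },
        weartime=float(np.sum(wear) * epoch_min / 60.0),
        sedentary_flagged_no_sleep=flagged,
    )
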