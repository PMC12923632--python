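"""Two-harmonic rhythm fitting, sleep-window detection and scoring, SRI.

The circadian profile of each recording is summarized by a two-harmonic
cosinor model

    a(t) = M + A1 cos(2*pi*(t - phi1)/24) + A2 cos(4*pi*(t - phi2)/24)

fitted by ordinary least squares over wear-valid epochs (t in clock hours).
The fitted curve drives sleep-window detection: the longest below-mesor
span of a day is the candidate rest period, and sustained low-activity
runs inside it define sleep onset and offset. Nightly sleep traits (WASO,
awakenings, efficiency, total sleep time, scotoperiod overlap) are scored
within the detected window, and the Sleep Regularity Index (SRI) measures
the probability of being in the same sleep/wake state at the same clock
time on consecutive days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import DayWindow
from .simulate import EpochSeries

__all__ = [
    "CosinorFit",
    "SleepTraits",
    "SRIResult",
    "fit_two_harmonic",
    "detect_sleep_period",
    "score_sleep_day",
    "compute_sri",
]

#: default sleep-activity threshold, as a fraction of the recording mesor
THETA_SLEEP_FRAC = 0.10
#: minimum sustained low-activity run defining sleep onset/offset, minutes
MIN_SLEEP_RUN_MIN = 10.0
#: light level below which an epoch belongs to the scotoperiod, lux
THETA_DARK = 10.0


@dataclass
class CosinorFit:
    mesor: float
    amp1: float
    amp2: float
    phase1: float  # peak clock hour of the 24 h harmonic (NaN if undefined)
    phase2: float  # peak clock hour of the 12 h harmonic (NaN if undefined)
    fitted_min: float
    fitted_max: float
    r2: float

    @property
    def range_osc(self) -> float:
        return self.fitted_max - self.fitted_min

    def predict(self, clock_hours: np.ndarray) -> np.ndarray:
        t = np.asarray(clock_hours, dtype=float)
        out = np.full_like(t, self.mesor)
        if np.isfinite(self.phase1):
            out = out + self.amp1 * np.cos(2 * np.pi * (t - self.phase1) / 24.0)
        if np.isfinite(self.phase2):
            out = out + self.amp2 * np.cos(4 * np.pi * (t - self.phase2) / 24.0)
        return out

    @property
    def alpha_hours(self) -> float:
        """Hours per day the fitted curve lies above its mesor (midpoint grid)."""
        grid = (np.arange(1440) + 0.5) * (24.0 / 1440.0)
        return float(np.mean(self.predict(grid) > self.mesor) * 24.0)

    @property
    def rho_hours(self) -> float:
        return 24.0 - self.alpha_hours

    @property
    def alpha_rho_ratio(self) -> float:
        rho = self.rho_hours
        return float("inf") if rho == 0 else self.alpha_hours / rho


@dataclass
class SleepTraits:
    onset_time: float  # clock hours
    wake_time: float
    sleep_period_dur: float  # hours, onset to offset
    sleep_dur_in_period: float  # hours asleep within the period
    waso_min: float
    n_awakenings: int
    n_awakenings_5min: int
    efficiency: float  # percent
    total_sleep_time: float  # hours
    frac_night_invalid: float
    pct_sleep_24h: float
    sleep_in_scotoperiod: float
    day_duration: float = float("nan")  # hours, onset-to-next-onset


@dataclass
class SRIResult:
    sri: float  # -100..100 scale (not clipped; negative = below random)
    n_epoch_pairs: int
    agreement_frac: float


def _clock_hours(ts: pd.Series) -> np.ndarray:
    t = pd.DatetimeIndex(ts)
    return t.hour + t.minute / 60.0 + t.second / 3600.0


def fit_two_harmonic(
    series: EpochSeries,
    window: DayWindow | None = None,
    min_hours: float | None = None,
) -> CosinorFit:
    """Least-squares two-harmonic cosinor fit over wear-valid epochs.

    ``window=None`` fits the whole recording (requires >= 24 h of valid
    data); passing a :class:`DayWindow` fits that day only (>= 12 h).
    The fit is exact (zero residual) on noiseless two-harmonic input.
    All-constant input yields ``amp1 = amp2 = 0`` with phases NaN.
    """
    data = series.data
    if window is not None:
        m = (data["timestamp"] >= window.start) & (data["timestamp"] < window.end)
        data = data.loc[m]
    data = data.loc[data["wear"]]
    need = (12.0 if window is not None else 24.0) if min_hours is None else min_hours
    hours_have = len(data) * series.epoch_len / 3600.0
    if hours_have < need:
        raise ValueError(f"insufficient wear-valid data: {hours_have:.1f} h < {need} h")

    t = _clock_hours(data["timestamp"])
    y = data["activity"].to_numpy(dtype=float)
    w = 2 * np.pi / 24.0
    X = np.column_stack(
        [np.ones_like(t), np.cos(w * t), np.sin(w * t), np.cos(2 * w * t), np.sin(2 * w * t)]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, b1, c1, b2, c2 = beta
    amp1 = float(np.hypot(b1, c1))
    amp2 = float(np.hypot(b2, c2))
    tol = 1e-10 * max(1.0, abs(m))
    phase1 = float(np.arctan2(c1, b1) / w % 24.0) if amp1 > tol else float("nan")
    phase2 = float(np.arctan2(c2, b2) / (2 * w) % 12.0) if amp2 > tol else float("nan")
    if amp1 <= tol:
        amp1 = 0.0
    if amp2 <= tol:
        amp2 = 0.0

    yhat = X @ beta
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    grid = (np.arange(86400) + 0.5) * (24.0 / 86400.0)  # 1-s resolution extrema
    fit = CosinorFit(
        mesor=float(m), amp1=amp1, amp2=amp2, phase1=phase1, phase2=phase2,
        fitted_min=0.0, fitted_max=0.0, r2=r2,
    )
    curve = fit.predict(grid)
    fit.fitted_min = float(curve.min())
    fit.fitted_max = float(curve.max())
    return fit


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index intervals of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    return list(zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]))


def detect_sleep_period(
    day: DayWindow,
    series: EpochSeries,
    fit: CosinorFit,
    theta_sleep: float | None = None,
    min_run_min: float = MIN_SLEEP_RUN_MIN,
) -> tuple[pd.Timestamp, pd.Timestamp] | None:
    """Locate the night's sleep window within one day.

    The candidate rest span is the longest contiguous stretch of the day
    where the fitted two-harmonic curve lies below its mesor. Sleep onset
    is the start of the first run of at least ``min_run_min`` consecutive
    minutes with activity below ``theta_sleep`` inside the candidate;
    offset is the end of the last such run. Returns ``None`` when no
    qualifying run exists (a valid outcome, e.g. a skipped night).

    ``theta_sleep`` defaults to 10% of the fit's mesor.
    """
    if theta_sleep is None:
        theta_sleep = THETA_SLEEP_FRAC * fit.mesor
    data = series.data
    m = (data["timestamp"] >= day.start) & (data["timestamp"] < day.end)
    data = data.loc[m]
    if len(data) == 0:
        return None
    clock = _clock_hours(data["timestamp"])
    below = fit.predict(clock) < fit.mesor
    cand_runs = _runs(below)
    if not cand_runs:
        return None
    s, e = max(cand_runs, key=lambda r: r[1] - r[0])

    act = data["activity"].to_numpy(dtype=float)
    wear = data["wear"].to_numpy(dtype=bool)
    low = (act < theta_sleep) & wear
    epm = series.epoch_len / 60.0
    min_ep = max(int(round(min_run_min / epm)), 1)
    # qualifying runs are anchored by the candidate span but may extend
    # past its edges (the fitted curve can cross its mesor before waking)
    qruns = [
        (a, b) for a, b in _runs(low)
        if b - a >= min_ep and a < e and b > s
    ]
    if not qruns:
        return None
    ts = data["timestamp"].reset_index(drop=True)
    onset = ts.iloc[qruns[0][0]]
    off_idx = qruns[-1][1]
    offset = ts.iloc[off_idx] if off_idx < len(ts) else ts.iloc[-1] + pd.Timedelta(seconds=series.epoch_len)
    return onset, offset


def score_sleep_day(
    day: DayWindow,
    series: EpochSeries,
    window: tuple[pd.Timestamp, pd.Timestamp],
    theta_sleep: float,
    theta_dark: float = THETA_DARK,
) -> SleepTraits:
    """Score nightly sleep traits within a detected sleep window.

    Within ``[onset, offset)`` a wear-valid epoch is asleep when activity
    falls below ``theta_sleep``. An awakening is a maximal run of awake
    epochs of at least 1 min; WASO is their total duration. Total sleep
    time counts sleep within the window only (nap detection is off).
    """
    onset, offset = window
    if onset < day.start or offset > day.end:
        raise ValueError("sleep window outside day bounds")
    data = series.data
    m = (data["timestamp"] >= onset) & (data["timestamp"] < offset)
    night = data.loc[m]
    epm = series.epoch_len / 60.0

    wear = night["wear"].to_numpy(dtype=bool)
    act = night["activity"].to_numpy(dtype=float)
    light = night["light"].to_numpy(dtype=float)
    asleep = (act < theta_sleep) & wear
    awake = (~asleep) & wear

    period_h = (offset - onset).total_seconds() / 3600.0
    sleep_h = asleep.sum() * epm / 60.0
    waso_runs = _runs(awake)
    min_ep_1 = max(int(round(1.0 / epm)), 1)
    min_ep_5 = max(int(round(5.0 / epm)), 1)
    awakenings = [(a, b) for a, b in waso_runs if b - a >= min_ep_1]
    waso_min = float(sum(b - a for a, b in waso_runs) * epm)
    n_awake = len(awakenings)
    n_awake5 = sum(1 for a, b in awakenings if b - a >= min_ep_5)

    eff = 100.0 * sleep_h / period_h if period_h > 0 else float("nan")
    scoto = float(np.mean(light[asleep] < theta_dark)) if asleep.any() else float("nan")
    onset_clock = onset.hour + onset.minute / 60.0 + onset.second / 3600.0
    wake_clock = offset.hour + offset.minute / 60.0 + offset.second / 3600.0
    return SleepTraits(
        onset_time=onset_clock,
        wake_time=wake_clock,
        sleep_period_dur=period_h,
        sleep_dur_in_period=sleep_h,
        waso_min=waso_min,
        n_awakenings=n_awake,
        n_awakenings_5min=n_awake5,
        efficiency=eff,
        total_sleep_time=sleep_h,
        frac_night_invalid=float(np.mean(~wear)) if len(wear) else float("nan"),
        pct_sleep_24h=100.0 * sleep_h / 24.0,
        sleep_in_scotoperiod=scoto,
    )


def compute_sri(states: np.ndarray) -> SRIResult:
    """Sleep Regularity Index from a days-by-epochs sleep/wake matrix.

    ``states`` holds 1/0 (or True/False) with NaN for missing epochs.
    Agreement is counted over pairs of epochs 24 h apart on consecutive
    day rows where both are observed:

        SRI = 200 * P(same state at same clock time on consecutive days) - 100

    100 means a perfectly repeating pattern, 0 random, and negative values
    (possible on this unclipped scale) mean below-random regularity.
    """
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 days")
    a, b = states[:-1], states[1:]
    both = np.isfinite(a) & np.isfinite(b)
    n_pairs = int(both.sum())
    if n_pairs == 0:
        raise ValueError("no observed epoch pairs on consecutive days")
    agree = float(np.mean(a[both] == b[both]))
    return SRIResult(sri=200.0 * agree - 100.0, n_epoch_pairs=n_pairs, agreement_frac=agree)
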