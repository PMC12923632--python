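"""Synthetic actigraphy cohorts with known ground truth.

Two tiers of simulation are provided:

* :func:`simulate_epoch_cohort` — epoch-level (default 1-min) activity/light
  series per participant, exercising the whole feature-extraction pipeline:
  two-harmonic circadian structure, nightly sleep windows with WASO events,
  daytime intensity pulses, exact-zero non-wear stretches, and a
  group-specific coupling of daytime sedentary hours to nightly sleep.
* :func:`simulate_feature_cohort` — day-level rows (sedentary hours, total
  sleep minutes) drawn directly from the variance-components model that the
  association stage fits, so mixed-model recovery tests are not confounded
  by feature-extraction error.

All randomness flows from one seeded :class:`numpy.random.Generator`; each
participant gets a spawned child stream, so cohorts are reproducible and
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "EpochSeries",
    "GroundTruth",
    "simulate_epoch_cohort",
    "simulate_feature_cohort",
    "simulate_diary",
]


@dataclass
class EpochSeries:
    """Time-ordered epoch data for one participant.

    ``data`` columns: ``timestamp`` (tz-naive), ``activity`` (mg-like,
    >= 0), ``light`` (lux-like, >= 0), ``wear`` (bool), and optionally
    ``sleep_state`` (bool ground truth, absent on real data).
    """

    participant_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        ts = self.data["timestamp"]
        if len(ts) > 1:
            deltas = ts.diff().dropna().unique()
            if len(deltas) != 1:
                raise ValueError("timestamps must be strictly increasing with constant spacing")
        if (self.data["activity"] < 0).any():
            raise ValueError("activity must be non-negative")

    @property
    def epoch_len(self) -> int:
        """Epoch length in seconds."""
        return int((self.data["timestamp"].iloc[1] - self.data["timestamp"].iloc[0]).total_seconds())

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GroundTruth:
    """Latent state of a simulated cohort.

    participants : per-participant metadata and latent traits
    days : per participant-day true sleep window, WASO and sedentary hours
    nonwear : true non-wear intervals (start/end timestamps)
    effects : injected feature effects (feature name, standardized size)
    slopes : group-specific sleep~sedentary coupling (min per hour)
    """

    participants: pd.DataFrame
    days: pd.DataFrame
    nonwear: pd.DataFrame = field(default_factory=pd.DataFrame)
    effects: list = field(default_factory=list)
    slopes: dict = field(default_factory=dict)


def _assign_families(n: int, dist, rng: np.random.Generator) -> np.ndarray:
    sizes, probs = zip(*dist)
    fam = np.empty(n, dtype=object)
    i = fid = 0
    while i < n:
        size = int(rng.choice(sizes, p=probs))
        size = min(size, n - i)
        fam[i : i + size] = f"F{fid:04d}"
        fid += 1
        i += size
    return fam


def _participant_frame(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_participants
    n_cases = int(round(n * cfg.prop_cases))
    group = np.array(["case"] * n_cases + ["control"] * (n - n_cases))
    rng.shuffle(group)
    fam = _assign_families(n, cfg.family_size_dist, rng)
    start0 = pd.Timestamp(cfg.start_date)
    starts = start0 + pd.to_timedelta(
        rng.integers(0, max(cfg.start_spread_days, 1), size=n), unit="D"
    )
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "family_id": fam,
            "group": group,
            "age": rng.uniform(18, 60, size=n),
            "sex": rng.choice(["F", "M"], size=n),
            "latent_score": rng.normal(size=n),
            "start_noon": starts + pd.Timedelta(hours=12),
        }
    )


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for a, b in iv[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def _simulate_participant(
    row: pd.Series, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[EpochSeries, pd.DataFrame, pd.DataFrame]:
    """Build one participant's epoch series plus day/non-wear truth tables."""
    epm = cfg.epoch_len / 60.0  # minutes per epoch
    ep_day = 86400 // cfg.epoch_len
    n_ep = cfg.n_days * ep_day
    is_case = row["group"] == "case"

    t0 = row["start_noon"]
    ts = t0 + pd.to_timedelta(np.arange(n_ep) * cfg.epoch_len, unit="s")
    clock = (12.0 + np.arange(n_ep) * cfg.epoch_len / 3600.0) % 24.0

    base = (
        cfg.mesor
        + cfg.amp1 * np.cos(2 * np.pi * (clock - cfg.phase1) / 24.0)
        + cfg.amp2 * np.cos(4 * np.pi * (clock - cfg.phase2) / 24.0)
    )
    if is_case:
        base = base * cfg.case_activity_scale

    # individual sleep phenotype
    onset_mu_i = rng.normal(cfg.sleep_onset_mu, 0.3)
    dur_mu_i = cfg.sleep_dur_mu
    onset_sd = cfg.sleep_onset_sd * (cfg.case_onset_sd_mult if is_case else 1.0)
    dur_sd = cfg.sleep_dur_sd * (cfg.case_dur_sd_mult if is_case else 1.0)
    slope = cfg.slope_case if is_case else cfg.slope_control
    sed_mu_g = cfg.sed_mu_case if is_case else cfg.sed_mu_control
    sed_mu_i = rng.normal(sed_mu_g, 0.75)
    u_sleep_i = rng.normal(0.0, cfg.sigma_individual)  # minutes

    activity = base.copy()

    # daytime intensity pulses (moderate/vigorous activity); placed in the
    # noon-20:00 span, before sedentary imposition so designated sedentary
    # minutes stay sedentary (their ground truth must be exact)
    if cfg.pulse_rate > 0:
        for d in range(cfg.n_days):
            for _ in range(rng.poisson(cfg.pulse_rate)):
                p0 = d * ep_day + int(rng.integers(0, int(8 * 60 / epm)))
                p_len = max(int(round(rng.uniform(5, 25) / epm)), 1)
                amp = rng.uniform(120, 500)
                seg = slice(p0, min(p0 + p_len, n_ep))
                activity[seg] = activity[seg] + amp

    sleep_state = np.zeros(n_ep, dtype=bool)  # asleep (window minus WASO)
    waso_mask = np.zeros(n_ep, dtype=bool)
    day_rows = []

    for d in range(cfg.n_days):
        d0, d1 = d * ep_day, (d + 1) * ep_day  # noon-to-noon window

        sed_h = np.nan
        if cfg.sedentary_coupling:
            # impose sedentary minutes between noon and 20:30 (pre-sleep)
            sed_h = float(np.clip(rng.normal(sed_mu_i, cfg.sed_sd), 0.5, 8.0))
            wake_span = int(8.5 * 60 / epm)
            n_sed = min(int(round(sed_h * 60 / epm)), wake_span)
            idx = rng.choice(wake_span, size=n_sed, replace=False) + d0
            activity[idx] = rng.uniform(1.0, 30.0, size=n_sed)

        if cfg.sleep_dur_mu > 0:
            onset_clock = rng.normal(onset_mu_i, onset_sd)
            dur_h = dur_mu_i + rng.normal(0.0, dur_sd)
            if cfg.sedentary_coupling and np.isfinite(sed_h):
                dur_h += (slope * (sed_h - sed_mu_g) + u_sleep_i + rng.normal(0, cfg.sigma_resid)) / 60.0
            dur_h = float(np.clip(dur_h, 1.0, 14.0))
            # keep the whole window inside this noon-to-noon span
            onset_clock = float(np.clip(onset_clock, 20.6, 26.0))
            onset_ep = d0 + int(round((onset_clock - 12.0) * 3600 / cfg.epoch_len))
            offset_ep = min(onset_ep + int(round(dur_h * 3600 / cfg.epoch_len)), d1 - 1)

            waso_iv: list[tuple[int, int]] = []
            n_waso = rng.poisson(cfg.waso_rate)
            # awakenings are interior to the night (>= 20 min from either
            # edge): wake abutting the window boundary is onset latency or
            # terminal wake, not WASO, and would make the truth ambiguous
            margin = max(int(round(20 / epm)), 1)
            for _ in range(n_waso):
                w_len = int(round(np.clip(rng.exponential(cfg.waso_len_mu), 1, 30) / epm))
                w_len = max(w_len, 1)
                span = offset_ep - onset_ep - w_len - 2 * margin
                if span <= 2:
                    continue
                w0 = onset_ep + margin + int(rng.integers(0, span))
                waso_iv.append((w0, w0 + w_len))
            waso_iv = _merge_intervals(waso_iv)

            sl = np.zeros(n_ep, dtype=bool)
            sl[onset_ep:offset_ep] = True
            for a, b in waso_iv:
                sl[a:b] = False
                waso_mask[a:b] = True
            sleep_state |= sl
            waso_min = sum(b - a for a, b in waso_iv) * epm
            day_rows.append(
                {
                    "participant_id": row["participant_id"],
                    "day_index": d + 1,
                    "onset": ts[onset_ep],
                    "offset": ts[offset_ep] if offset_ep < n_ep else ts[-1],
                    "onset_clock": onset_clock % 24.0,
                    "sleep_dur_h": (offset_ep - onset_ep) * epm / 60.0,
                    "waso_min": waso_min,
                    "sedentary_hours": sed_h,
                }
            )
        else:
            day_rows.append(
                {
                    "participant_id": row["participant_id"],
                    "day_index": d + 1,
                    "onset": pd.NaT,
                    "offset": pd.NaT,
                    "onset_clock": np.nan,
                    "sleep_dur_h": 0.0,
                    "waso_min": 0.0,
                    "sedentary_hours": sed_h,
                }
            )

    # awakenings carry movement; boost so they stand clear of sleep stillness
    activity[waso_mask] = activity[waso_mask] + 30.0

    if cfg.sigma_epoch > 0:
        activity = activity + rng.normal(0.0, cfg.sigma_epoch, size=n_ep)
    activity = np.maximum(activity, 0.0)
    # suppress (not zero) movement while asleep so sleep never aliases with
    # exact-zero non-wear
    activity[sleep_state] = activity[sleep_state] * cfg.sleep_suppression

    # light channel: bright day, dim evening, dark during sleep
    light = cfg.light_day_peak * np.maximum(0.0, np.cos(2 * np.pi * (clock - 13.0) / 24.0)) ** 2
    light = np.maximum(light, 30.0)  # indoor evening light while awake
    if cfg.sigma_epoch > 0:
        light = light * np.exp(rng.normal(0.0, 0.2, size=n_ep))
    light[sleep_state | waso_mask] = 0.5

    # non-wear: exact zero runs outside sleep
    nonwear_rows = []
    for _ in range(rng.poisson(cfg.nonwear_rate)):
        nw_len = max(int(round(cfg.nonwear_len / epm)), 1)
        for _attempt in range(20):
            s = int(rng.integers(0, max(n_ep - nw_len, 1)))
            if not (sleep_state[s : s + nw_len].any() or waso_mask[s : s + nw_len].any()):
                activity[s : s + nw_len] = 0.0
                nonwear_rows.append(
                    {
                        "participant_id": row["participant_id"],
                        "start": ts[s],
                        "end": ts[s] + pd.Timedelta(seconds=nw_len * cfg.epoch_len),
                        "len_min": nw_len * epm,
                    }
                )
                break

    data = pd.DataFrame(
        {
            "timestamp": ts,
            "activity": np.round(activity, 3),
            "light": np.round(light, 2),
            "wear": True,
            "sleep_state": sleep_state,
        }
    )
    series = EpochSeries(participant_id=row["participant_id"], data=data)
    return series, pd.DataFrame(day_rows), pd.DataFrame(nonwear_rows)


def simulate_epoch_cohort(cfg: SimulationConfig) -> tuple[list[EpochSeries], GroundTruth]:
    """Simulate an epoch-level actigraphy cohort.

    Returns the list of per-participant :class:`EpochSeries` plus the
    :class:`GroundTruth` (sleep windows, WASO, sedentary hours, non-wear
    intervals, injected group effects).
    """
    rng = np.random.default_rng(cfg.seed)
    participants = _participant_frame(cfg, rng)
    streams = rng.spawn(cfg.n_participants)

    series_list, day_frames, nw_frames = [], [], []
    for (_, prow), child in zip(participants.iterrows(), streams):
        s, days, nw = _simulate_participant(prow, cfg, child)
        series_list.append(s)
        day_frames.append(days)
        if len(nw):
            nw_frames.append(nw)

    effects = []
    if 0.0 < cfg.prop_cases < 1.0:
        effects = [
            ("time_sedentary_mean", +0.5),
            ("unbouted_light_dur_mean", -0.4),
            ("sleep_dur_in_period_sd", +0.5),
            ("sri", -0.5),
        ]
    truth = GroundTruth(
        participants=participants,
        days=pd.concat(day_frames, ignore_index=True),
        nonwear=pd.concat(nw_frames, ignore_index=True) if nw_frames else pd.DataFrame(),
        effects=effects,
        slopes={"case": cfg.slope_case, "control": cfg.slope_control},
    )
    return series_list, truth


def simulate_feature_cohort(cfg: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the day-level cohort used by the mixed-effects stage.

    Each row is one participant-day with total sleep minutes generated as::

        TST = intercept + slope_group * sedentary_hours
              + u_individual + u_family + eps

    where ``intercept = sleep_dur_mu * 60`` min, the random intercepts are
    centered Gaussians with SDs ``sigma_individual`` / ``sigma_family`` and
    the residual SD is ``sigma_resid`` (all in minutes).
    """
    if cfg.sigma_resid < 0:
        raise ValueError("sigma_resid must be non-negative")
    rng = np.random.default_rng(cfg.seed)
    participants = _participant_frame(cfg, rng)

    fam_ids = participants["family_id"].unique()
    u_fam = dict(zip(fam_ids, rng.normal(0.0, cfg.sigma_family, size=len(fam_ids))))
    u_ind = rng.normal(0.0, cfg.sigma_individual, size=cfg.n_participants)
    intercept = cfg.sleep_dur_mu * 60.0

    rows = []
    for i, (_, p) in enumerate(participants.iterrows()):
        is_case = p["group"] == "case"
        slope = cfg.slope_case if is_case else cfg.slope_control
        sed_mu = cfg.sed_mu_case if is_case else cfg.sed_mu_control
        sed = np.clip(rng.normal(sed_mu, cfg.sed_sd, size=cfg.n_days), 0.0, None)
        eps = rng.normal(0.0, cfg.sigma_resid, size=cfg.n_days) if cfg.sigma_resid > 0 else 0.0
        tst = intercept + slope * sed + u_ind[i] + u_fam[p["family_id"]] + eps
        for d in range(cfg.n_days):
            rows.append(
                {
                    "participant_id": p["participant_id"],
                    "family_id": p["family_id"],
                    "day_index": d + 1,
                    "group": p["group"],
                    "age": p["age"],
                    "sex": p["sex"],
                    "sedentary_hours": sed[d],
                    "total_sleep_min": tst if np.isscalar(tst) else tst[d],
                }
            )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        participants=participants,
        days=table,
        slopes={
            "case": cfg.slope_case,
            "control": cfg.slope_control,
            "intercept": intercept,
        },
    )
    return table, truth


def simulate_diary(truth: GroundTruth, cfg: SimulationConfig) -> pd.DataFrame:
    """Generate nightly sleep-diary reports from the true sleep windows.

    Reported onset/offset/total sleep/efficiency equal the true values plus
    the configured additive bias and Gaussian reporting noise. The default
    efficiency bias is +12 percentage points (diaries overestimate
    efficiency relative to actigraphy-derived estimates).
    """
    days = truth.days
    if "onset" not in days.columns or days["onset"].isna().all():
        raise ValueError("diary requires nights with a true sleep window")
    days = days.dropna(subset=["onset"])
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    n = len(days)
    bias, noise = cfg.diary_bias, cfg.diary_noise

    def jitter(key):
        sd = noise.get(key, 0.0)
        return rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)

    true_tst_min = days["sleep_dur_h"].to_numpy() * 60.0 - days["waso_min"].to_numpy()
    true_period_min = days["sleep_dur_h"].to_numpy() * 60.0
    with np.errstate(invalid="ignore", divide="ignore"):
        true_eff = 100.0 * true_tst_min / true_period_min

    out = pd.DataFrame(
        {
            "participant_id": days["participant_id"].to_numpy(),
            "day_index": days["day_index"].to_numpy(),
            "onset": days["onset"]
            + pd.to_timedelta(bias.get("onset_min", 0.0) + jitter("onset_min"), unit="m"),
            "offset": days["offset"]
            + pd.to_timedelta(bias.get("offset_min", 0.0) + jitter("offset_min"), unit="m"),
            "total_sleep_min": true_tst_min + bias.get("tst_min", 0.0) + jitter("tst_min"),
            # efficiency left unclipped above 100 so the configured reporting
            # bias stays additive (diaries near-perfect nights would otherwise
            # censor the bias)
            "efficiency": np.maximum(
                true_eff + bias.get("efficiency_pct", 0.0) + jitter("efficiency_pct"), 0.0
            ),
        }
    )
    return out
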