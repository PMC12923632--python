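"""Per-participant feature extraction: epochs in, day-level traits out.

For one participant's epoch series this stage (1) flags non-wear (zero
runs > 100 min, exempting spans inside the cosinor-predicted rest period,
where long stillness is expected), (2) segments noon-to-noon days,
(3) fits the whole-recording and daily two-harmonic rhythms, (4) detects
and scores the nightly sleep window, (5) computes the daily activity
traits, and (6) assembles the participant's sleep-regularity index and QC
report. The output day table carries every base trait later aggregated
to per-person mean/median/SD features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import activity as act_mod
from . import preprocess as pp
from . import sleep as sl
from .activity import IntensityCutoffs
from .simulate import EpochSeries

__all__ = ["ParticipantFeatures", "extract_participant", "extract_cohort", "sleep_state_matrix"]


@dataclass
class ParticipantFeatures:
    participant_id: str
    day_table: pd.DataFrame
    qc: pp.QCReport
    sri: sl.SRIResult | None
    cosinor_whole: sl.CosinorFit | None
    warnings: list = field(default_factory=list)


def _candidate_rest_windows(
    series: EpochSeries, fit: sl.CosinorFit, days: list[pp.DayWindow]
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Below-mesor spans of the fitted curve, one per day (the rest period)."""
    out = []
    for day in days:
        data = series.data
        m = (data["timestamp"] >= day.start) & (data["timestamp"] < day.end)
        sub = data.loc[m]
        if len(sub) == 0:
            continue
        clock = pd.DatetimeIndex(sub["timestamp"])
        t = clock.hour + clock.minute / 60.0 + clock.second / 3600.0
        below = fit.predict(np.asarray(t)) < fit.mesor
        runs = sl._runs(below)
        if runs:
            s, e = max(runs, key=lambda r: r[1] - r[0])
            ts = sub["timestamp"].reset_index(drop=True)
            out.append((ts.iloc[s], ts.iloc[min(e, len(ts) - 1)]))
    return out


def sleep_state_matrix(
    series: EpochSeries,
    days: list[pp.DayWindow],
    windows: dict[int, tuple[pd.Timestamp, pd.Timestamp] | None],
    theta_sleep: float,
) -> np.ndarray:
    """Days-by-epoch sleep/wake matrix for the SRI (NaN = non-wear)."""
    ep_day = 86400 // series.epoch_len
    mat = np.full((len(days), ep_day), np.nan)
    data = series.data
    for i, day in enumerate(days):
        m = (data["timestamp"] >= day.start) & (data["timestamp"] < day.end)
        sub = data.loc[m]
        if len(sub) == 0:
            continue
        pos = ((sub["timestamp"] - day.start).dt.total_seconds() // series.epoch_len).astype(int)
        state = np.zeros(len(sub))
        w = windows.get(day.day_index)
        if w is not None:
            onset, offset = w
            in_win = (sub["timestamp"] >= onset) & (sub["timestamp"] < offset)
            asleep = in_win.to_numpy() & (sub["activity"].to_numpy() < theta_sleep)
            state[asleep] = 1.0
        state[~sub["wear"].to_numpy()] = np.nan
        mat[i, pos.to_numpy()] = state
    return mat


def extract_participant(
    series: EpochSeries,
    cutoffs: IntensityCutoffs = IntensityCutoffs(),
    theta_sleep_frac: float = sl.THETA_SLEEP_FRAC,
    theta_dark: float = sl.THETA_DARK,
) -> ParticipantFeatures:
    """Run the whole per-participant extraction chain."""
    warns: list[str] = []
    epm = series.epoch_len / 60.0

    flagged = pp.detect_nonwear(series)
    try:
        fit_whole = sl.fit_two_harmonic(flagged)
    except ValueError as e:
        return ParticipantFeatures(
            participant_id=series.participant_id,
            day_table=pd.DataFrame(),
            qc=pp.QCReport(series.participant_id, 0, 0.0, 0.0, ["no_valid_data"]),
            sri=None,
            cosinor_whole=None,
            warnings=[str(e)],
        )
    days0 = pp.segment_days(flagged)
    rest = _candidate_rest_windows(flagged, fit_whole, days0)
    flagged = pp.detect_nonwear(series, exempt_windows=rest)
    days = pp.segment_days(flagged)

    theta = theta_sleep_frac * fit_whole.mesor
    rows = []
    windows: dict[int, tuple | None] = {}
    for day in days:
        row: dict = {
            "participant_id": series.participant_id,
            "day_index": day.day_index,
            "date": day.start.normalize(),
            "is_weekend": day.is_weekend,
            "hours_valid": day.hours_valid,
        }
        m = (flagged.data["timestamp"] >= day.start) & (flagged.data["timestamp"] < day.end)
        day_data = flagged.data.loc[m].reset_index(drop=True)
        day_series = EpochSeries(series.participant_id, day_data) if len(day_data) > 1 else None

        try:
            fit_day = sl.fit_two_harmonic(series=flagged, window=day)
        except ValueError:
            fit_day = fit_whole
        row.update(
            mesor_daily=fit_day.mesor,
            amp1_daily=fit_day.amp1,
            amp2_daily=fit_day.amp2,
            fitted_min=fit_day.fitted_min,
            range_osc=fit_day.range_osc,
            alpha_hours=fit_day.alpha_hours,
            alpha_rho_ratio=(
                fit_day.alpha_rho_ratio if np.isfinite(fit_day.alpha_rho_ratio) else np.nan
            ),
            cosinor_r2=fit_day.r2,
        )

        win = sl.detect_sleep_period(day, flagged, fit_day, theta_sleep=theta)
        windows[day.day_index] = win
        traits = None
        if win is not None:
            traits = sl.score_sleep_day(day, flagged, win, theta_sleep=theta, theta_dark=theta_dark)
            for k, v in vars(traits).items():
                row[k] = v

        if day_series is not None:
            labels = act_mod.classify_intensity(day_series, cutoffs)
            summ = act_mod.day_activity_summary(labels, day_data, win, cutoffs, epoch_min=epm)
            row.update(
                time_sedentary=summ.time_sedentary,
                time_mixed_activity=summ.time_mixed_activity,
                time_sit_stand=summ.time_sit_stand,
                unbouted_light_dur=summ.unbouted_light_dur,
                unbouted_moderate_dur=summ.unbouted_moderate_dur,
                n_bouts_mvpa_5_10=summ.n_bouts_mvpa_5_10,
                n_blocks_inactive_30=summ.n_blocks_by_level_and_bin["inactive"].get(">=30", 0),
                n_blocks_light_10=summ.n_blocks_by_level_and_bin["light"].get(">=10", 0),
                mean_accel_inactive_bouts=summ.mean_accel_by_context["inactivity_bouts_30min"],
                mean_accel_unbouted_light=summ.mean_accel_by_context["unbouted_light"],
                mean_accel_vigorous=summ.mean_accel_by_context["vigorous"],
                mean_accel_sleep_period=summ.mean_accel_by_context["sleep_period"],
                weartime=summ.weartime,
            )
            wt = act_mod.rolling_window_traits(flagged, day)
            if wt is not None:
                row.update(
                    m10_onset=wt.m10_onset,
                    m10_mean=wt.m10_mean,
                    m10_mean_light=wt.m10_mean_light,
                    m10_max_light=wt.m10_max_light,
                    m5_onset=wt.m5_onset,
                    m5_mean=wt.m5_mean,
                    m5_max_light=wt.m5_max_light,
                    l10_onset=wt.l10_onset,
                    l10_mean=wt.l10_mean,
                    l5_onset=wt.l5_onset,
                    l5_mean=wt.l5_mean,
                )
        rows.append(row)

    day_table = pd.DataFrame(rows)

    # day duration: onset-to-onset on consecutive scored days
    if "onset_time" in day_table.columns:
        onsets = {}
        for day in days:
            w = windows.get(day.day_index)
            if w is not None:
                onsets[day.day_index] = w[0]
        durs = []
        for _, r in day_table.iterrows():
            d = int(r["day_index"])
            if d in onsets and (d + 1) in onsets:
                durs.append((onsets[d + 1] - onsets[d]).total_seconds() / 3600.0)
            else:
                durs.append(np.nan)
        day_table["day_duration"] = durs

    sleep_by_day = {
        int(r["day_index"]): float(r["sleep_dur_in_period"])
        for _, r in day_table.iterrows()
        if "sleep_dur_in_period" in r and np.isfinite(r.get("sleep_dur_in_period", np.nan))
    }
    qc = pp.apply_qc(days, sleep_by_day, participant_id=series.participant_id)

    sri = None
    if len(days) >= 2:
        try:
            mat = sleep_state_matrix(flagged, days, windows, theta)
            sri = sl.compute_sri(mat)
        except ValueError as e:
            warns.append(f"SRI undefined: {e}")
    day_table["sri"] = sri.sri if sri is not None else np.nan

    return ParticipantFeatures(
        participant_id=series.participant_id,
        day_table=day_table,
        qc=qc,
        sri=sri,
        cosinor_whole=fit_whole,
        warnings=warns,
    )


def extract_cohort(
    series_list: list[EpochSeries],
    meta: pd.DataFrame | None = None,
    cutoffs: IntensityCutoffs = IntensityCutoffs(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract day-level traits for a whole cohort.

    Returns ``(day_table, qc_table)``; the day table keeps only included
    participants and merges metadata (group, family, age, sex) when given.
    """
    feats = [extract_participant(s, cutoffs=cutoffs) for s in series_list]
    qc_rows = [
        {
            "participant_id": f.participant_id,
            "n_valid_days": f.qc.n_valid_days,
            "mean_hours_per_day": f.qc.mean_hours_per_day,
            "mean_sleep_hours": f.qc.mean_sleep_hours,
            "included": f.qc.included,
            "exclusion_reasons": ";".join(f.qc.exclusion_reasons),
        }
        for f in feats
    ]
    qc_table = pd.DataFrame(qc_rows)
    kept = [f.day_table for f in feats if f.qc.included and len(f.day_table)]
    day_table = pd.concat(kept, ignore_index=True) if kept else pd.DataFrame()
    if meta is not None and len(day_table):
        cols = [c for c in ("participant_id", "family_id", "group", "age", "sex") if c in meta.columns]
        day_table = day_table.merge(meta[cols], on="participant_id", how="left")
    return day_table, qc_table
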