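"""Configuration objects for cohort simulation and analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence


@dataclass
class SimulationConfig:
    """Parameters of the synthetic actigraphy cohort generator.

    The generator emulates a three-week wrist-actigraphy protocol: per-minute
    activity (mg-like units) with a two-harmonic circadian profile, nightly
    sleep windows with brief awakenings (WASO), occasional non-wear stretches
    of exact zeros, a light channel, and a group-specific linear coupling of
    daytime sedentary hours to the following night's total sleep time.

    Activity-distribution defaults are artifact choices: the protocol this
    emulates does not publish a parametric description of its cohort's
    activity, so values here were picked once to look like healthy adult
    wrist data under conventional mg cutoffs (inactive < 40 mg).

    Parameters
    ----------
    n_participants : int
        Cohort size.
    prop_cases : float
        Fraction of participants labelled as cases (autistic group).
    n_days : int
        Recording length in days (default 21, the study protocol).
    epoch_len : int
        Epoch length in seconds; must divide 86400 (default 60).
    mesor, amp1, amp2 : float
        Two-harmonic activity profile: midline and first/second harmonic
        amplitudes, in activity units (mg-like).
    phase1, phase2 : float
        Peak clock hours of the 24 h and 12 h harmonics.
    sleep_onset_mu, sleep_onset_sd : float
        Population mean / night-to-night SD of sleep onset clock hour.
    sleep_dur_mu, sleep_dur_sd : float
        Population mean / night-to-night SD of nightly sleep duration (h).
        ``sleep_dur_mu = 0`` disables sleep windows entirely.
    waso_rate : float
        Expected awakenings per night (Poisson).
    waso_len_mu : float
        Mean awakening length, minutes (exponential, clipped to [1, 30]).
    nonwear_rate : float
        Expected non-wear events per whole recording (Poisson).
    nonwear_len : float
        Non-wear event length in minutes.
    slope_case, slope_control : float
        Linear coupling of nightly total sleep time to that day's sedentary
        hours, in minutes of sleep per hour sedentary (signed; negative
        means more sedentary time -> less sleep).
    family_size_dist : sequence of (size, prob)
        Distribution of family sizes used to assign family IDs.
    sigma_individual, sigma_family, sigma_resid : float
        SDs (minutes) of the individual random intercept, family random
        intercept and residual night-level noise on total sleep time.
    diary_bias : mapping
        Additive diary reporting bias per trait: ``onset_min``/``offset_min``
        /``tst_min`` in minutes, ``efficiency_pct`` in percentage points.
    diary_noise : mapping
        SD of diary reporting noise per trait, same keys/units.
    sigma_epoch : float
        SD of per-epoch Gaussian activity noise (activity units).
    pulse_rate : float
        Expected daytime moderate/vigorous activity pulses per day.
    case_activity_scale : float
        Multiplier on the waking activity profile for cases (< 1 raises
        sedentary time and lowers light activity in the case group).
    case_onset_sd_mult, case_dur_sd_mult : float
        Multipliers on onset SD / duration SD for cases (raise sleep-timing
        irregularity, lowering the case group's sleep regularity index).
    sed_mu_control, sed_mu_case, sed_sd : float
        Target daytime sedentary hours (mean per group, day-to-day SD) for
        the day-level generator and for the epoch-level coupling.
    sleep_suppression : float
        Multiplier applied to activity inside the sleep window (kept > 0 so
        that sleep does not alias with exact-zero non-wear).
    light_day_peak : float
        Peak midday light (lux-like).
    theta_dark : float
        Light threshold defining the scotoperiod (lux).
    sedentary_coupling : bool
        If False, neither sedentary minutes nor the sleep-sedentary slope
        are imposed on the epoch-level series.
    start_date : str
        Civil date (ISO) on which the earliest recording can start; each
        participant starts at noon of a day drawn within
        ``start_spread_days`` of it, so recordings spread across seasons.
    seed : int
        Root seed; all randomness derives from it.
    """

    n_participants: int = 60
    prop_cases: float = 0.5
    n_days: int = 21
    epoch_len: int = 60
    mesor: float = 85.0
    amp1: float = 50.0
    amp2: float = 12.0
    phase1: float = 15.0
    phase2: float = 13.0
    sleep_onset_mu: float = 23.5
    sleep_onset_sd: float = 0.5
    sleep_dur_mu: float = 8.0
    sleep_dur_sd: float = 0.5
    waso_rate: float = 2.0
    waso_len_mu: float = 8.0
    nonwear_rate: float = 0.5
    nonwear_len: float = 150.0
    slope_case: float = -23.5
    slope_control: float = -17.1
    family_size_dist: Sequence[tuple[int, float]] = ((1, 0.3), (2, 0.5), (3, 0.2))
    sigma_individual: float = 20.0
    sigma_family: float = 10.0
    sigma_resid: float = 40.0
    diary_bias: Mapping[str, float] = field(
        default_factory=lambda: {
            "onset_min": -15.0,
            "offset_min": 0.0,
            "tst_min": 0.0,
            "efficiency_pct": 12.0,
        }
    )
    diary_noise: Mapping[str, float] = field(
        default_factory=lambda: {
            "onset_min": 20.0,
            "offset_min": 20.0,
            "tst_min": 30.0,
            "efficiency_pct": 5.0,
        }
    )
    sigma_epoch: float = 8.0
    pulse_rate: float = 3.0
    case_activity_scale: float = 0.9
    case_onset_sd_mult: float = 2.0
    case_dur_sd_mult: float = 1.6
    sed_mu_control: float = 6.0
    sed_mu_case: float = 7.0
    sed_sd: float = 1.5
    sleep_suppression: float = 0.02
    light_day_peak: float = 400.0
    theta_dark: float = 10.0
    sedentary_coupling: bool = True
    start_date: str = "2023-01-02"
    start_spread_days: int = 330
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_cases <= 1.0:
            raise ValueError("prop_cases must lie in [0, 1]")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.epoch_len <= 0 or 86400 % self.epoch_len != 0:
            raise ValueError("epoch_len must be a positive divisor of 86400")
        if self.epoch_len > 3600:
            raise ValueError("epoch_len > 3600 s makes day windows degenerate")
        if self.sleep_dur_mu >= 24:
            raise ValueError("sleep_dur_mu must be < 24 h")
        if min(self.mesor, self.amp1, self.amp2) < 0:
            raise ValueError("mesor, amp1, amp2 must be non-negative")
        for name in ("sigma_individual", "sigma_family", "sigma_resid", "sigma_epoch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        probs = [p for _, p in self.family_size_dist]
        if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
            raise ValueError("family_size_dist probabilities must be a distribution")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["family_size_dist"] = [list(x) for x in self.family_size_dist]
        d["diary_bias"] = dict(self.diary_bias)
        d["diary_noise"] = dict(self.diary_noise)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "family_size_dist" in d:
            d["family_size_dist"] = tuple(tuple(x) for x in d["family_size_dist"])
        return cls(**d)
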