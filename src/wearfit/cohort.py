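"""Synthetic free-living cohort generator.

Emulates a population-cohort wearable study: a participant table
(anthropometrics, resting heart rate, submaximal-test VO2max), one
minute-resolution sensor week per participant (raw acceleration,
movement intensity, heart rate, heart-rate variability), and a
longitudinal follow-up visit roughly seven years later.  The generator
imposes a *known* link between cardiorespiratory fitness and the heart
rate response to physical activity, so downstream models can be scored
against an analytic parameter-recovery oracle.

Heart-rate response model
-------------------------
For a participant with latent fitness ``v`` (VO2max, mL O2/min/kg),
resting heart rate ``rhr`` and age-predicted maximal heart rate
``hrmax = 208 - 0.7 * age``, each minute's heart rate is

.. math::

    hr_t = rhr + (hrmax - rhr) \\cdot \\min(1, s \\cdot L_t) + \\eta_t,
    \\qquad s = \\frac{\\beta}{v (1 + b)}

where ``L_t = max(0, METs_t - 1)`` is the metabolic load above rest,
``beta`` is a population response constant (``CohortConfig.hr_beta``),
``b`` is a persistent per-participant response bias with standard
deviation ``hr_response_sd`` and ``eta_t`` is minute-level Gaussian
noise (``hr_noise_sd``).  Fitter participants therefore mount a
*smaller* heart-rate response to the same activity.  Inverting the
noiseless form on any unsaturated active minute,

.. math::

    v = \\beta L_t \\frac{hrmax - rhr}{hr_t - rhr},

recovers fitness exactly; :func:`recover_vo2max` applies this inverse
(median over active minutes) and is the oracle that bounds what any
statistical model can achieve on these data.

Latent fitness itself follows a linear anthropometric model,

``v = intercept(sex) - a (age - 48) - b (BMI - 26) + c (activity - 1) + e``,

with preset coefficients calibrated so the ``fenland_like`` preset has
an overall observed VO2max of about 39.5 +/- 5 (women about 37.4) and
the ``bbvs_like`` preset about 32.9 +/- 7.  The observed value adds
submaximal-test measurement error (``measurement_sd``).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

MINUTES_PER_DAY = 1440
#: 1 MET expressed as activity energy expenditure.
JOULES_PER_MET = 71.0

PARTICIPANT_CSV_COLUMNS = [
    "participant_id",
    "sex",
    "age",
    "height",
    "weight",
    "bmi",
    "rhr",
    "vo2max",
    "phase",
    "start_month",
]
TRACE_CSV_COLUMNS = ["timestamp", "acc_raw", "intensity_jminkg", "hr_bpm", "hrv_ms"]


def _substream(seed: int, *tokens) -> np.random.Generator:
    """Deterministic, collision-resistant random substream.

    Every random decision in the generator draws from a stream keyed by
    the master seed plus a string path, so cohorts are extensible (adding
    participants never reshuffles existing ones) and any single artifact
    is regenerable in isolation.
    """
    key = "|".join([str(int(seed))] + [str(t) for t in tokens])
    digest = hashlib.blake2b(key.encode(), digest_size=16).digest()
    return np.random.default_rng(np.random.SeedSequence(int.from_bytes(digest, "little")))


@dataclass(frozen=True)
class ParticipantRecord:
    """One person at one study phase.

    ``vo2max_true``, ``activity_level`` and ``hr_response_bias`` are
    generator latents: they exist so tests can score estimators against
    ground truth and must never be fed to models.  ``vo2max_measured``
    is the noisy submaximal-test observation models are trained on.
    """

    participant_id: str
    sex: str  # "female" | "male"
    age: float  # years
    height: float  # metres
    weight: float  # kg
    bmi: float  # kg/m^2, always weight/height^2
    rhr: float  # beats/min
    vo2max_true: float  # mL O2/min/kg (latent)
    vo2max_measured: float  # mL O2/min/kg (observed)
    phase: str  # "baseline" | "followup"
    start_month: int  # 1..12, month the sensor week starts
    activity_level: float = 1.0  # latent habitual activity (mean 1)
    hr_response_bias: float = 0.0  # latent multiplicative HR-response bias

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female/male, got {self.sex!r}")
        if self.phase not in ("baseline", "followup"):
            raise ValueError(f"phase must be baseline/followup, got {self.phase!r}")
        if not 1 <= int(self.start_month) <= 12:
            raise ValueError("start_month must be in 1..12")
        if abs(self.bmi - self.weight / self.height**2) > 1e-9:
            raise ValueError("bmi must equal weight/height^2")
        if self.vo2max_measured <= 0:
            raise ValueError("vo2max_measured must be positive")
        if not 35.0 <= self.rhr <= 110.0:
            raise ValueError("rhr outside physiological range [35, 110]")

    @property
    def hrmax(self) -> float:
        """Age-predicted maximal heart rate, 208 - 0.7 * age."""
        return 208.0 - 0.7 * self.age


@dataclass(frozen=True)
class DeltaModel:
    """Distribution of the 7-year change in latent VO2max.

    The generated change is ``location + age_effect * (age - 48)
    - fitness_reversion * (v - cohort mean) + skew-normal noise`` and is
    clipped to ``clip_range``.  The skew-normal noise is centred so the
    deterministic part carries the mean.
    """

    location: float = -0.5  # mL O2/min/kg per follow-up interval
    scale: float = 2.8
    skewness: float = -2.0
    age_effect: float = -0.06  # per year of baseline age above 48
    fitness_reversion: float = 0.15  # pull toward the cohort mean
    clip_range: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("DeltaModel scale must be non-negative")
        if self.clip_range[0] >= self.clip_range[1]:
            raise ValueError("clip_range must be (low, high) with low < high")

    def sample(self, age: np.ndarray, vo2max_true: np.ndarray, cohort_mean: float,
               rng: np.random.Generator) -> np.ndarray:
        det = (
            self.location
            + self.age_effect * (np.asarray(age) - 48.0)
            - self.fitness_reversion * (np.asarray(vo2max_true) - cohort_mean)
        )
        if self.scale == 0:
            noise = np.zeros_like(det)
        else:
            raw = stats.skewnorm.rvs(self.skewness, scale=self.scale,
                                     size=det.shape, random_state=rng)
            d = self.skewness / np.hypot(1.0, self.skewness)
            noise = raw - self.scale * d * np.sqrt(2.0 / np.pi)  # centre at 0
        return np.clip(det + noise, *self.clip_range)


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic study, fully determined by ``seed``.

    Defaults describe the ``fenland_like`` preset: ~6-day wear at one
    sample per minute, VO2max 39.5 +/- 5 overall and 37.4 for women,
    with occasional non-wear gaps whose durations straddle the 90-min
    detection threshold.
    """

    n_participants: int = 100
    days: int = 6
    follow_up_years: float = 7.0
    seed: int = 0
    preset: str = "fenland_like"

    # participant table
    female_fraction: float = 0.5
    age_mean: float = 48.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (30.0, 64.0)
    height_female: tuple[float, float] = (1.63, 0.065)
    height_male: tuple[float, float] = (1.77, 0.07)
    bmi_mean: float = 26.0
    bmi_sd: float = 4.0
    bmi_range: tuple[float, float] = (17.0, 45.0)

    # latent fitness model
    vo2max_female_mean: float = 37.4
    vo2max_male_mean: float = 41.6
    vo2max_age_coef: float = 0.12  # decline per year above 48
    vo2max_bmi_coef: float = 0.35  # decline per BMI unit above 26
    vo2max_activity_coef: float = 4.0  # gain per unit habitual activity
    vo2max_resid_sd: float = 3.3
    vo2max_floor: float = 18.0
    measurement_sd: float = 1.5  # submaximal-test error on observed VO2max

    # resting heart rate: rhr = intercept - slope * vo2max_true + noise
    rhr_intercept: float = 88.0
    rhr_slope: float = 0.55
    rhr_sd: float = 5.0

    # heart-rate response (see module docstring)
    hr_beta: float = 5.0
    hr_noise_sd: float = 3.0
    hr_response_sd: float = 0.033

    # activity schedule
    activity_shape: float = 4.0  # Gamma(shape, scale) habitual activity, mean 1
    bout_rate_per_day: float = 3.0
    bout_mets_range: tuple[float, float] = (2.5, 7.5)
    bout_mets_sd: float = 0.3
    bout_min_minutes: float = 10.0
    bout_mean_extra_minutes: float = 15.0
    sleep_intensity: tuple[float, float] = (40.0, 8.0)  # J/min/kg mean, sd
    awake_intensity: tuple[float, float] = (75.0, 25.0)
    season_amplitude: float = 0.15

    # other channels
    hrv_intercept: float = 140.0
    hrv_slope: float = 0.9
    hrv_sd: float = 5.0
    acc_scale: float = 0.5  # acc_raw ~ acc_scale * intensity + noise
    acc_sd: float = 3.0

    # non-wear gaps
    gap_rate_per_day: float = 0.25
    gap_duration_log_mean: float = float(np.log(100.0))
    gap_duration_log_sd: float = 0.5
    gap_min_minutes: int = 10

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.days < 1:
            raise ValueError("days must be at least 1")
        for name in ("age_sd", "bmi_sd", "rhr_sd", "hr_beta", "activity_shape",
                     "measurement_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("hr_noise_sd", "hr_response_sd", "vo2max_resid_sd",
                     "gap_rate_per_day", "season_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.preset not in ("fenland_like", "bbvs_like", "custom"):
            raise ValueError(f"unknown preset {self.preset!r}")

    # -- presets ---------------------------------------------------------
    @classmethod
    def fenland_like(cls, n_participants: int, seed: int = 0, **overrides) -> "CohortConfig":
        return cls(n_participants=n_participants, seed=seed,
                   preset="fenland_like", **overrides)

    @classmethod
    def bbvs_like(cls, n_participants: int, seed: int = 0, **overrides) -> "CohortConfig":
        """A less-fit validation-study-like population (~32.9 +/- 7)."""
        defaults = dict(
            vo2max_female_mean=30.8,
            vo2max_male_mean=35.0,
            vo2max_resid_sd=5.9,
        )
        defaults.update(overrides)
        return cls(n_participants=n_participants, seed=seed,
                   preset="bbvs_like", **defaults)

    def noiseless(self) -> "CohortConfig":
        """Copy with all observation noise off; the oracle inverse is exact."""
        return dataclasses.replace(
            self, hr_noise_sd=0.0, hr_response_sd=0.0, gap_rate_per_day=0.0
        )

    def replace(self, **changes) -> "CohortConfig":
        return dataclasses.replace(self, **changes)

    @property
    def vo2max_overall_mean(self) -> float:
        return (self.female_fraction * self.vo2max_female_mean
                + (1.0 - self.female_fraction) * self.vo2max_male_mean)


@dataclass
class SensorTrace:
    """Minute-indexed multichannel sensor week for one participant.

    ``data`` is indexed by 0-based minute index and always carries the
    raw channels ``acc_raw`` (device units), ``intensity`` (J/min/kg),
    ``hr`` (beats/min, NaN when missing) and ``hrv`` (ms).  Processing
    adds the derived ``enmo``, ``mets`` and boolean ``wear`` columns.
    ``nonwear_true`` is the generator's hidden per-minute truth mask,
    present only on synthetic traces and used exclusively for scoring.
    """

    participant_id: str
    start: pd.Timestamp
    data: pd.DataFrame
    nonwear_true: Optional[np.ndarray] = None

    @property
    def n_minutes(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(self.data.index.to_numpy(), unit="min")

    @property
    def minute_of_day(self) -> np.ndarray:
        offset = self.start.hour * 60 + self.start.minute
        return (self.data.index.to_numpy() + offset) % MINUTES_PER_DAY

    def copy(self) -> "SensorTrace":
        return SensorTrace(
            participant_id=self.participant_id,
            start=self.start,
            data=self.data.copy(),
            nonwear_true=None if self.nonwear_true is None else self.nonwear_true.copy(),
        )

    # -- CSV dialect -----------------------------------------------------
    def to_csv(self, path) -> None:
        out = pd.DataFrame(
            {
                "timestamp": self.timestamps.strftime("%Y-%m-%dT%H:%M"),
                "acc_raw": self.data["acc_raw"].to_numpy(),
                "intensity_jminkg": self.data["intensity"].to_numpy(),
                "hr_bpm": self.data["hr"].to_numpy(),
                "hrv_ms": self.data["hrv"].to_numpy(),
            }
        )
        out.to_csv(path, index=False, float_format="%.4f")

    @classmethod
    def from_csv(cls, path, participant_id: str) -> "SensorTrace":
        raw = pd.read_csv(path, parse_dates=["timestamp"])
        missing = [c for c in TRACE_CSV_COLUMNS if c not in raw.columns]
        if missing:
            raise ValueError(f"trace file {path} missing columns {missing}")
        start = pd.Timestamp(raw["timestamp"].iloc[0])
        minutes = ((raw["timestamp"] - start).dt.total_seconds() / 60).round().astype(int)
        if not np.array_equal(minutes.to_numpy(), np.arange(len(raw))):
            raise ValueError(f"trace file {path} is not on a contiguous minute grid")
        data = pd.DataFrame(
            {
                "acc_raw": raw["acc_raw"].to_numpy(float),
                "intensity": raw["intensity_jminkg"].to_numpy(float),
                "hr": raw["hr_bpm"].to_numpy(float),
                "hrv": raw["hrv_ms"].to_numpy(float),
            },
            index=pd.RangeIndex(len(raw), name="minute_index"),
        )
        return cls(participant_id=participant_id, start=start, data=data)


# ---------------------------------------------------------------------------
# participant table
# ---------------------------------------------------------------------------

def generate_participants(config: CohortConfig) -> list[ParticipantRecord]:
    """Draw the baseline participant table for ``config``.

    Latent fitness follows the anthropometric model documented in the
    module docstring; resting heart rate is generated as
    ``rhr_intercept - rhr_slope * vo2max_true + noise`` so it correlates
    negatively with fitness, as observed physiologically.
    """
    records = []
    for i in range(config.n_participants):
        rng = _substream(config.seed, "participant", i)
        pid = f"P{i:05d}"
        sex = "female" if rng.random() < config.female_fraction else "male"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), *config.age_range))
        h_mean, h_sd = config.height_female if sex == "female" else config.height_male
        height = float(np.clip(rng.normal(h_mean, h_sd), 1.40, 2.10))
        bmi = float(np.clip(rng.normal(config.bmi_mean, config.bmi_sd), *config.bmi_range))
        weight = bmi * height**2
        activity = float(rng.gamma(config.activity_shape, 1.0 / config.activity_shape))
        intercept = (config.vo2max_female_mean if sex == "female"
                     else config.vo2max_male_mean)
        vo2_true = (
            intercept
            - config.vo2max_age_coef * (age - 48.0)
            - config.vo2max_bmi_coef * (bmi - 26.0)
            + config.vo2max_activity_coef * (activity - 1.0)
            + rng.normal(0.0, config.vo2max_resid_sd)
        )
        vo2_true = float(max(vo2_true, config.vo2max_floor))
        vo2_meas = float(max(vo2_true + rng.normal(0.0, config.measurement_sd), 10.0))
        rhr = float(np.clip(
            config.rhr_intercept - config.rhr_slope * vo2_true
            + rng.normal(0.0, config.rhr_sd),
            35.0, 110.0,
        ))
        bias = float(rng.normal(0.0, config.hr_response_sd)) if config.hr_response_sd else 0.0
        bias = max(bias, -0.8)  # keep the response slope positive
        records.append(
            ParticipantRecord(
                participant_id=pid,
                sex=sex,
                age=age,
                height=height,
                weight=weight,
                bmi=weight / height**2,
                rhr=rhr,
                vo2max_true=vo2_true,
                vo2max_measured=vo2_meas,
                phase="baseline",
                start_month=int(rng.integers(1, 13)),
                activity_level=activity,
                hr_response_bias=bias,
            )
        )
    return records


# ---------------------------------------------------------------------------
# sensor traces
# ---------------------------------------------------------------------------

def generate_trace(participant: ParticipantRecord, config: CohortConfig) -> SensorTrace:
    """Simulate one free-living sensor week at one sample per minute.

    Structure: a fixed 23:30-06:30 nocturnal low-activity block,
    Poisson-scheduled daytime activity bouts whose frequency scales with
    the participant's habitual activity level and a mild seasonal
    multiplier, heart rate from the documented fitness-dependent
    response model, and non-wear gaps inserted as runs of zero movement
    with absent heart rate.  The hidden truth mask of inserted gaps is
    attached as ``nonwear_true``.
    """
    if config.days < 1:
        raise ValueError("days must be at least 1")
    rng = _substream(config.seed, "trace", participant.participant_id, participant.phase)
    n = config.days * MINUTES_PER_DAY
    minute_of_day = np.arange(n) % MINUTES_PER_DAY
    sleep = (minute_of_day >= 1410) | (minute_of_day < 390)

    intensity = np.empty(n)
    intensity[sleep] = rng.normal(*config.sleep_intensity, size=int(sleep.sum()))
    intensity[~sleep] = rng.normal(*config.awake_intensity, size=int((~sleep).sum()))
    intensity = np.clip(intensity, 2.0, None)

    season = 1.0 + config.season_amplitude * np.cos(
        2.0 * np.pi * (participant.start_month - 7) / 12.0
    )
    lam = config.bout_rate_per_day * participant.activity_level * season
    lo_met, hi_met = config.bout_mets_range
    for day in range(config.days):
        for _ in range(rng.poisson(lam)):
            dur = int(config.bout_min_minutes
                      + rng.exponential(config.bout_mean_extra_minutes))
            start_mod = int(rng.integers(395, 1409 - min(dur, 900)))
            a = day * MINUTES_PER_DAY + start_mod
            b = min(a + dur, n)
            level = rng.uniform(lo_met, hi_met)
            mets_bout = np.clip(level + rng.normal(0.0, config.bout_mets_sd, b - a), 1.2, None)
            intensity[a:b] = JOULES_PER_MET * mets_bout

    mets = intensity / JOULES_PER_MET
    load = np.clip(mets - 1.0, 0.0, None)
    slope = config.hr_beta / (participant.vo2max_true * (1.0 + participant.hr_response_bias))
    frac = np.clip(slope * load, 0.0, 1.0)
    hrmax = participant.hrmax
    hr = participant.rhr + (hrmax - participant.rhr) * frac
    if config.hr_noise_sd > 0:
        hr = hr + rng.normal(0.0, config.hr_noise_sd, n)
    hrv = np.clip(
        config.hrv_intercept - config.hrv_slope * hr + rng.normal(0.0, config.hrv_sd, n),
        3.0, None,
    )
    acc = np.clip(config.acc_scale * intensity + rng.normal(0.0, config.acc_sd, n), 0.0, None)

    nonwear = np.zeros(n, dtype=bool)
    if config.gap_rate_per_day > 0:
        for _ in range(rng.poisson(config.gap_rate_per_day * config.days)):
            dur = int(np.clip(
                rng.lognormal(config.gap_duration_log_mean, config.gap_duration_log_sd),
                config.gap_min_minutes, n - 1,
            ))
            a = int(rng.integers(0, n - dur))
            nonwear[a:a + dur] = True
    intensity = np.where(nonwear, 0.0, intensity)
    acc = np.where(nonwear, 0.0, acc)
    hr = np.where(nonwear, np.nan, hr)
    hrv = np.where(nonwear, np.nan, hrv)

    year = 2015 if participant.phase == "baseline" else 2022
    day0 = int(_substream(config.seed, "trace-start",
                          participant.participant_id, participant.phase).integers(1, 23))
    start = pd.Timestamp(year=year, month=participant.start_month, day=day0)
    data = pd.DataFrame(
        {"acc_raw": acc, "intensity": intensity, "hr": hr, "hrv": hrv},
        index=pd.RangeIndex(n, name="minute_index"),
    )
    return SensorTrace(participant.participant_id, start, data, nonwear_true=nonwear)


def recover_vo2max(trace: SensorTrace, participant: ParticipantRecord,
                   config: CohortConfig) -> float:
    """Analytic inverse of the generator's heart-rate response model.

    Evaluates ``beta * L_t * (hrmax - rhr) / (hr_t - rhr)`` on every
    unsaturated active minute and returns the median.  On noise-free
    traces this recovers ``vo2max_true`` to machine precision; on noisy
    traces it is the best-achievable benchmark estimate downstream
    models are compared against.
    """
    hr = trace.data["hr"].to_numpy(float)
    mets = trace.data["intensity"].to_numpy(float) / JOULES_PER_MET
    load = mets - 1.0
    span = participant.hrmax - participant.rhr
    with np.errstate(invalid="ignore"):
        frac = (hr - participant.rhr) / span
        valid = np.isfinite(hr) & (load > 0.5) & (frac > 0.05) & (frac < 0.95)
    if not valid.any():
        raise ValueError(f"no active minutes usable for recovery "
                         f"({participant.participant_id})")
    est = config.hr_beta * load[valid] * span / (hr[valid] - participant.rhr)
    return float(np.median(est))


# ---------------------------------------------------------------------------
# longitudinal follow-up
# ---------------------------------------------------------------------------

def _elapsed_years_params(median: float = 7.0, q25: float = 5.0,
                          q75: float = 8.0) -> tuple[float, float, float]:
    """Shape, scale and offset of the reflected-Gamma elapsed-time law.

    ``elapsed = L - Gamma(k, theta)`` matched so the continuous law has
    the requested median and interquartile range (left-skewed: most
    participants return near the upper end of the window).
    """
    lo_gap = median - q25  # between q75 of the gamma and its median
    hi_gap = q75 - median  # between the gamma's median and its q25

    def ratio(k: float) -> float:
        g = stats.gamma(k)
        return (g.ppf(0.75) - g.ppf(0.5)) / (g.ppf(0.5) - g.ppf(0.25)) - lo_gap / hi_gap

    k = optimize.brentq(ratio, 0.05, 80.0)
    g = stats.gamma(k)
    theta = lo_gap / (g.ppf(0.75) - g.ppf(0.5))
    L = median + theta * g.ppf(0.5)
    return k, theta, L


def generate_followup(baseline: Sequence[ParticipantRecord],
                      delta_model: DeltaModel,
                      config: CohortConfig) -> list[ParticipantRecord]:
    """Create the follow-up visit records for ``baseline`` participants.

    Elapsed time is a discretized reflected Gamma with median ~7 years
    and IQR ~[5, 8]; latent fitness moves by a clipped skew-normal delta
    from ``delta_model``; weight drifts; the persistent heart-rate
    response bias is carried over so repeat sensor weeks remain
    consistent with the participant's physiology.
    """
    if len(baseline) == 0:
        raise ValueError("baseline cohort is empty")
    if delta_model.scale < 0:
        raise ValueError("delta_model scale must be non-negative")
    k, theta, L = _elapsed_years_params(config.follow_up_years,
                                        config.follow_up_years - 2.0,
                                        config.follow_up_years + 1.0)
    cohort_mean = config.vo2max_overall_mean
    out = []
    for rec in baseline:
        rng = _substream(config.seed, "followup", rec.participant_id)
        elapsed = float(np.clip(np.round(L - theta * rng.gamma(k)), 4.0, np.floor(L)))
        delta = float(delta_model.sample(
            np.array([rec.age]), np.array([rec.vo2max_true]), cohort_mean, rng)[0])
        vo2_true = max(rec.vo2max_true + delta, 12.0)
        vo2_meas = float(max(vo2_true + rng.normal(0.0, config.measurement_sd), 8.0))
        weight = float(np.clip(rec.weight + rng.normal(1.5, 3.0), 40.0, 160.0))
        rhr = float(np.clip(
            config.rhr_intercept - config.rhr_slope * vo2_true
            + rng.normal(0.0, config.rhr_sd),
            35.0, 110.0,
        ))
        activity = float(max(rec.activity_level + rng.normal(0.0, 0.15), 0.05))
        out.append(
            ParticipantRecord(
                participant_id=rec.participant_id,
                sex=rec.sex,
                age=rec.age + elapsed,
                height=rec.height,
                weight=weight,
                bmi=weight / rec.height**2,
                rhr=rhr,
                vo2max_true=vo2_true,
                vo2max_measured=vo2_meas,
                phase="followup",
                start_month=int(rng.integers(1, 13)),
                activity_level=activity,
                hr_response_bias=rec.hr_response_bias,
            )
        )
    return out


# ---------------------------------------------------------------------------
# whole-study convenience
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Baseline records plus follow-up records for the longitudinal subset."""

    baseline: list[ParticipantRecord]
    followup: list[ParticipantRecord]

    @property
    def longitudinal_ids(self) -> list[str]:
        return [r.participant_id for r in self.followup]


def simulate_study(config: CohortConfig,
                   delta_model: Optional[DeltaModel] = None,
                   longitudinal_fraction: float = 0.25) -> StudyData:
    """Generate a baseline cohort and a longitudinal follow-up subset.

    A deterministic random subset of participants (fraction
    ``longitudinal_fraction``) returns for the follow-up visit,
    mirroring the study design in which a minority of the baseline
    cohort is re-assessed years later.
    """
    if not 0.0 < longitudinal_fraction <= 1.0:
        raise ValueError("longitudinal_fraction must be in (0, 1]")
    baseline = generate_participants(config)
    rng = _substream(config.seed, "longitudinal-subset")
    n_long = int(round(longitudinal_fraction * len(baseline)))
    idx = np.sort(rng.choice(len(baseline), size=n_long, replace=False))
    subset = [baseline[i] for i in idx]
    followup = generate_followup(subset, delta_model or DeltaModel(), config)
    return StudyData(baseline=baseline, followup=followup)


def participants_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Public participant table (CSV dialect); latents are *not* included."""
    rows = [
        {
            "participant_id": r.participant_id,
            "sex": r.sex,
            "age": r.age,
            "height": r.height,
            "weight": r.weight,
            "bmi": r.bmi,
            "rhr": r.rhr,
            "vo2max": r.vo2max_measured,
            "phase": r.phase,
            "start_month": r.start_month,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=PARTICIPANT_CSV_COLUMNS)


def participants_truth_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Hidden ground-truth side-car (tests and scoring only)."""
    columns = ["participant_id", "phase", "vo2max_true", "activity_level",
               "hr_response_bias"]
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "phase": r.phase,
                "vo2max_true": r.vo2max_true,
                "activity_level": r.activity_level,
                "hr_response_bias": r.hr_response_bias,
            }
            for r in records
        ],
        columns=columns,
    )
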