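"""Synthetic data generation for two-arm actigraphy/affect trials.

Everything the downstream pipeline consumes can be generated here: latent
mean/volatility/noise series from the hierarchical random-walk model,
epoch-level activity profiles for a single day, and complete two-arm trial
datasets with week-indexed treatment effects injected into the active arm.

The trial generator works at the participant-day level (daily M10/L5
amounts, onset times, and affect sums), which is the resolution at which
the statistical models operate; :func:`simulate_epoch_day` provides the
epoch-level path for validating the non-parametric window metrics, and
:func:`hourly_activity` reconstructs hourly series for the rhythmicity
statistics (IS/IV) that need sub-daily data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenerativeParams",
    "LatentTrajectory",
    "DayProfileSpec",
    "TrialDesign",
    "TrialDataset",
    "simulate_latent_series",
    "simulate_epoch_day",
    "simulate_trial",
    "inject_missing_days",
    "hourly_activity",
]

MEASURES = ("pa", "na", "m10", "l5", "m10_onset", "l5_onset")

#: bounds of each daily measure in its natural units
MEASURE_BOUNDS = {
    "pa": (5.0, 25.0),
    "na": (5.0, 25.0),
    "m10": (0.0, np.inf),
    "l5": (0.0, np.inf),
    "m10_onset": (0.0, 14.0),
    "l5_onset": (12.0, 31.0),
}


# ---------------------------------------------------------------------------
# latent-volatility generative model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the hierarchical random-walk observation model.

    The observation at time t is Gaussian with mean ``mu_t`` and standard
    deviation ``SD_t = exp(logSD_t)``.  The mean drifts as a random walk
    whose step size is the volatility ``exp(logvmu_t)``; the log-volatility
    and log-noise themselves drift as random walks with step sizes ``kmu``
    and ``vSD``.
    """

    mu0: float
    log_sd0: float
    log_vmu0: float
    kmu: float
    vsd: float

    def __post_init__(self) -> None:
        vals = (self.mu0, self.log_sd0, self.log_vmu0, self.kmu, self.vsd)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("generative parameters must be finite")
        if self.kmu <= 0 or self.vsd <= 0:
            raise ValueError("kmu and vSD must be positive")


@dataclass(frozen=True)
class LatentTrajectory:
    """True per-time-point latent states of one simulated series."""

    mu: np.ndarray
    log_vmu: np.ndarray
    log_sd: np.ndarray

    def __len__(self) -> int:
        return len(self.mu)


def simulate_latent_series(
    params: GenerativeParams, length: int, seed: int
) -> tuple[LatentTrajectory, np.ndarray]:
    """Simulate a latent trajectory and its noisy observations.

    Time point 0 carries the initial states (``mu0``, ``log_vmu0``,
    ``log_sd0``); each later point first diffuses the log-volatility and
    log-noise, then the mean, and finally emits an observation.

    Returns the trajectory and the observation sequence ``y``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    mu = np.empty(length)
    log_vmu = np.empty(length)
    log_sd = np.empty(length)
    mu[0], log_vmu[0], log_sd[0] = params.mu0, params.log_vmu0, params.log_sd0
    for t in range(1, length):
        log_vmu[t] = log_vmu[t - 1] + rng.normal(0.0, params.kmu)
        log_sd[t] = log_sd[t - 1] + rng.normal(0.0, params.vsd)
        mu[t] = mu[t - 1] + rng.normal(0.0, np.exp(log_vmu[t]))
    y = rng.normal(mu, np.exp(log_sd))
    return LatentTrajectory(mu=mu, log_vmu=log_vmu, log_sd=log_sd), y


# ---------------------------------------------------------------------------
# epoch-level single-day profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DayProfileSpec:
    """Square-wave daytime-active / night-quiescent 24-h activity profile.

    Hours are measured from the focal day's midnight; the simulated span is
    00:00-36:00 so the noon-to-noon L5 search window is fully covered (the
    profile repeats with period 24 h).  ``nonwear_intervals`` are
    ``(start_hour, end_hour)`` pairs within [0, 36].
    """

    active_onset: float = 8.0
    active_duration: float = 10.0
    active_level: float = 100.0
    rest_level: float = 1.0
    noise_sd: float = 0.0
    epoch_length: int = 60
    nonwear_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.active_onset < 24):
            raise ValueError("active_onset must be in [0, 24)")
        if not (self.active_level >= self.rest_level >= 0):
            raise ValueError("need active_level >= rest_level >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.epoch_length <= 0 or 86400 % self.epoch_length != 0:
            raise ValueError("epoch_length must divide 86400")
        ivs = sorted(self.nonwear_intervals)
        for (a, b) in ivs:
            if not (0 <= a < b <= 36):
                raise ValueError("non-wear interval outside [0, 36]")
        for (_, b), (a2, _) in zip(ivs, ivs[1:]):
            if a2 < b:
                raise ValueError("overlapping non-wear intervals")


def simulate_epoch_day(spec: DayProfileSpec, seed: int):
    """Generate one 36-h epoch series (midnight through next-day noon).

    Activity equals ``active_level`` inside the active window (applied on
    the 24-h clock) and ``rest_level`` outside it, plus Gaussian noise
    truncated at zero.  Non-wear intervals are emitted as flagged epochs.
    """
    from .metrics import EpochSeries  # local import: metrics owns the container

    rng = np.random.default_rng(seed)
    n = int(36 * 3600 // spec.epoch_length)
    hours = (np.arange(n) + 0.5) * spec.epoch_length / 3600.0
    clock = hours % 24.0
    end = spec.active_onset + spec.active_duration
    if end <= 24.0:
        active = (clock >= spec.active_onset) & (clock < end)
    else:  # active window wraps past midnight
        active = (clock >= spec.active_onset) | (clock < end - 24.0)
    base = np.where(active, spec.active_level, spec.rest_level)
    values = base + rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else base.astype(float)
    values = np.clip(values, 0.0, None)
    nonwear = np.zeros(n, dtype=bool)
    for (a, b) in spec.nonwear_intervals:
        nonwear |= (hours >= a) & (hours < b)
    return EpochSeries(
        start=pd.Timestamp("2000-01-01 00:00:00"),
        epoch_length=spec.epoch_length,
        values=values,
        nonwear=nonwear,
    )


# ---------------------------------------------------------------------------
# two-arm trial
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialDesign:
    """Design of a simulated two-arm (lithium vs placebo) actigraphy trial.

    Baseline means/SDs are calibrated to the field-typical values of a
    mood-instability cohort wearing wrist actigraphs (daytime activity
    M10 ~ 57 absolute units between-person SD ~ 19; nocturnal L5 ~ 3.9;
    daytime activity onset ~ 12.3 h; rest onset ~ 25.5 h after the focal
    midnight).  Effects are week-indexed maps applied to the active arm
    only; the defaults mirror the direction and approximate size of the
    treatment contrasts the pipeline is meant to detect (activity reduced
    ~19-31%, onset advanced ~1.5-1.7 h in weeks 3-4, log-volatility raised
    ~0.2-0.45) and are calibration aids, not ground truth.

    Within-person dynamics: each measure follows a slowly drifting latent
    mean (random-walk step = ``*_walk_sd``) plus day-to-day observation
    noise (``*_daily_sd``).  ``pa_m10_coupling`` is the target
    within-subject correlation between daily M10 and PA.
    """

    n_per_arm: int = 20
    day_range: tuple[int, int] = (-14, 28)
    baseline_m10_mean: float = 57.3
    baseline_m10_sd: float = 18.9
    baseline_l5_mean: float = 3.9
    baseline_l5_sd: float = 0.7
    baseline_m10_onset_mean: float = 12.3
    baseline_m10_onset_sd: float = 2.2
    baseline_l5_onset_mean: float = 25.5
    baseline_l5_onset_sd: float = 1.9
    baseline_pa_mean: float = 10.6
    baseline_pa_sd: float = 3.3
    baseline_na_mean: float = 9.7
    baseline_na_sd: float = 3.7
    m10_daily_sd: float = 8.0
    m10_walk_sd: float = 1.5
    l5_daily_sd: float = 0.6
    l5_walk_sd: float = 0.05
    m10_onset_daily_sd: float = 1.2
    m10_onset_walk_sd: float = 0.15
    l5_onset_daily_sd: float = 1.3
    l5_onset_walk_sd: float = 0.15
    pa_daily_sd: float = 1.4
    pa_walk_sd: float = 0.25
    na_daily_sd: float = 1.4
    na_walk_sd: float = 0.25
    hourly_noise_sd: float = 1.5
    m10_daily_family: str = "truncnorm"  # or "lognormal"
    pa_m10_coupling: float = 0.15
    effect_m10_by_week: dict = field(
        default_factory=lambda: {1: -0.188, 2: -0.181, 3: -0.272, 4: -0.309}
    )
    effect_onset_by_week: dict = field(
        default_factory=lambda: {3: -1.55, 4: -1.69}
    )
    effect_volatility_by_week: dict = field(
        default_factory=lambda: {1: 0.45, 2: 0.33, 3: 0.23, 4: 0.29}
    )
    effect_is_by_week: dict = field(default_factory=dict)
    missing_day_rate: float = 0.3
    affect_item_count: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        first, last = self.day_range
        if not (first <= 0 <= last):
            raise ValueError("day_range must contain day 0")
        if not (0 <= self.missing_day_rate < 1):
            raise ValueError("missing_day_rate must be in [0, 1)")
        if self.m10_daily_family not in ("truncnorm", "lognormal"):
            raise ValueError("m10_daily_family must be 'truncnorm' or 'lognormal'")
        max_week = max(0, (last + 6) // 7)
        for name, eff in (
            ("effect_m10_by_week", self.effect_m10_by_week),
            ("effect_onset_by_week", self.effect_onset_by_week),
            ("effect_volatility_by_week", self.effect_volatility_by_week),
            ("effect_is_by_week", self.effect_is_by_week),
        ):
            for w in eff:
                if not (1 <= int(w) <= max_week) or 7 * int(w) - 6 > last:
                    raise ValueError(
                        f"{name}: week {w} lies outside day_range {self.day_range}"
                    )


@dataclass
class TrialDataset:
    """A simulated trial: participant table, day table, and latent truth.

    ``days`` columns: id, arm, day, valid, m10, l5, m10_onset, l5_onset,
    pa, na.  ``latent`` columns: id, measure, day, true_mu, true_log_vmu,
    true_log_sd.  Values are present for every participant-day; ``valid``
    marks the days the wearer actually recorded (invalid days are treated
    as unobserved downstream, latent truths are untouched).
    """

    participants: pd.DataFrame
    days: pd.DataFrame
    latent: pd.DataFrame
    design: TrialDesign | None = None

    def to_csv(self, days_path, participants_path=None, latent_path=None) -> None:
        cols = ["id", "arm", "day", "valid", "m10", "l5", "m10_onset", "l5_onset", "pa", "na"]
        self.days[cols].to_csv(days_path, index=False)
        if participants_path is not None:
            self.participants.to_csv(participants_path, index=False)
        if latent_path is not None:
            self.latent.to_csv(latent_path, index=False)

    @staticmethod
    def from_csv(days_path, participants_path=None, latent_path=None) -> "TrialDataset":
        days = pd.read_csv(days_path)
        parts = (
            pd.read_csv(participants_path)
            if participants_path is not None
            else days[["id", "arm"]].drop_duplicates().reset_index(drop=True)
        )
        latent = pd.read_csv(latent_path) if latent_path is not None else pd.DataFrame()
        return TrialDataset(participants=parts, days=days, latent=latent)


def _week_of(day: int) -> int:
    """Post-randomization week index (1-based); 0 for run-in days."""
    return 0 if day <= 0 else (day - 1) // 7 + 1


def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    """Normal draw truncated to [lo, hi] (rejection-free via scipy ppf)."""
    from scipy.stats import truncnorm

    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi))) if size else float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.random(size)
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def simulate_trial(design: TrialDesign) -> TrialDataset:
    """Simulate a full two-arm trial at daily resolution.

    Each participant gets one latent random-walk series per measure; the
    active-arm treatment effects are then applied week-wise: the M10 level
    (and its latent mean) is multiplied by ``1 + effect_m10_by_week[w]``,
    the M10 onset is shifted by ``effect_onset_by_week[w]`` hours, and the
    latent log-volatility of every activity measure is shifted by
    ``effect_volatility_by_week[w]``.  Missing days are i.i.d. Bernoulli.
    """
    rng = np.random.default_rng(design.seed)
    first, last = design.day_range
    days_idx = np.arange(first, last + 1)
    n_days = len(days_idx)
    n = 2 * design.n_per_arm

    seasons = np.array(["Spring", "Summer", "Autumn", "Winter"])
    parts = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "arm": ["lithium"] * design.n_per_arm + ["placebo"] * design.n_per_arm,
            "age": np.round(_trunc_normal(rng, 31.0, 12.0, 18.0, 70.0, n), 1),
            "sex": rng.choice(["F", "M"], size=n),
            "season_of_intake": rng.choice(seasons, size=n),
        }
    )

    base_cfg = {
        "m10": (design.baseline_m10_mean, design.baseline_m10_sd, 5.0, np.inf,
                design.m10_walk_sd, design.m10_daily_sd),
        "l5": (design.baseline_l5_mean, design.baseline_l5_sd, 0.1, np.inf,
               design.l5_walk_sd, design.l5_daily_sd),
        "m10_onset": (design.baseline_m10_onset_mean, design.baseline_m10_onset_sd,
                      0.0, 14.0, design.m10_onset_walk_sd, design.m10_onset_daily_sd),
        "l5_onset": (design.baseline_l5_onset_mean, design.baseline_l5_onset_sd,
                     12.0, 31.0, design.l5_onset_walk_sd, design.l5_onset_daily_sd),
        "pa": (design.baseline_pa_mean, design.baseline_pa_sd, 5.0, 25.0,
               design.pa_walk_sd, design.pa_daily_sd),
        "na": (design.baseline_na_mean, design.baseline_na_sd, 5.0, 25.0,
               design.na_walk_sd, design.na_daily_sd),
    }

    # PA is coupled to (pre-treatment) M10 within person: each day's PA
    # deviation from the participant's own baseline is a rho-weighted mix
    # of the scaled M10 deviation and an independent deviation, so the
    # day-to-day M10-PA correlation equals the design's coupling parameter
    rho = design.pa_m10_coupling
    t_mean = (n_days + 1) / 2.0
    sig_m10 = math.sqrt(design.m10_daily_sd**2 + design.m10_walk_sd**2 * t_mean)
    sig_pa = math.sqrt(design.pa_daily_sd**2 + design.pa_walk_sd**2 * t_mean)

    weeks = np.array([_week_of(int(d)) for d in days_idx])
    day_rows, latent_rows = [], []
    for _, p in parts.iterrows():
        pid, arm = int(p["id"]), p["arm"]
        is_li = arm == "lithium"
        vol_shift = np.array(
            [design.effect_volatility_by_week.get(int(w), 0.0) if is_li else 0.0 for w in weeks]
        )
        m10_fac = np.array(
            [1.0 + (design.effect_m10_by_week.get(int(w), 0.0) if is_li else 0.0) for w in weeks]
        )
        onset_shift = np.array(
            [design.effect_onset_by_week.get(int(w), 0.0) if is_li else 0.0 for w in weeks]
        )

        values: dict[str, np.ndarray] = {}
        pre_m10: dict[str, np.ndarray] = {}
        for meas, (bm, bs, lo, hi, walk, daily) in base_cfg.items():
            b0 = _trunc_normal(rng, bm, bs, lo, hi)
            log_walk = math.log(walk) if walk > 0 else -np.inf
            shift = vol_shift if meas in ("m10", "l5", "m10_onset", "l5_onset") else 0.0
            log_vmu = np.full(n_days, log_walk) + shift
            steps = rng.normal(0.0, 1.0, n_days) * np.exp(log_vmu)
            steps[0] = 0.0
            mu = b0 + np.cumsum(steps)
            eps = rng.normal(0.0, 1.0, n_days)
            if meas == "m10" and design.m10_daily_family == "lognormal" and daily > 0:
                # multiplicative day-to-day variation with matched CV
                cv = daily / max(bm, 1e-9)
                sig = math.sqrt(math.log(1 + cv**2))
                obs = mu * np.exp(sig * eps - 0.5 * sig**2)
            else:
                obs = mu + daily * eps
            if meas == "m10":
                pre_m10 = {"mu": mu.copy(), "obs": obs.copy(), "b0": b0}
            if meas == "pa" and rho != 0.0:
                # couple affect to the pre-treatment within-person activity deviation
                scale = rho * sig_pa / sig_m10
                c = math.sqrt(1.0 - rho**2)
                obs = b0 + scale * (pre_m10["obs"] - pre_m10["b0"]) + c * (obs - b0)
                mu = b0 + scale * (pre_m10["mu"] - pre_m10["b0"]) + c * (mu - b0)
            # treatment effects (applied to truth and observation alike)
            if meas == "m10":
                mu, obs = mu * m10_fac, obs * m10_fac
            elif meas == "m10_onset":
                mu, obs = mu + onset_shift, obs + onset_shift
            obs = np.clip(obs, lo, hi)
            mu = np.clip(mu, lo, hi)
            if meas in ("pa", "na"):
                obs = np.clip(np.round(obs), 5, 25)
            values[meas] = obs
            latent_rows.append(
                pd.DataFrame(
                    {
                        "id": pid,
                        "measure": meas,
                        "day": days_idx,
                        "true_mu": mu,
                        "true_log_vmu": log_vmu,
                        "true_log_sd": math.log(daily) if daily > 0 else -np.inf,
                    }
                )
            )
        valid = rng.random(n_days) >= design.missing_day_rate
        day_rows.append(
            pd.DataFrame(
                {
                    "id": pid,
                    "arm": arm,
                    "day": days_idx,
                    "valid": valid,
                    "m10": values["m10"],
                    "l5": values["l5"],
                    "m10_onset": values["m10_onset"],
                    "l5_onset": values["l5_onset"],
                    "pa": values["pa"],
                    "na": values["na"],
                }
            )
        )

    return TrialDataset(
        participants=parts,
        days=pd.concat(day_rows, ignore_index=True),
        latent=pd.concat(latent_rows, ignore_index=True),
        design=design,
    )


def inject_missing_days(dataset: TrialDataset, rate: float, seed: int) -> TrialDataset:
    """Flag additional valid days invalid at the given i.i.d. rate.

    Latent truths and stored values are untouched; only the ``valid``
    flags change.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    days = dataset.days.copy()
    drop = rng.random(len(days)) < rate
    days["valid"] = days["valid"].to_numpy() & ~drop
    return TrialDataset(
        participants=dataset.participants.copy(),
        days=days,
        latent=dataset.latent.copy(),
        design=dataset.design,
    )


def hourly_activity(dataset: TrialDataset, seed: int) -> pd.DataFrame:
    """Reconstruct hourly activity series from daily window summaries.

    For each valid participant-day the 24 hourly values are a square wave:
    ``m10/10`` per hour inside the 10-h active window starting at the
    day's M10 onset, ``l5/5`` per hour elsewhere, plus truncated Gaussian
    noise.  An active-arm IS effect (``effect_is_by_week``) scales the
    hourly noise by ``1 + effect`` for that week, so a negative effect
    yields a more stable (higher-IS) day-to-day pattern.

    Returns a frame with columns id, day, hour, activity.
    """
    design = dataset.design or TrialDesign()
    rng = np.random.default_rng(seed)
    rows = []
    hours = np.arange(24)
    for (pid, arm), sub in dataset.days.groupby(["id", "arm"], sort=True):
        sub = sub[sub["valid"]]
        for r in sub.itertuples():
            onset = int(round(r.m10_onset)) % 24
            active = (hours - onset) % 24 < 10
            base = np.where(active, r.m10 / 10.0, r.l5 / 5.0)
            noise_sd = design.hourly_noise_sd
            if arm == "lithium":
                w = _week_of(int(r.day))
                noise_sd *= 1.0 + design.effect_is_by_week.get(w, 0.0)
            vals = np.clip(base + rng.normal(0.0, max(noise_sd, 0.0), 24), 0.0, None)
            rows.append(
                pd.DataFrame({"id": pid, "day": int(r.day), "hour": hours, "activity": vals})
            )
    if not rows:
        return pd.DataFrame(columns=["id", "day", "hour", "activity"])
    return pd.concat(rows, ignore_index=True)
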