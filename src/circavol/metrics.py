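"""Non-parametric circadian rest-activity metrics from epoch-level activity.

Implements the standard wrist-actigraphy summary chain: raw triaxial
acceleration -> per-epoch signal magnitude vector (SVM) -> day validity by
non-wear time -> most-active-10-h (M10) and least-active-5-h (L5) window
amounts and onsets -> relative amplitude, interdaily stability (IS) and
intradaily variability (IV).

Conventions
-----------
* SVM is the within-epoch sum of ``|sqrt(x^2+y^2+z^2) - g|``.
* M10 is searched midnight-to-midnight; L5 noon-to-noon, with its onset
  reported in hours after the focal day's midnight (hence up to 31 h).
* Window searches step one epoch; ties break to the earliest start.
* A day is excluded when *more than* 3 h of non-wear is flagged (3 h
  exactly is still valid).
* IS and IV operate on clock-hour bins; both are undefined (and raise
  :class:`UndefinedMetricError`) for constant input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedMetricError",
    "EpochSeries",
    "CircadianDay",
    "RhythmStats",
    "compute_svm",
    "infer_nonwear",
    "flag_day_validity",
    "most_active_window",
    "least_active_window",
    "relative_amplitude",
    "interdaily_stability",
    "intradaily_variability",
    "hourly_bins",
    "day_metrics",
    "summarize_period",
]

NONWEAR_LIMIT_SECONDS = 3 * 3600  # strict: a day is invalid beyond 3 h


class UndefinedMetricError(ValueError):
    """Raised when a rhythm metric is mathematically undefined (0/0)."""


@dataclass
class EpochSeries:
    """Fixed-length-epoch activity series for one participant span."""

    start: pd.Timestamp
    epoch_length: int
    values: np.ndarray
    nonwear: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nonwear = np.asarray(self.nonwear, dtype=bool)
        if self.values.shape != self.nonwear.shape:
            raise ValueError("values and nonwear flags must align")
        if np.any(self.values < 0):
            raise ValueError("activity values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def hours(self) -> np.ndarray:
        """Epoch start offset in hours from the series start."""
        return np.arange(len(self)) * self.epoch_length / 3600.0

    def to_csv(self, path) -> None:
        ts = self.start + pd.to_timedelta(np.arange(len(self)) * self.epoch_length, unit="s")
        pd.DataFrame(
            {
                "timestamp_iso": ts.strftime("%Y-%m-%dT%H:%M:%S"),
                "activity": self.values,
                "nonwear_flag": self.nonwear.astype(int),
            }
        ).to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "EpochSeries":
        df = pd.read_csv(path, parse_dates=["timestamp_iso"])
        ts = pd.DatetimeIndex(df["timestamp_iso"])
        if len(ts) < 2:
            raise ValueError("epoch series needs at least 2 rows")
        deltas = np.diff(ts.asi8) // 10**9
        if len(set(deltas.tolist())) != 1:
            raise ValueError("non-uniform epoch spacing")
        return EpochSeries(
            start=ts[0],
            epoch_length=int(deltas[0]),
            values=df["activity"].to_numpy(float),
            nonwear=df["nonwear_flag"].to_numpy() != 0,
        )


@dataclass(frozen=True)
class CircadianDay:
    """One participant-day's window summaries."""

    day: int
    valid: bool
    m10_amount: float = np.nan
    m10_onset: float = np.nan
    l5_amount: float = np.nan
    l5_onset: float = np.nan


@dataclass(frozen=True)
class RhythmStats:
    """Per-period rhythmicity summaries (NaN where undefined)."""

    period: str
    relative_amplitude: float
    interdaily_stability: float
    intradaily_variability: float


# ---------------------------------------------------------------------------
# SVM and non-wear
# ---------------------------------------------------------------------------

def compute_svm(
    samples: np.ndarray,
    sample_hz: float,
    epoch_length: int,
    g: float = 1.0,
    start: pd.Timestamp | None = None,
) -> EpochSeries:
    """Aggregate raw triaxial samples into per-epoch SVM values.

    ``samples`` is an (N, 3) array of accelerations in g-units recorded at
    a fixed rate ``sample_hz``.  Each epoch's value is the sum over its
    samples of the absolute deviation of the Euclidean norm from gravity.
    Trailing samples that do not fill a whole epoch are dropped.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample array")
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError("samples must be (N, 3)")
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples must be finite")
    per_epoch = sample_hz * epoch_length
    if abs(per_epoch - round(per_epoch)) > 1e-9 or per_epoch < 1:
        raise ValueError("epoch_length must hold a whole number of samples")
    per_epoch = int(round(per_epoch))
    n_epochs = len(samples) // per_epoch
    if n_epochs == 0:
        raise ValueError("fewer samples than one epoch")
    dev = np.abs(np.linalg.norm(samples[: n_epochs * per_epoch], axis=1) - g)
    values = dev.reshape(n_epochs, per_epoch).sum(axis=1)
    return EpochSeries(
        start=start if start is not None else pd.Timestamp("2000-01-01"),
        epoch_length=epoch_length,
        values=values,
        nonwear=np.zeros(n_epochs, dtype=bool),
    )


def read_triaxial_csv(path) -> tuple[np.ndarray, float]:
    """Read a raw triaxial CSV ``timestamp_iso,x,y,z`` (g-units).

    Returns the (N, 3) sample array and the sampling rate in Hz inferred
    from the (required uniform) timestamp spacing.
    """
    df = pd.read_csv(path, parse_dates=["timestamp_iso"])
    if len(df) < 2:
        raise ValueError("need at least 2 samples")
    ts = pd.DatetimeIndex(df["timestamp_iso"]).asi8
    deltas = np.diff(ts)
    if deltas.min() <= 0 or (np.abs(deltas - deltas[0]) > max(1, deltas[0] // 1000)).any():
        raise ValueError("non-uniform sampling")
    hz = 1e9 / float(deltas[0])
    return df[["x", "y", "z"]].to_numpy(float), hz


def infer_nonwear(
    series: EpochSeries, window_minutes: int = 30, sd_threshold: float = 1e-3
) -> np.ndarray:
    """Fallback stationarity heuristic for non-wear flags.

    Flags every epoch inside any run of at least ``window_minutes`` whose
    rolling standard deviation stays below ``sd_threshold``.  This is NOT
    the device vendor's algorithm - it is a simple, clearly non-canonical
    stand-in for use when flags are absent from the input.
    """
    w = max(1, int(window_minutes * 60 // series.epoch_length))
    v = pd.Series(series.values)
    sd = v.rolling(w).std().to_numpy()
    flags = np.zeros(len(series), dtype=bool)
    low = np.nan_to_num(sd, nan=np.inf) < sd_threshold
    for i in np.flatnonzero(low):  # window [i-w+1, i] was stationary
        flags[max(0, i - w + 1): i + 1] = True
    return flags


def flag_day_validity(series: EpochSeries) -> dict[int, bool]:
    """Per-calendar-day validity: invalid iff non-wear exceeds 3 h."""
    seconds_flagged: dict[int, float] = {}
    day_idx = (np.arange(len(series)) * series.epoch_length) // 86400
    for d in np.unique(day_idx):
        mask = day_idx == d
        seconds_flagged[int(d)] = float(series.nonwear[mask].sum()) * series.epoch_length
    return {d: s <= NONWEAR_LIMIT_SECONDS for d, s in seconds_flagged.items()}


# ---------------------------------------------------------------------------
# window finders
# ---------------------------------------------------------------------------

def _window_sums(values: np.ndarray, w: int) -> np.ndarray:
    # direct per-window summation: bit-identical to summing each slice,
    # avoiding the cancellation drift of a cumulative-sum rolling window
    return np.lib.stride_tricks.sliding_window_view(values, w).sum(axis=1)


def most_active_window(
    series: EpochSeries, day: int = 0, window_hours: float = 10.0
) -> tuple[float, float]:
    """Total activity and onset of the most active window of one day.

    Searches every epoch-aligned start within 00:00-24:00 of ``day``
    (window fully inside the day); ties break to the earliest start.
    Returns ``(amount, onset_hours_after_midnight)``.
    """
    per_day = 86400 // series.epoch_length
    w = int(round(window_hours * 3600 / series.epoch_length))
    seg = series.values[day * per_day: (day + 1) * per_day]
    if len(seg) < per_day:
        raise ValueError("day not fully covered by epochs")
    if w > len(seg):
        raise ValueError("window longer than day coverage")
    sums = _window_sums(seg, w)
    i = int(np.argmax(sums))  # argmax returns the first maximum
    return float(sums[i]), i * series.epoch_length / 3600.0


def least_active_window(
    series: EpochSeries, day: int = 0, window_hours: float = 5.0
) -> tuple[float, float]:
    """Total activity and onset of the least active window, noon-to-noon.

    Searches 12:00 of ``day`` through 12:00 of the next day; the onset is
    reported in hours after the focal day's midnight, so it lies in
    [12, 36 - window].  Ties break to the earliest start.
    """
    per_day = 86400 // series.epoch_length
    w = int(round(window_hours * 3600 / series.epoch_length))
    lo = day * per_day + per_day // 2
    hi = lo + per_day
    seg = series.values[lo:hi]
    if len(seg) < per_day:
        raise ValueError("noon-to-noon span not fully covered")
    sums = _window_sums(seg, w)
    i = int(np.argmin(sums))
    return float(sums[i]), 12.0 + i * series.epoch_length / 3600.0


# ---------------------------------------------------------------------------
# rhythm statistics
# ---------------------------------------------------------------------------

def relative_amplitude(m10_amount: float, l5_amount: float) -> float:
    """Rest-activity rhythm amplitude (M10 - L5)/(M10 + L5).

    Inputs must be directly comparable quantities (e.g. per-hour means);
    the ratio of a raw 10-h sum to a raw 5-h sum inflates the value.
    Both-zero input is undefined.
    """
    if m10_amount < 0 or l5_amount < 0:
        raise ValueError("amounts must be non-negative")
    tot = m10_amount + l5_amount
    if tot == 0:
        raise UndefinedMetricError("relative amplitude undefined for zero activity")
    return (m10_amount - l5_amount) / tot


def interdaily_stability(hourly: np.ndarray) -> float:
    """Day-to-day stability of the 24-h profile, in [0, 1].

    ``IS = N * sum_h (xbar_h - xbar)^2 / (24 * sum_i (x_i - xbar)^2)``
    over complete days of hourly values: the variance of the hour-of-day
    means relative to the total variance.  1 for a perfectly repeated
    pattern, about 1/D for D days of white noise.
    """
    x = np.asarray(hourly, dtype=float)
    if x.ndim != 1 or len(x) % 24 != 0 or len(x) < 48:
        raise ValueError("need >= 2 complete days of hourly values")
    n = len(x)
    xbar = x.mean()
    denom = ((x - xbar) ** 2).sum()
    if denom == 0:
        raise UndefinedMetricError("IS undefined for constant series")
    hour_means = x.reshape(-1, 24).mean(axis=0)
    return float(n * ((hour_means - xbar) ** 2).sum() / (24.0 * denom))


def intradaily_variability(hourly: np.ndarray) -> float:
    """Fragmentation of the rhythm: normalized mean squared successive
    difference of the hourly series (about 2 for white noise, small for a
    smooth 24-h profile)."""
    x = np.asarray(hourly, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need at least 2 hourly values")
    n = len(x)
    var = ((x - x.mean()) ** 2).sum() / n
    if var == 0:
        raise UndefinedMetricError("IV undefined for constant series")
    msd = (np.diff(x) ** 2).sum() / (n - 1)
    return float(msd / var)


def hourly_bins(series: EpochSeries) -> np.ndarray:
    """Sum epoch values into clock-hour bins; drop a partial trailing hour."""
    per_hour = 3600 // series.epoch_length
    n_hours = len(series) // per_hour
    if n_hours == 0:
        raise ValueError("series shorter than one hour")
    return series.values[: n_hours * per_hour].reshape(n_hours, per_hour).sum(axis=1)


# ---------------------------------------------------------------------------
# per-day and per-period summaries
# ---------------------------------------------------------------------------

def day_metrics(series: EpochSeries, day: int = 0) -> CircadianDay:
    """M10/L5 summaries for one day (requires 36-h coverage from the focal
    midnight for the noon-to-noon L5 search)."""
    validity = flag_day_validity(series)
    valid = validity.get(day, False)
    if not valid:
        return CircadianDay(day=day, valid=False)
    m10, m10_on = most_active_window(series, day, 10.0)
    l5, l5_on = least_active_window(series, day, 5.0)
    return CircadianDay(
        day=day, valid=True, m10_amount=m10, m10_onset=m10_on, l5_amount=l5, l5_onset=l5_on
    )


def summarize_period(
    days: list[CircadianDay],
    period: str,
    hourly: np.ndarray | None = None,
) -> RhythmStats:
    """Period-level rhythm statistics from daily records.

    Relative amplitude uses the period means of the M10 and L5 amounts,
    rescaled to per-hour means so the 10-h and 5-h sums are comparable.
    IS/IV need the period's concatenated hourly data (``hourly``).  Fewer
    than 2 valid days (or absent hourly data) yields NaN fields rather
    than an exception, so sparse periods propagate as missing values.
    """
    valid = [d for d in days if d.valid]
    ra = is_ = iv = np.nan
    if len(valid) >= 2:
        m10_hourly = float(np.mean([d.m10_amount for d in valid])) / 10.0
        l5_hourly = float(np.mean([d.l5_amount for d in valid])) / 5.0
        try:
            ra = relative_amplitude(m10_hourly, l5_hourly)
        except UndefinedMetricError:
            pass
        if hourly is not None and len(hourly) >= 48:
            try:
                is_ = interdaily_stability(np.asarray(hourly)[: len(hourly) // 24 * 24])
                iv = intradaily_variability(np.asarray(hourly, dtype=float))
            except UndefinedMetricError:
                pass
    return RhythmStats(
        period=period, relative_amplitude=ra, interdaily_stability=is_, intradaily_variability=iv
    )
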