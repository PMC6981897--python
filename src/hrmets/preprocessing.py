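"""R-R interval preprocessing: epoch HR, outlier screening, minute averaging.

The cleaning pipeline mirrors the study protocol for patch-ECG recordings:

1. beat-to-beat R-R intervals are resampled onto fixed 0.4-s epochs (each
   epoch's HR is 60 / overlap-weighted mean R-R);
2. empty epochs and epochs outside mean +- k SD of the activity's recording
   are discarded (k = 4 for radio calisthenics, 3 otherwise);
3. the activity HR is the unweighted mean of per-minute means;
4. resting HR applies the same minute averaging to a 7-min seated window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RRIntervalSeries",
    "EpochHRSeries",
    "rr_to_epoch_hr",
    "remove_epoch_outliers",
    "activity_mean_hr",
    "resting_hr_from_window",
    "read_rr_csv",
    "write_rr_csv",
]

DEFAULT_EPOCH_S = 0.4
RESTING_WINDOW_S = 420.0
# A trailing partial minute must hold at least this much non-missing epoch
# coverage to enter the minute average.
MIN_PARTIAL_MINUTE_S = 15.0


@dataclass(frozen=True)
class RRIntervalSeries:
    """Beat-to-beat R-R intervals for one subject-activity recording.

    timestamps are beat end-times (s, monotone non-decreasing); rr are the
    interval lengths (s).  Beat i is taken to occupy
    (timestamps[i] - rr[i], timestamps[i]], i.e. the record is contiguous.
    """

    subject_id: str
    activity_name: str
    timestamps: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        rr = np.asarray(self.rr, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "rr", rr)
        if t.shape != rr.shape or t.ndim != 1:
            raise ValueError("timestamps and rr must be 1-D arrays of equal length")
        if len(rr) and np.any(rr <= 0):
            raise ValueError("all R-R intervals must be positive")
        if len(t) > 1 and np.any(np.diff(t) < 0):
            raise ValueError("timestamps must be monotone non-decreasing")

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1]) if len(self.timestamps) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_seconds": self.timestamps, "rr_seconds": self.rr})


@dataclass(frozen=True)
class EpochHRSeries:
    """Per-epoch heart rate (bpm); NaN marks empty/removed epochs."""

    epoch_length: float
    hr_values: np.ndarray

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        object.__setattr__(self, "hr_values", np.asarray(self.hr_values, dtype=float))

    @property
    def n_epochs(self) -> int:
        return len(self.hr_values)

    @property
    def n_valid(self) -> int:
        return int(np.sum(~np.isnan(self.hr_values)))


def rr_to_epoch_hr(series: RRIntervalSeries, epoch_length: float = DEFAULT_EPOCH_S) -> EpochHRSeries:
    """Resample beat-to-beat R-R onto fixed epochs.

    Each epoch's HR is 60 divided by the mean R-R over the epoch, weighted by
    how long each beat's interval overlaps the epoch.  Epochs past the end of
    the recording (no beat coverage) are NaN.
    """
    if len(series.rr) == 0:
        raise ValueError("series is empty")
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")

    t_end = series.timestamps
    rr = series.rr
    start = t_end[0] - rr[0]
    # Piecewise-linear cumulative integral of the R-R step function:
    # F(t_end[i]) = sum_{j<=i} rr_j^2, linear (slope rr_i) inside beat i.
    knots = np.concatenate([[start], t_end])
    F = np.concatenate([[0.0], np.cumsum(rr * rr)])
    total = t_end[-1] - start

    n_epochs = int(np.ceil(total / epoch_length - 1e-9))
    edges = start + epoch_length * np.arange(n_epochs + 1)
    covered_hi = np.minimum(edges[1:], t_end[-1])
    cover = covered_hi - edges[:-1]
    Fi = np.interp(np.clip(edges, start, t_end[-1]), knots, F)
    integral = np.interp(covered_hi, knots, F) - Fi[:-1]

    hr = np.full(n_epochs, np.nan)
    ok = cover > 1e-12
    hr[ok] = 60.0 * cover[ok] / integral[ok]  # 60 / weighted-mean RR
    return EpochHRSeries(epoch_length=epoch_length, hr_values=hr)


def remove_epoch_outliers(epochs: EpochHRSeries, k_sd: float) -> tuple[EpochHRSeries, int]:
    """Screen epochs outside mean +- k_sd x SD of the recording.

    Mean and SD are computed once over the activity's non-missing epochs
    (single pass, whole recording).  A zero SD (constant trace) removes
    nothing.  Returns (cleaned copy, number of epochs removed).
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    hr = epochs.hr_values
    valid = ~np.isnan(hr)
    if not valid.any():
        raise ValueError("all epochs are missing; nothing to screen")
    mean = float(np.mean(hr[valid]))
    sd = float(np.std(hr[valid], ddof=0))
    if sd == 0.0:
        return EpochHRSeries(epochs.epoch_length, hr.copy()), 0
    out = valid & (np.abs(hr - mean) > k_sd * sd)
    cleaned = hr.copy()
    cleaned[out] = np.nan
    return EpochHRSeries(epochs.epoch_length, cleaned), int(out.sum())


def _minute_means(epochs: EpochHRSeries) -> np.ndarray:
    """Per-minute mean HR over non-missing epochs.

    Minutes with no surviving epoch are dropped.  A trailing partial minute
    enters only if it holds >= 15 s of non-missing epoch coverage.
    """
    hr = epochs.hr_values
    per_min = max(int(round(60.0 / epochs.epoch_length)), 1)
    n_full = len(hr) // per_min
    means = []
    for m in range(n_full):
        chunk = hr[m * per_min:(m + 1) * per_min]
        if np.any(~np.isnan(chunk)):
            means.append(float(np.nanmean(chunk)))
    tail = hr[n_full * per_min:]
    if len(tail):
        coverage = np.sum(~np.isnan(tail)) * epochs.epoch_length
        if coverage >= MIN_PARTIAL_MINUTE_S:
            means.append(float(np.nanmean(tail)))
    return np.asarray(means)


def activity_mean_hr(epochs: EpochHRSeries, minutes: int | None = None) -> float:
    """Activity HR: unweighted mean of per-minute mean HRs, bpm.

    If ``minutes`` is given, only the first that many minutes of the trace
    are used (the protocol scores a fixed measurement window per activity).
    """
    if minutes is not None:
        if minutes < 1:
            raise ValueError("minutes must be >= 1")
        per_min = max(int(round(60.0 / epochs.epoch_length)), 1)
        epochs = EpochHRSeries(epochs.epoch_length, epochs.hr_values[: minutes * per_min])
    means = _minute_means(epochs)
    if len(means) == 0:
        raise ValueError("no usable minutes (all epochs missing or trace too short)")
    return float(np.mean(means))


def resting_hr_from_window(epochs: EpochHRSeries, window: float = RESTING_WINDOW_S) -> float:
    """Resting HR over a seated window (default 7 min), minute-averaged."""
    if window <= 0:
        raise ValueError("window must be positive")
    n = int(round(window / epochs.epoch_length))
    if n > epochs.n_epochs:
        raise ValueError(
            f"window of {window:.0f}s needs {n} epochs; recording has {epochs.n_epochs}"
        )
    return activity_mean_hr(EpochHRSeries(epochs.epoch_length, epochs.hr_values[:n]))


def write_rr_csv(series: RRIntervalSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_rr_csv(path, subject_id: str = "", activity_name: str = "") -> RRIntervalSeries:
    df = pd.read_csv(path)
    return RRIntervalSeries(
        subject_id=subject_id,
        activity_name=activity_name,
        timestamps=df["t_seconds"].to_numpy(float),
        rr=df["rr_seconds"].to_numpy(float),
    )
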