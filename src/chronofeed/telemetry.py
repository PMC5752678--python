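"""Telemetry analysis: RR filtering, time-domain HRV, CBT waveforms.

Beat-to-beat (RR) intervals from implanted telemetry are artifact-filtered
into normal-to-normal (NN) intervals; 20-s segments of NN means give
instantaneous heart rate, averaged into ZT-hour bins.  SDNN (the SD of all
NN intervals, per hour and over 24 h) is the time-domain HRV index, and the
heart-rate rhythm amplitude is the max/min ratio of the hourly HR waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .core import DataError, LightSchedule, QualityError

__all__ = [
    "RRSeries",
    "NNSeries",
    "HRVSummary",
    "filter_rr",
    "segment_stats",
    "hr_amplitude",
    "cbt_waveform",
    "read_rr_csv",
    "write_rr_csv",
]


@dataclass
class RRSeries:
    """Beat-to-beat intervals (ms) with cumulative timestamps (s)."""

    animal_id: str
    rr_ms: np.ndarray
    t_s: np.ndarray  # time of each beat from recording start, strictly increasing
    start_zt: float = 0.0
    schedule: LightSchedule = field(default_factory=LightSchedule)

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.t_s = np.asarray(self.t_s, dtype=float)
        if self.rr_ms.shape != self.t_s.shape:
            raise DataError("rr_ms and t_s must have the same length")
        if np.any(self.rr_ms <= 0):
            raise DataError("RR intervals must be positive")
        if np.any(np.diff(self.t_s) <= 0):
            raise DataError("timestamps must be strictly increasing")


@dataclass
class NNSeries:
    """Artifact-filtered normal-to-normal intervals."""

    nn_ms: np.ndarray
    t_s: np.ndarray
    start_zt: float
    retained_fraction: float


@dataclass
class HRVSummary:
    """Hourly HR/SDNN waveforms and 24-h means (ZT-hour indexed)."""

    hourly_hr_bpm: np.ndarray  # 24 values, NaN where the hour is empty
    hourly_sdnn_ms: np.ndarray
    mean_24h_hr_bpm: float
    mean_24h_sdnn_ms: float
    missing_hours: tuple[int, ...]

    @property
    def hr_amplitude_ratio(self) -> float:
        return hr_amplitude(self)


def filter_rr(
    rr: RRSeries,
    band_ms: tuple[float, float] = (50.0, 250.0),
    local_k: float = 4.0,
    window_beats: int = 31,
    min_retained: float = 0.5,
) -> NNSeries:
    """Filter RR intervals to normal-to-normal (NN) intervals.

    Two-stage artifact rejection: (1) drop intervals outside the
    physiological band ``band_ms``; (2) drop intervals deviating more than
    ``local_k`` robust SDs (1.4826 x the median absolute deviation, floored
    at 1 ms so noise-free series are not degenerate) from a
    ``window_beats``-beat rolling median.

    Raises :class:`QualityError` when fewer than ``min_retained`` of the
    beats survive.
    """
    if rr.rr_ms.size == 0:
        raise DataError("empty RR series")
    in_band = (rr.rr_ms >= band_ms[0]) & (rr.rr_ms <= band_ms[1])
    x = rr.rr_ms[in_band]
    t = rr.t_s[in_band]
    if x.size:
        rolling_med = median_filter(x, size=window_beats, mode="nearest")
        dev = np.abs(x - rolling_med)
        scale = max(1.4826 * np.median(dev), 1.0)
        keep = dev <= local_k * scale
        x, t = x[keep], t[keep]
    retained = x.size / rr.rr_ms.size
    if retained < min_retained:
        raise QualityError(
            f"only {retained:.1%} of beats retained after filtering "
            f"(threshold {min_retained:.0%}); check the recording"
        )
    return NNSeries(nn_ms=x, t_s=t, start_zt=rr.start_zt, retained_fraction=retained)


def segment_stats(
    nn: NNSeries,
    segment_s: float = 20.0,
    population_sd: bool = True,
) -> HRVSummary:
    """Hourly HR and SDNN waveforms from a filtered NN series.

    NN intervals are grouped into ``segment_s``-second segments; each
    segment's mean NN gives an instantaneous HR (bpm = 60000 / mean NN) and
    segments are averaged into ZT-hour bins.  SDNN per hour is the SD of all
    NN intervals in that hour (population SD by default, per the "SD of all
    NN intervals" time-domain convention).  24-h means average over the
    hours present; empty hours are reported and excluded.
    """
    seg_idx = np.floor(nn.t_s / segment_s).astype(np.int64)
    hr_hour = np.full(24, np.nan)
    sdnn_hour = np.full(24, np.nan)
    hour_of_beat = np.floor((nn.start_zt + nn.t_s / 3600.0) % 24.0).astype(int)
    uniq = np.unique(seg_idx)
    # mean NN per segment via bincount
    pos = np.searchsorted(uniq, seg_idx)
    seg_mean = np.bincount(pos, weights=nn.nn_ms) / np.bincount(pos)
    seg_hr = 60000.0 / seg_mean
    seg_hour_u = np.floor(
        (nn.start_zt + uniq * segment_s / 3600.0) % 24.0
    ).astype(int)
    ddof = 0 if population_sd else 1
    for h in range(24):
        hr_vals = seg_hr[seg_hour_u == h]
        if hr_vals.size:
            hr_hour[h] = hr_vals.mean()
        beats = nn.nn_ms[hour_of_beat == h]
        if beats.size > ddof:
            sdnn_hour[h] = beats.std(ddof=ddof)
    missing = tuple(int(h) for h in range(24) if np.isnan(hr_hour[h]))
    return HRVSummary(
        hourly_hr_bpm=hr_hour,
        hourly_sdnn_ms=sdnn_hour,
        mean_24h_hr_bpm=float(np.nanmean(hr_hour)),
        mean_24h_sdnn_ms=float(np.nanmean(sdnn_hour)),
        missing_hours=missing,
    )


def hr_amplitude(summary: HRVSummary) -> float:
    """Heart-rate rhythm amplitude: max/min ratio of the hourly HR waveform.

    Refuses to compute on incomplete days (missing hours would produce
    spurious extremes); impute or exclude the animal instead.
    """
    if summary.missing_hours:
        raise DataError(
            f"hours {summary.missing_hours} missing; amplitude requires a "
            "complete 24-h waveform (exclude the animal or impute upstream)"
        )
    return float(summary.hourly_hr_bpm.max() / summary.hourly_hr_bpm.min())


def cbt_waveform(
    t_s: np.ndarray,
    temp_c: np.ndarray,
    start_zt: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Hourly core-body-temperature waveform and 24-h mean.

    Uniform temperature samples are binned by ZT hour exactly as the HR
    segments are; the SEM per hour is computed across per-day hourly means,
    and the 24-h mean is the mean of the 24 hourly means.

    Returns ``(hourly_mean, hourly_sem, mean_24h)``.
    """
    t_s = np.asarray(t_s, dtype=float)
    temp_c = np.asarray(temp_c, dtype=float)
    zt = (start_zt + t_s / 3600.0) % 24.0
    hour = np.floor(zt).astype(int)
    day = np.floor((start_zt * 3600.0 + t_s) / 86400.0).astype(int)
    hourly_mean = np.full(24, np.nan)
    hourly_sem = np.full(24, np.nan)
    for h in range(24):
        sel = hour == h
        if not sel.any():
            continue
        hourly_mean[h] = temp_c[sel].mean()
        day_means = [temp_c[sel & (day == d)].mean() for d in np.unique(day[sel])]
        if len(day_means) > 1:
            hourly_sem[h] = np.std(day_means, ddof=1) / np.sqrt(len(day_means))
        else:
            hourly_sem[h] = 0.0
    return hourly_mean, hourly_sem, float(np.nanmean(hourly_mean))


def read_rr_csv(path, schedule: LightSchedule | None = None) -> RRSeries:
    """Read an RR series from CSV with columns ``t_s`` and ``rr_ms``."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("t_s", "rr_ms"):
        if col not in df.columns:
            raise DataError(f"column {col!r} missing from {path}")
    animal = str(df["animal_id"].iloc[0]) if "animal_id" in df.columns else "rr"
    return RRSeries(
        animal_id=animal,
        rr_ms=df["rr_ms"].to_numpy(dtype=float),
        t_s=df["t_s"].to_numpy(dtype=float),
        schedule=schedule or LightSchedule(),
    )


def write_rr_csv(rr: RRSeries, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"t_s": rr.t_s, "rr_ms": rr.rr_ms, "animal_id": rr.animal_id}
    ).to_csv(path, index=False)
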