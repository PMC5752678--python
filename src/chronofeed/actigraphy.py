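"""Locomotor-rhythm analysis.

Chi-square periodogram rhythm power, activity-bout segmentation, daily
activity-onset estimation and onset variability, hourly waveforms and
activity totals, for evenly binned cage-activity count series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    ACTIVE_PHASE,
    FULL_DAY,
    REST_PHASE,
    ActivityRecording,
    InsufficientDataError,
    PhaseWindow,
)

__all__ = [
    "PeriodogramResult",
    "Bout",
    "OnsetSeries",
    "ActivityWaveform",
    "chi_square_periodogram",
    "detect_bouts",
    "bout_summary",
    "estimate_onsets",
    "average_waveform",
    "mean_activity_per_hour",
]


@dataclass
class PeriodogramResult:
    """Chi-square periodogram over a grid of trial periods.

    ``power_pct_v`` is the rhythm power (%V): the peak statistic, expressed
    as a percentage of the number of analysed bins, in excess of the
    significance line at the peak (clamped at 0 when the peak does not reach
    significance; ``below_threshold`` is then set).  ``raw_power_pct_v``
    carries the un-subtracted 100*Qp/N variant for cross-tool comparison.
    """

    periods_h: np.ndarray
    qp: np.ndarray
    sig_line: np.ndarray
    alpha: float
    peak_period_h: float
    power_pct_v: float
    raw_power_pct_v: float
    below_threshold: bool
    n_bins: np.ndarray = field(default=None, repr=False)  # bins analysed per trial period


def chi_square_periodogram(
    rec: ActivityRecording,
    period_range_h: tuple[float, float] = (20.0, 28.0),
    alpha: float = 0.001,
    correct_for_periods: bool = True,
) -> PeriodogramResult:
    """Chi-square (Sokolove-Bushell) periodogram of a binned activity series.

    For each trial period of ``P`` whole bins, the series is folded into
    ``K = floor(N/P)`` complete cycles (the trailing remainder is discarded)
    and the column-variance statistic is computed::

        Qp = N' * SS_between_columns / SS_total,   N' = K * P

    Under the i.i.d. null, Qp ~ chi2(P - 1); the significance line is the
    ``1 - alpha`` quantile of that distribution, Bonferroni-corrected for
    the number of trial periods on the grid by default so that the rate of
    false peaks anywhere on the grid stays below ``alpha``-level overall
    (``correct_for_periods=False`` reproduces the classical per-period
    line, under which a ~160-period grid shows a few percent of spurious
    significant peaks on rhythm-free data).  The peak is the maximum Qp
    over the grid; rhythm power is derived from the peak as documented on
    :class:`PeriodogramResult`.

    Raises
    ------
    InsufficientDataError
        If the recording is shorter than two cycles of the longest trial
        period.
    """
    x = rec.counts.astype(float)
    n_total = x.size
    bph = rec.bins_per_hour
    p_lo = int(np.ceil(period_range_h[0] * bph))
    p_hi = int(np.floor(period_range_h[1] * bph))
    if p_lo > p_hi:
        raise ValueError("empty trial-period grid")
    if n_total < 2 * p_hi:
        raise InsufficientDataError(
            f"recording of {n_total} bins is shorter than two cycles of the "
            f"longest trial period ({p_hi} bins)"
        )
    periods = np.arange(p_lo, p_hi + 1)
    qp = np.empty(periods.size)
    n_used = np.empty(periods.size, dtype=int)
    for i, p in enumerate(periods):
        k = n_total // p
        n = k * p
        folded = x[:n].reshape(k, p)
        grand = folded.mean()
        ss_between = k * np.sum((folded.mean(axis=0) - grand) ** 2)
        ss_total = np.sum((folded - grand) ** 2)
        qp[i] = 0.0 if ss_total == 0 else n * ss_between / ss_total
        n_used[i] = n
    level = alpha / periods.size if correct_for_periods else alpha
    sig = stats.chi2.ppf(1 - level, periods - 1)
    peak = int(np.argmax(qp))
    below = qp[peak] <= sig[peak]
    excess = 100.0 * (qp[peak] - sig[peak]) / n_used[peak]
    return PeriodogramResult(
        periods_h=periods / bph,
        qp=qp,
        sig_line=sig,
        alpha=alpha,
        peak_period_h=periods[peak] / bph,
        power_pct_v=max(excess, 0.0),
        raw_power_pct_v=100.0 * qp[peak] / n_used[peak],
        below_threshold=bool(below),
        n_bins=n_used,
    )


@dataclass(frozen=True)
class Bout:
    """Maximal run of suprathreshold activity, half-open in bin indices.

    Sub-threshold gaps up to the maximum gap are contained within a bout;
    bouts always start and end on a suprathreshold bin.
    """

    start: int
    end: int
    duration_min: float
    total_counts: float


def detect_bouts(
    rec: ActivityRecording,
    threshold_cpm: float = 3.0,
    max_gap_min: float = 21.0,
) -> list[Bout]:
    """Segment a recording into activity bouts.

    A bin is active when its counts reach ``threshold_cpm * bin_minutes``
    (the counts/min threshold converted to the bin width).  Consecutive
    active runs separated by sub-threshold gaps of at most ``max_gap_min``
    are merged into one bout; bouts are maximal.
    """
    thr = threshold_cpm * rec.bin_minutes
    active = rec.counts >= thr
    if not active.any():
        return []
    max_gap_bins = int(max_gap_min // rec.bin_minutes)
    idx = np.nonzero(active)[0]
    bouts: list[Bout] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 > max_gap_bins:  # gap too long: close the bout
            bouts.append(_make_bout(rec, start, prev + 1))
            start = i
        prev = i
    bouts.append(_make_bout(rec, start, prev + 1))
    return bouts


def _make_bout(rec: ActivityRecording, start: int, end: int) -> Bout:
    return Bout(
        start=int(start),
        end=int(end),
        duration_min=(end - start) * rec.bin_minutes,
        total_counts=float(rec.counts[start:end].sum()),
    )


def bout_summary(
    bouts: list[Bout],
    rec: ActivityRecording,
    windows: tuple[PhaseWindow, ...] = (REST_PHASE, ACTIVE_PHASE, FULL_DAY),
) -> dict[str, dict[str, float]]:
    """Bouts per day and mean bout duration per phase window.

    A bout is assigned to the window containing its start bin, so a bout
    straddling lights-off is counted once, in the phase where it began.
    """
    out: dict[str, dict[str, float]] = {}
    start_zt = np.array([rec.zt_of_bin(b.start) for b in bouts])
    durations = np.array([b.duration_min for b in bouts])
    for w in windows:
        label = w.label or f"ZT{w.start_zt:g}-{w.end_zt:g}"
        in_w = w.contains(start_zt) if bouts else np.zeros(0, bool)
        n = int(np.sum(in_w))
        out[label] = {
            "bouts_per_day": n / rec.n_days,
            "mean_duration_min": float(durations[in_w].mean()) if n else np.nan,
        }
    return out


@dataclass
class OnsetSeries:
    """Daily activity onsets with their best-fit line and variability.

    ``variability_min`` is the mean absolute deviation of daily onsets from
    the least-squares regression line over days, in minutes (a signed mean
    would vanish by construction of the fit).
    """

    day_index: np.ndarray
    onset_zt: np.ndarray  # NaN where no onset was found
    slope_h_per_day: float
    intercept_zt: float
    variability_min: float
    quality_warning: bool


def estimate_onsets(
    rec: ActivityRecording,
    template_hours: tuple[float, float] = (6.0, 6.0),
    search_window_zt: tuple[float, float] = (8.0, 16.0),
) -> OnsetSeries:
    """Estimate daily activity onsets and their cycle-to-cycle variability.

    Per day, the onset is the bin time maximising the correlation of the
    activity series with a step template (``template_hours[0]`` hours of
    quiet at -1 followed by ``template_hours[1]`` hours of activity at +1),
    searched within ``search_window_zt``; ties break to the earliest time.
    A least-squares line over (day, onset) absorbs any linear drift, and the
    variability is the mean absolute deviation from that line.
    """
    if rec.n_days < 7:
        raise InsufficientDataError("onset variability needs at least 7 days")
    bph = rec.bins_per_hour
    x = rec.counts.astype(float)
    l_pre = int(round(template_hours[0] * bph))
    l_post = int(round(template_hours[1] * bph))
    # score(t) = sum(x[t:t+l_post]) - sum(x[t-l_pre:t]) via cumulative sums
    cs = np.concatenate([[0.0], np.cumsum(x)])

    def score(t: np.ndarray) -> np.ndarray:
        return (cs[t + l_post] - cs[t]) - (cs[t] - cs[t - l_pre])

    onsets = np.full(rec.n_days, np.nan)
    bpd = rec.bins_per_day
    for d in range(rec.n_days):
        day0 = d * bpd
        lo = day0 + int(round(((search_window_zt[0] - rec.start_zt) % 24) * bph))
        hi = day0 + int(round(((search_window_zt[1] - rec.start_zt) % 24) * bph))
        lo = max(lo, l_pre)
        hi = min(hi, x.size - l_post)
        if lo >= hi:
            continue
        cand = np.arange(lo, hi)
        s = score(cand)
        if s.max() <= 0:  # no activity rise inside the window
            continue
        onsets[d] = rec.zt_of_bin(cand[np.argmax(s)])
    found = ~np.isnan(onsets)
    quality_warning = found.sum() < 0.7 * rec.n_days
    days = np.arange(rec.n_days)
    if found.sum() >= 2:
        fit = stats.linregress(days[found], onsets[found])
        resid = onsets[found] - (fit.intercept + fit.slope * days[found])
        variability_min = float(np.mean(np.abs(resid)) * 60)
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        slope = intercept = variability_min = np.nan
    return OnsetSeries(
        day_index=days,
        onset_zt=onsets,
        slope_h_per_day=slope,
        intercept_zt=intercept,
        variability_min=variability_min,
        quality_warning=bool(quality_warning),
    )


@dataclass
class ActivityWaveform:
    """Hourly activity profile (a.u./h), averaged over days then animals."""

    hourly_mean: np.ndarray  # 24 values
    hourly_sem: np.ndarray  # 24 values; across animals for group waveforms
    n_days: int
    n_animals: int
    per_animal: np.ndarray = field(default=None, repr=False)  # animals x 24


def average_waveform(
    recs: ActivityRecording | list[ActivityRecording],
    days: int | None = None,
) -> ActivityWaveform:
    """Hourly activity waveform for one animal or a group.

    Each animal's profile is the mean counts per ZT hour over its analysed
    days; the group waveform is the mean and SEM of those profiles across
    animals (not across days).
    """
    if isinstance(recs, ActivityRecording):
        recs = [recs]
    profiles = []
    n_days_used = None
    for rec in recs:
        if days is not None:
            rec = rec.last_days(days)
        n_days_used = rec.n_days
        bpd, bph = rec.bins_per_day, rec.bins_per_hour
        daily = rec.counts.reshape(rec.n_days, bpd).mean(axis=0)
        hourly = daily.reshape(24, bph).sum(axis=1)  # counts per clock hour
        # rotate so index 0 is ZT 0
        shift = int(round(rec.start_zt)) % 24
        profiles.append(np.roll(hourly, shift))
    prof = np.vstack(profiles)
    n_animals = prof.shape[0]
    sem = (
        prof.std(axis=0, ddof=1) / np.sqrt(n_animals)
        if n_animals > 1
        else np.zeros(24)
    )
    return ActivityWaveform(
        hourly_mean=prof.mean(axis=0),
        hourly_sem=sem,
        n_days=n_days_used,
        n_animals=n_animals,
        per_animal=prof,
    )


def mean_activity_per_hour(
    rec: ActivityRecording, window: PhaseWindow | None = None
) -> float:
    """Mean activity in a.u./h: total counts divided by total hours.

    With a ``window``, only bins whose start ZT falls inside it contribute,
    and the divisor is the windowed hours actually analysed.
    """
    if window is None:
        return float(rec.counts.sum()) / (rec.n_days * 24.0)
    in_w = window.contains(rec.bin_zt)
    hours = in_w.sum() * rec.bin_minutes / 60.0
    return float(rec.counts[in_w].sum()) / hours
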