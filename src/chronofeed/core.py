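"""Shared domain types, zeitgeber-time conventions, and tabular I/O.

Zeitgeber time (ZT) is measured in hours since lights-on: ZT 0 = lights-on,
ZT 12 = lights-off under a 12/12 h light/dark cycle.  All analyses use
half-open bins ``[start, start + width)`` and delimit analysis days at ZT 0,
so the active phase ZT 12-24 lies within a single analysis day.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "DataError",
    "FormatError",
    "InsufficientDataError",
    "QualityError",
    "LightSchedule",
    "PhaseWindow",
    "REST_PHASE",
    "ACTIVE_PHASE",
    "FULL_DAY",
    "ActivityRecording",
    "MotorScores",
    "to_zt",
    "read_activity_csv",
    "write_activity_csv",
    "write_results",
]


class ConfigurationError(ValueError):
    """Invalid analysis configuration (schedule, windows, parameters)."""


class DataError(ValueError):
    """Input data violate a type invariant (e.g. negative counts)."""


class FormatError(ValueError):
    """Malformed input file (non-uniform bins, missing columns...)."""


class InsufficientDataError(ValueError):
    """Recording too short for the requested analysis."""


class QualityError(ValueError):
    """Data quality below the configured acceptability threshold."""


@dataclass(frozen=True)
class LightSchedule:
    """Lighting schedule of the recording chamber.

    Parameters
    ----------
    lights_on : datetime.time
        Clock time at which lights turn on (ZT 0).
    photoperiod_h : float
        Hours of light per day; 12 for a 12/12 h LD cycle.
    """

    lights_on: _dt.time = _dt.time(6, 0)
    photoperiod_h: float = 12.0

    def __post_init__(self) -> None:
        if not (0 < self.photoperiod_h < 24):
            raise ConfigurationError(
                f"photoperiod_h must lie in (0, 24), got {self.photoperiod_h}"
            )


def to_zt(clock_time: _dt.time | _dt.datetime, schedule: LightSchedule) -> float:
    """Convert a clock time to zeitgeber time in hours.

    ZT 0 is lights-on; the mapping is periodic with period 24 h, so
    ``to_zt(t + 24h) == to_zt(t)``.
    """
    if not isinstance(schedule, LightSchedule):
        raise ConfigurationError("schedule must be a LightSchedule")
    if isinstance(clock_time, _dt.datetime):
        clock_time = clock_time.time()
    hours = clock_time.hour + clock_time.minute / 60 + clock_time.second / 3600
    on = schedule.lights_on
    on_hours = on.hour + on.minute / 60 + on.second / 3600
    return (hours - on_hours) % 24.0


@dataclass(frozen=True)
class PhaseWindow:
    """Half-open window ``[start_zt, end_zt)`` of the zeitgeber day."""

    start_zt: float
    end_zt: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start_zt < 24):
            raise ConfigurationError("start_zt must lie in [0, 24)")
        if not (0 < self.length_h <= 24):
            raise ConfigurationError("window length must lie in (0, 24] h")

    @property
    def length_h(self) -> float:
        return (self.end_zt - self.start_zt) % 24 or 24.0

    def contains(self, zt: float | np.ndarray) -> np.ndarray | bool:
        """Whether ZT hour(s) fall inside the (possibly wrapping) window."""
        zt = np.asarray(zt) % 24.0
        start, end = self.start_zt, self.end_zt % 24
        if self.length_h == 24.0:
            return np.ones_like(zt, dtype=bool) if zt.ndim else True
        if start < end:
            out = (zt >= start) & (zt < end)
        else:  # wraps midnight (ZT 0)
            out = (zt >= start) | (zt < end)
        return out if zt.ndim else bool(out)


REST_PHASE = PhaseWindow(0, 12, "rest")
ACTIVE_PHASE = PhaseWindow(12, 24, "active")
FULL_DAY = PhaseWindow(0, 24, "24h")


@dataclass
class ActivityRecording:
    """Evenly binned locomotor counts with light-schedule metadata.

    ``counts`` holds one non-negative integer per ``bin_minutes``-wide bin,
    spanning ``n_days`` complete days starting at ZT ``start_zt``.
    """

    animal_id: str
    counts: np.ndarray
    bin_minutes: int = 3
    start_zt: float = 0.0
    schedule: LightSchedule = field(default_factory=LightSchedule)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise DataError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise DataError("counts must be non-negative")
        if 60 % self.bin_minutes:
            raise DataError(f"bin_minutes ({self.bin_minutes}) must divide 60")
        if self.counts.size == 0 or self.counts.size % self.bins_per_day:
            raise DataError(
                f"counts length {self.counts.size} is not a whole number of "
                f"days ({self.bins_per_day} bins/day)"
            )

    @property
    def bins_per_hour(self) -> int:
        return 60 // self.bin_minutes

    @property
    def bins_per_day(self) -> int:
        return 24 * self.bins_per_hour

    @property
    def n_days(self) -> int:
        return self.counts.size // self.bins_per_day

    def zt_of_bin(self, index: int | np.ndarray) -> np.ndarray | float:
        """ZT hour of the start of bin ``index``."""
        return (self.start_zt + np.asarray(index) * self.bin_minutes / 60) % 24.0

    @property
    def bin_zt(self) -> np.ndarray:
        return self.zt_of_bin(np.arange(self.counts.size))

    def last_days(self, n_days: int) -> "ActivityRecording":
        """The last ``n_days`` complete days of the recording."""
        if n_days > self.n_days:
            raise InsufficientDataError(
                f"recording has {self.n_days} days, {n_days} requested"
            )
        return ActivityRecording(
            self.animal_id,
            self.counts[-n_days * self.bins_per_day :],
            self.bin_minutes,
            self.start_zt,
            self.schedule,
        )


@dataclass(frozen=True)
class MotorScores:
    """Per-animal motor test scores, already averaged over the five trials."""

    animal_id: str
    latency_to_fall_s: float
    beam_errors: float
    per_beam_errors: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        vals = [self.latency_to_fall_s, self.beam_errors]
        if self.per_beam_errors is not None:
            vals += list(self.per_beam_errors)
        if any(v < 0 for v in vals):
            raise DataError("motor scores must be non-negative")


# ---------------------------------------------------------------------------
# Tabular I/O


def read_activity_csv(
    path: str | Path,
    schedule: LightSchedule | None = None,
    *,
    fill_missing: bool = False,
) -> ActivityRecording:
    """Read an activity recording from CSV.

    Expected columns: ``zt_hours`` (decimal ZT hours since recording start,
    uniformly spaced) and ``counts``; optional ``animal_id``.  Missing bins
    are rejected by default; with ``fill_missing=True`` they are zero-filled
    and a warning is logged.
    """
    import logging

    df = pd.read_csv(path)
    for col in ("zt_hours", "counts"):
        if col not in df.columns:
            raise FormatError(f"column {col!r} missing from {path}")
    if np.any(df["counts"].to_numpy() < 0):
        raise DataError(f"negative counts in {path}")
    t = df["zt_hours"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least two bins")
    steps = np.diff(t)
    step = np.min(steps)
    if step <= 0:
        raise FormatError(f"{path}: timestamps must be strictly increasing")
    bad = np.nonzero(~np.isclose(steps, step, rtol=0, atol=1e-9))[0]
    if bad.size:
        missing_at = t[bad[0]] + step
        if not fill_missing:
            raise FormatError(
                f"{path}: non-uniform bins; first missing bin at "
                f"{missing_at:.6g} h from start"
            )
        logging.getLogger(__name__).warning(
            "%s: zero-filling missing bins (first at %.6g h)", path, missing_at
        )
        full_t = np.round((t - t[0]) / step).astype(int)
        counts = np.zeros(full_t[-1] + 1, dtype=df["counts"].dtype)
        counts[full_t] = df["counts"].to_numpy()
    else:
        counts = df["counts"].to_numpy()
    bin_minutes = int(round(step * 60))
    if not np.isclose(step * 60, bin_minutes):
        raise FormatError(f"{path}: bin width {step * 60:.6g} min is not whole minutes")
    animal = str(df["animal_id"].iloc[0]) if "animal_id" in df.columns else Path(path).stem
    return ActivityRecording(
        animal_id=animal,
        counts=counts,
        bin_minutes=bin_minutes,
        start_zt=float(t[0] % 24.0),
        schedule=schedule or LightSchedule(),
    )


def write_activity_csv(rec: ActivityRecording, path: str | Path) -> None:
    """Write an :class:`ActivityRecording` in the format ``read_activity_csv`` expects."""
    t = rec.start_zt + np.arange(rec.counts.size) * rec.bin_minutes / 60
    pd.DataFrame(
        {"zt_hours": t, "counts": rec.counts, "animal_id": rec.animal_id}
    ).to_csv(path, index=False)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    display_decimals: int = 3,
    manifest: dict | None = None,
) -> list[Path]:
    """Write result tables as CSV with deterministic column order.

    Each table is written at full precision plus a display-rounded copy
    (``<name>_display.csv``).  An optional JSON run manifest is written
    alongside.  Writing the same tables twice yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        df = tables[name]
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
        pdisp = out_dir / f"{name}_display.csv"
        df.round(display_decimals).to_csv(pdisp, index=False)
        written.append(pdisp)
    if manifest is not None:
        mp = out_dir / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        written.append(mp)
    return written
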