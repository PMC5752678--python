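import numpy as np
import pytest

from chronofeed.core import ActivityRecording, LightSchedule


@pytest.fixture
def schedule() -> LightSchedule:
    return LightSchedule()


def square_wave_recording(
    n_days: int = 10,
    bin_minutes: int = 3,
    night_level: int = 100,
    day_level: int = 0,
    onset_offsets_min: list[float] | None = None,
    animal_id: str = "square",
) -> ActivityRecording:
    """Noiseless square-wave activity: day_level during ZT 0-12 and
    night_level during ZT 12-24, with optional per-day onset shifts."""
    bpd = 24 * 60 // bin_minutes
    counts = np.full(n_days * bpd, day_level, dtype=int)
    offsets = onset_offsets_min or [0.0] * n_days
    for d in range(n_days):
        onset_bin = d * bpd + int(round((12 * 60 + offsets[d]) / bin_minutes))
        night_end = d * bpd + bpd
        counts[onset_bin:night_end] = night_level
    return ActivityRecording(animal_id, counts, bin_minutes=bin_minutes)


@pytest.fixture
def square_recording() -> ActivityRecording:
    return square_wave_recording()
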