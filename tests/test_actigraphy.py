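import numpy as np
import pytest

from chronofeed.actigraphy import (
    average_waveform,
    bout_summary,
    chi_square_periodogram,
    detect_bouts,
    estimate_onsets,
    mean_activity_per_hour,
)
from chronofeed.core import ACTIVE_PHASE, REST_PHASE, ActivityRecording, InsufficientDataError
from chronofeed.simulate import ActivitySimParams, simulate_activity

from conftest import square_wave_recording


def naive_periodogram_qp(x, period_bins):
    """Independent fold-and-variance oracle, written as plainly as possible."""
    x = [float(v) for v in x]
    k = len(x) // period_bins
    used = x[: k * period_bins]
    cols = [[used[r * period_bins + c] for r in range(k)] for c in range(period_bins)]
    grand = sum(used) / len(used)
    col_means = [sum(c) / len(c) for c in cols]
    ss_between = k * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((v - grand) ** 2 for v in used)
    return len(used) * ss_between / ss_total


class TestPeriodogram:
    def test_matches_naive_oracle_on_toy_series(self):
        rng = np.random.default_rng(42)
        # 3 days of 6-min bins keeps the brute-force python oracle fast
        counts = rng.poisson(5 * (1 + 0.8 * np.sin(2 * np.pi * np.arange(720) / 240)))
        rec = ActivityRecording("toy", np.abs(counts), bin_minutes=6)
        res = chi_square_periodogram(rec, period_range_h=(20, 28))
        for i, p_h in enumerate(res.periods_h):
            expected = naive_periodogram_qp(rec.counts, int(round(p_h * 10)))
            assert res.qp[i] == pytest.approx(expected, rel=1e-9)

    def test_noiseless_24h_signal_peaks_exactly_at_24(self, square_recording):
        res = chi_square_periodogram(square_recording)
        assert res.peak_period_h == 24.0
        assert not res.below_threshold

    def test_power_invariant_to_count_scaling(self):
        rec = simulate_activity(ActivitySimParams(rel_amplitude=0.8, seed=3), n_days=10)
        scaled = ActivityRecording(rec.animal_id, rec.counts * 7, rec.bin_minutes)
        r1 = chi_square_periodogram(rec)
        r2 = chi_square_periodogram(scaled)
        assert r2.power_pct_v == pytest.approx(r1.power_pct_v, rel=1e-12)

    def test_significance_line_increases_with_period_bins(self, square_recording):
        res = chi_square_periodogram(square_recording)
        assert np.all(np.diff(res.sig_line) > 0)

    def test_short_recording_rejected(self):
        rec = ActivityRecording("short", np.ones(480, dtype=int), bin_minutes=3)
        with pytest.raises(InsufficientDataError):
            chi_square_periodogram(rec)

    def test_power_monotone_in_amplitude(self):
        amps = np.linspace(0.05, 0.95, 10)
        powers = [
            chi_square_periodogram(
                simulate_activity(ActivitySimParams(rel_amplitude=a, seed=11), n_days=10)
            ).power_pct_v
            for a in amps
        ]
        assert np.all(np.diff(powers) > 0) or _spearman(amps, powers) > 0.9


def _spearman(x, y):
    from scipy.stats import spearmanr

    return spearmanr(x, y).statistic


def brute_force_bouts(active, max_gap_bins):
    """Oracle: enumerate active indices and merge greedily by definition."""
    idx = [i for i, a in enumerate(active) if a]
    bouts = []
    for i in idx:
        if bouts and i - bouts[-1][-1] - 1 <= max_gap_bins:
            bouts[-1].append(i)
        else:
            bouts.append([i])
    return [(b[0], b[-1] + 1) for b in bouts]


class TestBouts:
    def test_all_zero_recording_has_no_bouts(self):
        rec = ActivityRecording("z", np.zeros(480, dtype=int), bin_minutes=3)
        assert detect_bouts(rec) == []

    def test_single_block_is_one_bout_with_its_duration(self):
        counts = np.zeros(480, dtype=int)
        counts[100:110] = 50  # 30 min at 3-min bins
        rec = ActivityRecording("b", counts, bin_minutes=3)
        bouts = detect_bouts(rec)
        assert len(bouts) == 1
        assert bouts[0].duration_min == 30
        assert bouts[0].total_counts == 500

    @pytest.mark.parametrize("gap_min", range(3, 46, 3))
    def test_gap_merging_agrees_with_brute_force(self, gap_min):
        counts = np.zeros(480, dtype=int)
        counts[50:60] = 20
        gap_bins = gap_min // 3
        counts[60 + gap_bins : 70 + gap_bins] = 20
        rec = ActivityRecording("g", counts, bin_minutes=3)
        bouts = detect_bouts(rec)
        expected = brute_force_bouts(counts >= 9, max_gap_bins=7)
        assert [(b.start, b.end) for b in bouts] == expected
        assert len(bouts) == (1 if gap_min <= 21 else 2)

    def test_random_series_agree_with_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            counts = rng.poisson(6, size=480)
            rec = ActivityRecording("r", counts, bin_minutes=3)
            got = [(b.start, b.end) for b in detect_bouts(rec)]
            assert got == brute_force_bouts(counts >= 9, max_gap_bins=7)

    def test_invariant_to_appended_quiet_days(self):
        rec = simulate_activity(ActivitySimParams(seed=5), n_days=3)
        padded = ActivityRecording(
            "p", np.concatenate([rec.counts, np.zeros(480, dtype=int)]), 3
        )
        assert [(b.start, b.end) for b in detect_bouts(rec)] == [
            (b.start, b.end) for b in detect_bouts(padded)
        ]

    def test_bout_straddling_lights_off_counts_in_rest_phase(self):
        counts = np.zeros(480, dtype=int)
        # active from ZT 11.9 to ZT 12.5: starts in the rest phase
        counts[238:250] = 50
        rec = ActivityRecording("s", counts, bin_minutes=3)
        summary = bout_summary(detect_bouts(rec), rec)
        assert summary["rest"]["bouts_per_day"] == 1.0
        assert summary["active"]["bouts_per_day"] == 0.0
        assert summary["24h"]["bouts_per_day"] == 1.0

    def test_bout_rate_rises_with_fragmentation(self):
        frags = np.linspace(0.0, 0.15, 8)
        rates = []
        for f in frags:
            per_seed = [
                len(detect_bouts(simulate_activity(
                    ActivitySimParams(mesor_rate=6, rel_amplitude=0.8, fragmentation_p=f, seed=s),
                    n_days=10,
                )))
                for s in range(3)
            ]
            rates.append(np.mean(per_seed))
        assert _spearman(frags, rates) > 0.8


class TestOnsets:
    def test_exact_onsets_give_zero_variability(self, square_recording):
        res = estimate_onsets(square_recording)
        assert res.variability_min == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.onset_zt, 12.0)

    def test_balanced_alternating_shifts_give_their_magnitude(self):
        # +9/-9 min pattern with zero covariance against day number, so the
        # fitted line is flat at ZT 12 and every deviation is exactly 9 min
        pattern = [9, -9, -9, 9, 9, -9, -9, 9]
        rec = square_wave_recording(n_days=8, onset_offsets_min=pattern)
        res = estimate_onsets(rec)
        assert abs(res.slope_h_per_day) < 1e-9
        assert res.variability_min == pytest.approx(9.0, abs=1e-6)

    def test_constant_phase_shift_leaves_variability_unchanged(self):
        pattern = [9, -9, -9, 9, 9, -9, -9, 9]
        base = square_wave_recording(n_days=8, onset_offsets_min=pattern)
        shifted = square_wave_recording(
            n_days=8, onset_offsets_min=[p + 30 for p in pattern]
        )
        assert estimate_onsets(shifted).variability_min == pytest.approx(
            estimate_onsets(base).variability_min, abs=1e-6
        )

    def test_linear_drift_absorbed_by_regression(self):
        drift = [6 * d for d in range(8)]  # steady 6 min/day phase delay
        rec = square_wave_recording(n_days=8, onset_offsets_min=drift)
        res = estimate_onsets(rec)
        assert res.variability_min == pytest.approx(0.0, abs=1e-6)
        assert res.slope_h_per_day == pytest.approx(0.1, abs=1e-6)

    def test_too_few_days_rejected(self):
        rec = square_wave_recording(n_days=5)
        with pytest.raises(InsufficientDataError):
            estimate_onsets(rec)


class TestWaveformAndTotals:
    def test_constant_signal_hourly_means(self):
        rec = ActivityRecording("c", np.full(4800, 5), bin_minutes=3)
        wf = average_waveform(rec)
        np.testing.assert_allclose(wf.hourly_mean, 5 * 20)

    def test_waveform_conserves_daily_total(self):
        rec = simulate_activity(ActivitySimParams(seed=9), n_days=10)
        wf = average_waveform(rec)
        assert wf.hourly_mean.sum() == pytest.approx(rec.counts.sum() / rec.n_days)

    def test_identical_animals_have_zero_sem(self):
        rec = simulate_activity(ActivitySimParams(seed=1), n_days=10)
        wf = average_waveform([rec] * 8)
        assert wf.n_animals == 8
        np.testing.assert_allclose(wf.hourly_sem, 0.0, atol=1e-10)

    def test_mean_activity_per_hour_arithmetic(self):
        rec = ActivityRecording("m", np.full(4800, 5), bin_minutes=3)
        assert mean_activity_per_hour(rec) == pytest.approx(100.0)
        zero = ActivityRecording("z", np.zeros(480, dtype=int), bin_minutes=3)
        assert mean_activity_per_hour(zero) == 0.0

    def test_windowed_total_matches_hand_sum(self, square_recording):
        rec = square_recording
        zt = rec.bin_zt
        hand = rec.counts[(zt >= 0) & (zt < 12)].sum() / (rec.n_days * 12)
        assert mean_activity_per_hour(rec, REST_PHASE) == pytest.approx(hand)
        hand_active = rec.counts[(zt >= 12)].sum() / (rec.n_days * 12)
        assert mean_activity_per_hour(rec, ACTIVE_PHASE) == pytest.approx(hand_active)
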