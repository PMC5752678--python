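"""Synthetic cohort generator.

Generates activity, immobility, RR, motor-score and expression data with the
statistical structure the downstream analyses assume: plateau-like nocturnal
activity with jittered onsets and optional fragmentation, two-state
sleep/wake dynamics with a forced morning awakening, sinusoidally modulated
heart rate with additive RR noise and injected artifacts, and overdispersed
panel counts with stable housekeeping genes.  Identical seeds and parameters
produce bit-identical outputs; one master seed expands into independent
per-animal substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .actigraphy import chi_square_periodogram
from .core import ActivityRecording, LightSchedule, MotorScores
from .expression import HOUSEKEEPING_GENES, ExpressionMatrix
from .sleep import SECONDS_PER_DAY, ImmobilityTrace
from .telemetry import RRSeries

__all__ = [
    "ActivitySimParams",
    "SleepSimParams",
    "RRSimParams",
    "ExpressionSimParams",
    "GroupSpec",
    "CohortConfig",
    "Cohort",
    "simulate_activity",
    "simulate_immobility",
    "simulate_rr",
    "simulate_expression",
    "simulate_cohort",
    "default_study_config",
    "derive_seed",
]


def derive_seed(master: int, *key: int) -> int:
    """Deterministic per-stream seed below 2**31 from a master seed and key."""
    ss = np.random.SeedSequence([int(master), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Activity


@dataclass(frozen=True)
class ActivitySimParams:
    """Parameters of the locomotor-activity generator.

    The per-bin Poisson rate is ``mesor_rate * (1 + rel_amplitude * s)``
    where ``s`` is a smoothed square wave (logistic edges, ~30-min
    transition) that is +1 in the active phase and -1 in the rest phase,
    with the nightly onset jittered by N(0, onset_jitter_sd_min).  The rest
    phase rate is further multiplied by ``day_leak``, and during the active
    phase a suppression state toggling with per-bin probability
    ``fragmentation_p`` multiplies the rate by ``suppressed_factor``.
    """

    mesor_rate: float = 4.0  # counts per bin at the midline
    rel_amplitude: float = 0.6
    period_h: float = 24.0
    onset_jitter_sd_min: float = 20.0
    fragmentation_p: float = 0.0
    day_leak: float = 1.0
    suppressed_factor: float = 0.1
    onset_protect_h: float = 2.0  # consolidated dusk bout: no suppression here
    transition_h: float = 0.5  # logistic edge 10-90% width ~ 2.2 * scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mesor_rate < 0 or not (0 <= self.rel_amplitude <= 1):
            raise ValueError("rates must be >= 0 and rel_amplitude in [0, 1]")
        if not (0 <= self.fragmentation_p <= 1):
            raise ValueError("fragmentation_p must lie in [0, 1]")
        if not (0 <= self.day_leak <= 1):
            raise ValueError("day_leak must lie in [0, 1]")


def _smoothed_square(u: np.ndarray, onset: float, offset: float, scale: float) -> np.ndarray:
    """Smoothed square wave in [-1, 1]: +1 on [onset, offset), logistic edges."""
    rise = 1.0 / (1.0 + np.exp(-(u - onset) / scale))
    fall = 1.0 / (1.0 + np.exp(-(offset - u) / scale))
    return 2.0 * rise * fall - 1.0


def simulate_activity(
    params: ActivitySimParams,
    n_days: int = 10,
    bin_minutes: int = 3,
    animal_id: str = "sim",
    schedule: LightSchedule | None = None,
) -> ActivityRecording:
    """Simulate a binned cage-activity recording (see class docstring)."""
    rng = np.random.default_rng(params.seed)
    bpd = 24 * 60 // bin_minutes
    n_bins = n_days * bpd
    t_h = np.arange(n_bins) * bin_minutes / 60.0
    u = t_h % params.period_h
    half = params.period_h / 2.0
    scale = params.transition_h / 2.2
    day = (t_h // params.period_h).astype(int)
    jitter_h = rng.normal(0.0, params.onset_jitter_sd_min / 60.0, size=int(day.max()) + 1)
    s = _smoothed_square(u, half + jitter_h[day], params.period_h, scale)
    rate = params.mesor_rate * (1.0 + params.rel_amplitude * s)
    rest = s < 0
    rate = np.where(rest, rate * params.day_leak, rate)
    if params.fragmentation_p > 0:
        # suppression toggles only within the active phase; it resets at each
        # activity onset and the consolidated dusk bout (onset_protect_h) is
        # exempt, so fragmentation never masks the onset itself
        toggles = rng.random(n_bins) < params.fragmentation_p
        state = np.ones(n_bins)
        suppressed = False
        run_active = 0  # consecutive active-phase bins since onset
        protect_bins = int(round(params.onset_protect_h * 60 / bin_minutes))
        for i in range(n_bins):
            if rest[i]:
                suppressed = False
                run_active = 0
                continue
            run_active += 1
            if run_active <= protect_bins:
                continue
            if toggles[i]:
                suppressed = not suppressed
            if suppressed:
                state[i] = params.suppressed_factor
        rate = rate * state
    counts = rng.poisson(np.clip(rate, 0.0, None))
    return ActivityRecording(
        animal_id=animal_id,
        counts=counts,
        bin_minutes=bin_minutes,
        start_zt=0.0,
        schedule=schedule or LightSchedule(),
    )


# ---------------------------------------------------------------------------
# Immobility / sleep


@dataclass(frozen=True)
class SleepSimParams:
    """Parameters of the two-state sleep/wake generator.

    Sleep and wake alternate as a Markov chain at 1 Hz; the per-second exit
    probability from sleep is ``1 / (mean_episode_min * 60)`` and the entry
    probability is set so the stationary sleep occupancy equals
    ``p_sleep_rest`` before the (jittered) wake onset and ``p_sleep_active``
    after it.  At the jittered wake onset the animal is forced awake, which
    emulates the morning sleep-to-wake transition that the sleep-offset
    estimator measures.  During sleep the emitted immobile fraction is
    >= 0.95; during wake it is below 0.95.
    """

    p_sleep_rest: float = 0.70
    p_sleep_active: float = 0.25
    mean_episode_min: float = 30.0
    wake_onset_zt: float = 12.0
    wake_onset_jitter_min: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_sleep_rest, self.p_sleep_active):
            if not (0 <= p <= 1):
                raise ValueError("sleep probabilities must lie in [0, 1]")
        if self.mean_episode_min <= 40 / 60:
            raise ValueError("mean_episode_min must exceed the 40-s scoring rule")


def simulate_immobility(
    params: SleepSimParams,
    n_days: int = 5,
    animal_id: str = "sim",
    schedule: LightSchedule | None = None,
) -> ImmobilityTrace:
    """Simulate a per-second immobile-fraction trace (see class docstring).

    Also stores the true per-second sleep state on the returned trace as
    ``trace.true_state`` for generator-recovery tests.
    """
    rng = np.random.default_rng(params.seed)
    n_sec = n_days * SECONDS_PER_DAY
    mu = 1.0 / (params.mean_episode_min * 60.0)  # sleep exit prob / s

    def entry_prob(p_occ: float) -> float:
        if p_occ <= 0:
            return 0.0
        if p_occ >= 1:
            return 1.0
        return min(mu * p_occ / (1.0 - p_occ), 1.0)

    state = np.zeros(n_sec, dtype=np.int8)
    asleep = params.p_sleep_rest > 0.5  # start the night pre-onset in the likelier state
    t = 0
    onsets = params.wake_onset_zt + rng.normal(
        0.0, params.wake_onset_jitter_min / 60.0, size=n_days
    )
    # piecewise-constant segments: [day start, jittered onset) rest dynamics,
    # [onset, next day) active dynamics; state forced awake at each onset
    boundaries: list[tuple[int, int, float, bool]] = []
    for d in range(n_days):
        day0 = d * SECONDS_PER_DAY
        on = day0 + int(round(np.clip(onsets[d], 0.0, 24.0) * 3600))
        boundaries.append((day0, on, params.p_sleep_rest, False))
        boundaries.append((on, (d + 1) * SECONDS_PER_DAY, params.p_sleep_active, True))
    for seg_start, seg_end, p_occ, force_wake in boundaries:
        if force_wake:
            asleep = False
        lam = entry_prob(p_occ)
        t = seg_start
        while t < seg_end:
            prob = mu if asleep else lam
            if prob <= 0:
                dur = seg_end - t  # absorbing until the segment ends
            else:
                dur = int(rng.geometric(prob))
            end = min(t + dur, seg_end)
            if asleep:
                state[t:end] = 1
            if end < seg_end:
                asleep = not asleep
            t = end
    frac = np.where(
        state == 1,
        rng.uniform(0.95, 1.0, size=n_sec),
        rng.uniform(0.0, 0.90, size=n_sec),
    )
    trace = ImmobilityTrace(
        animal_id=animal_id,
        immobile_fraction=frac,
        start_zt=0.0,
        schedule=schedule or LightSchedule(),
    )
    trace.true_state = state  # ground truth for recovery tests
    return trace


# ---------------------------------------------------------------------------
# RR intervals


@dataclass(frozen=True)
class RRSimParams:
    """Parameters of the telemetry RR generator.

    Instantaneous heart rate follows
    ``HR(t) = mesor + amplitude * cos(2*pi*(ZT - acrophase)/24)`` (bpm);
    each beat interval is ``60000 / HR`` plus zero-mean Gaussian noise of SD
    ``rr_noise_sd_ms`` (the target SDNN), and a fraction ``artifact_rate``
    of beats is replaced by 3-10x outliers.
    """

    hr_mesor_bpm: float = 410.0
    hr_amplitude_bpm: float = 80.0
    acrophase_zt: float = 18.0
    rr_noise_sd_ms: float = 15.0
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hr_mesor_bpm - self.hr_amplitude_bpm <= 0:
            raise ValueError("hr_mesor_bpm - hr_amplitude_bpm must be positive")
        if self.rr_noise_sd_ms < 0:
            raise ValueError("rr_noise_sd_ms must be >= 0")
        if not (0 <= self.artifact_rate < 0.1):
            raise ValueError("artifact_rate must lie in [0, 0.1)")


def simulate_rr(
    params: RRSimParams,
    n_days: int = 1,
    animal_id: str = "sim",
    schedule: LightSchedule | None = None,
) -> RRSeries:
    """Simulate a telemetry RR series (see class docstring).

    Beat times are laid out on the mean-rate grid before evaluating the slow
    circadian modulation (the phase error this introduces is far below the
    24-h modulation timescale), then accumulated from the realized
    intervals.
    """
    rng = np.random.default_rng(params.seed)
    total_s = n_days * 86400.0
    mean_rr_s = 60.0 / params.hr_mesor_bpm
    n_beats = int(total_s / mean_rr_s)
    t_approx = np.arange(n_beats) * mean_rr_s
    zt = (t_approx / 3600.0) % 24.0
    hr = params.hr_mesor_bpm + params.hr_amplitude_bpm * np.cos(
        2 * np.pi * (zt - params.acrophase_zt) / 24.0
    )
    rr = 60000.0 / hr
    if params.rr_noise_sd_ms > 0:
        rr = rr + rng.normal(0.0, params.rr_noise_sd_ms, size=n_beats)
    rr = np.clip(rr, 1.0, None)
    if params.artifact_rate > 0:
        hit = rng.random(n_beats) < params.artifact_rate
        rr = np.where(hit, rr * rng.uniform(3.0, 10.0, size=n_beats), rr)
    t_s = np.cumsum(rr) / 1000.0
    keep = t_s <= total_s
    return RRSeries(
        animal_id=animal_id,
        rr_ms=rr[keep],
        t_s=t_s[keep],
        start_zt=0.0,
        schedule=schedule or LightSchedule(),
    )


# ---------------------------------------------------------------------------
# Expression


@dataclass(frozen=True)
class ExpressionSimParams:
    """Parameters of the panel-count generator.

    Counts are negative-binomial around ``base_means * library factor``,
    with the treated group's means shifted by per-gene ``group_log2fc``.
    Housekeeping and positive-control genes always have zero fold change;
    positive-control counts share the per-sample library factor so that
    positive normalization can recover it.
    """

    n_genes: int = 100
    housekeeping_ids: tuple[str, ...] = HOUSEKEEPING_GENES
    n_positive: int = 6
    base_means: np.ndarray | None = None  # per gene; derived if None
    dispersion: float = 0.01
    sample_scale_sd: float = 0.15  # SD of log library factors
    group_log2fc: dict[str, float] = field(default_factory=dict)
    n_per_group: int = 8
    seed: int = 0

    def gene_table(self) -> pd.DataFrame:
        """Deterministic panel layout: ids, classes and base means."""
        n_hk = len(self.housekeeping_ids)
        n_endo = self.n_genes - n_hk - self.n_positive
        if n_endo <= 0:
            raise ValueError("n_genes too small for the control probes")
        ids = (
            [f"G{i + 1:03d}" for i in range(n_endo)]
            + list(self.housekeeping_ids)
            + [f"POS_{chr(65 + i)}" for i in range(self.n_positive)]
        )
        classes = ["endogenous"] * n_endo + ["housekeeping"] * n_hk + ["positive"] * self.n_positive
        if self.base_means is not None:
            base = np.asarray(self.base_means, dtype=float)
            if base.size != self.n_genes:
                raise ValueError("base_means length must equal n_genes")
        else:
            # geometric ladder over a NanoString-like dynamic range
            endo = np.geomspace(150.0, 8000.0, n_endo)
            hk = np.geomspace(800.0, 2500.0, n_hk)
            pos = np.geomspace(20000.0, 100.0, self.n_positive)  # titration series
            base = np.concatenate([endo, hk, pos])
        if np.any(base <= 0):
            raise ValueError("base_means must be positive")
        lfc = np.array([self.group_log2fc.get(g, 0.0) for g in ids])
        ctrl = np.array([c != "endogenous" for c in classes])
        if np.any(lfc[ctrl] != 0):
            raise ValueError("control/housekeeping genes must have zero log2fc")
        return pd.DataFrame({"gene_id": ids, "gene_class": classes, "base_mean": base, "log2fc": lfc})


def simulate_expression(
    params: ExpressionSimParams,
    group_a: str = "ad_lib",
    group_b: str = "TRF",
) -> ExpressionMatrix:
    """Simulate a two-group panel count matrix (see class docstring).

    The realized per-sample library factors are stored on the returned
    matrix as ``matrix.true_library_factors`` for recovery tests.
    """
    rng = np.random.default_rng(params.seed)
    table = params.gene_table()
    n = params.n_per_group
    samples = [f"{group_a}_{i + 1}" for i in range(n)] + [f"{group_b}_{i + 1}" for i in range(n)]
    groups = pd.Series([group_a] * n + [group_b] * n, index=samples)
    sf = np.exp(rng.normal(0.0, params.sample_scale_sd, size=2 * n))
    is_b = np.array([g == group_b for g in groups])
    mu = (
        table["base_mean"].to_numpy()[:, None]
        * sf[None, :]
        * np.power(2.0, table["log2fc"].to_numpy()[:, None] * is_b[None, :])
    )
    if params.dispersion > 0:
        size = 1.0 / params.dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)
    mat = ExpressionMatrix(
        counts=pd.DataFrame(counts.astype(float), index=pd.Index(table["gene_id"], name="gene_id"), columns=samples),
        gene_class=pd.Series(table["gene_class"].to_numpy(), index=pd.Index(table["gene_id"], name="gene_id")),
        sample_group=groups,
    )
    mat.true_library_factors = pd.Series(sf, index=samples)
    return mat


# ---------------------------------------------------------------------------
# Cohort


@dataclass(frozen=True)
class GroupSpec:
    """Per-group generator settings for a simulated cohort."""

    name: str
    n_animals: int = 8
    n_telemetry: int = 7
    activity: ActivitySimParams = field(default_factory=ActivitySimParams)
    sleep: SleepSimParams = field(default_factory=SleepSimParams)
    rr: RRSimParams = field(default_factory=RRSimParams)
    # linear coupling of motor scores to the realized rhythm power (%V)
    latency_base_s: float = 20.0
    latency_per_power: float = 8.0
    latency_noise_sd: float = 70.0
    errors_base: float = 12.0
    errors_per_power: float = -0.15
    errors_noise_sd: float = 1.2
    beam_shares: tuple[float, float, float, float] = (0.12, 0.18, 0.24, 0.46)
    # between-animal biological variability (0 disables individualization)
    heterogeneity_cv: float = 0.10


def _individualize(spec: GroupSpec, rng: np.random.Generator) -> GroupSpec:
    """Draw one animal's parameters around the group's nominal values.

    Rates and scales vary log-normally with CV ``heterogeneity_cv``;
    probabilities and phases get small additive jitter on matching scales.
    """
    cv = spec.heterogeneity_cv
    if cv <= 0:
        return spec

    def ln() -> float:
        return float(np.exp(rng.normal(0.0, cv)))

    act = replace(
        spec.activity,
        mesor_rate=spec.activity.mesor_rate * ln(),
        rel_amplitude=float(np.clip(spec.activity.rel_amplitude + rng.normal(0.0, 0.4 * cv), 0.0, 1.0)),
        onset_jitter_sd_min=spec.activity.onset_jitter_sd_min * ln(),
    )
    slp = replace(
        spec.sleep,
        p_sleep_rest=float(np.clip(spec.sleep.p_sleep_rest + rng.normal(0.0, 0.3 * cv), 0.0, 1.0)),
        p_sleep_active=float(np.clip(spec.sleep.p_sleep_active + rng.normal(0.0, 0.3 * cv), 0.0, 1.0)),
        mean_episode_min=spec.sleep.mean_episode_min * ln(),
        wake_onset_zt=spec.sleep.wake_onset_zt + float(rng.normal(0.0, 1.5 * cv)),
    )
    rr = replace(
        spec.rr,
        hr_mesor_bpm=spec.rr.hr_mesor_bpm + float(rng.normal(0.0, 120 * cv)),
        hr_amplitude_bpm=spec.rr.hr_amplitude_bpm * ln(),
        rr_noise_sd_ms=spec.rr.rr_noise_sd_ms * ln(),
    )
    return replace(spec, activity=act, sleep=slp, rr=rr)


@dataclass(frozen=True)
class CohortConfig:
    """Design of a simulated study cohort."""

    groups: tuple[GroupSpec, ...]
    expression: ExpressionSimParams = field(default_factory=ExpressionSimParams)
    activity_days: int = 10
    sleep_days: int = 5
    rr_days: int = 1
    seed: int = 0


@dataclass
class Cohort:
    """A fully simulated study bundle."""

    activity: dict[str, ActivityRecording]
    immobility: dict[str, ImmobilityTrace]
    rr: dict[str, RRSeries]
    motor: pd.DataFrame  # animal_id, group, latency, errors, per-beam errors
    expression: ExpressionMatrix
    group_of: dict[str, str]
    realized_power: dict[str, float]
    config: CohortConfig


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate a full cohort per the design (see module docstring).

    Motor scores are drawn with the configured linear coupling to each
    animal's *realized* rhythm power (computed by the package's own
    periodogram on the simulated activity), so correlation analyses can be
    exercised with a known coupling structure.
    """
    activity: dict[str, ActivityRecording] = {}
    immobility: dict[str, ImmobilityTrace] = {}
    rr: dict[str, RRSeries] = {}
    group_of: dict[str, str] = {}
    power: dict[str, float] = {}
    motor_rows = []
    for gi, spec in enumerate(config.groups):
        for ai in range(spec.n_animals):
            animal = f"{spec.name}_{ai + 1}"
            group_of[animal] = spec.name
            ind = _individualize(
                spec, np.random.default_rng(derive_seed(config.seed, gi, ai, 4))
            )
            act_p = replace(ind.activity, seed=derive_seed(config.seed, gi, ai, 0))
            slp_p = replace(ind.sleep, seed=derive_seed(config.seed, gi, ai, 1))
            activity[animal] = simulate_activity(
                act_p, n_days=config.activity_days, animal_id=animal
            )
            immobility[animal] = simulate_immobility(
                slp_p, n_days=config.sleep_days, animal_id=animal
            )
            if ai < spec.n_telemetry:
                rr_p = replace(ind.rr, seed=derive_seed(config.seed, gi, ai, 2))
                rr[animal] = simulate_rr(rr_p, n_days=config.rr_days, animal_id=animal)
            pv = chi_square_periodogram(activity[animal]).power_pct_v
            power[animal] = pv
            mrng = np.random.default_rng(derive_seed(config.seed, gi, ai, 3))
            latency = float(
                np.clip(
                    spec.latency_base_s
                    + spec.latency_per_power * pv
                    + mrng.normal(0.0, spec.latency_noise_sd),
                    0.0,
                    600.0,
                )
            )
            errors = float(
                np.clip(
                    spec.errors_base
                    + spec.errors_per_power * pv
                    + mrng.normal(0.0, spec.errors_noise_sd),
                    0.0,
                    None,
                )
            )
            shares = np.asarray(spec.beam_shares)
            per_beam = np.clip(
                errors * shares + mrng.normal(0.0, 0.15, size=4), 0.0, None
            )
            scores = MotorScores(animal, latency, errors, tuple(per_beam))
            motor_rows.append(
                {
                    "animal_id": animal,
                    "group": spec.name,
                    "latency_to_fall_s": scores.latency_to_fall_s,
                    "beam_errors": scores.beam_errors,
                    **{f"errors_beam{j + 1}": per_beam[j] for j in range(4)},
                }
            )
    expr = simulate_expression(
        replace(config.expression, seed=derive_seed(config.seed, 99)),
        group_a=config.groups[0].name,
        group_b=config.groups[-1].name,
    )
    return Cohort(
        activity=activity,
        immobility=immobility,
        rr=rr,
        motor=pd.DataFrame(motor_rows),
        expression=expr,
        group_of=group_of,
        realized_power=power,
        config=config,
    )


def default_study_config(seed: int = 0) -> CohortConfig:
    """Cohort design mirroring the study conditions.

    Two groups of 8 animals (7 with telemetry): an ad-lib control group with
    a dampened, fragmented, variable-onset rhythm, and a TRF-treated group
    with a higher-amplitude, better-consolidated rhythm, earlier and more
    precise awakening, and higher HRV and HR rhythm amplitude.
    """
    ad_lib = GroupSpec(
        name="ad_lib",
        activity=ActivitySimParams(
            mesor_rate=5.7,
            rel_amplitude=0.75,
            onset_jitter_sd_min=34.0,
            fragmentation_p=0.16,
            day_leak=0.9,
        ),
        sleep=SleepSimParams(
            p_sleep_rest=0.70,
            p_sleep_active=0.30,
            mean_episode_min=30.0,
            wake_onset_zt=12.6,
            wake_onset_jitter_min=47.0,
        ),
        rr=RRSimParams(
            hr_mesor_bpm=406.0,
            hr_amplitude_bpm=81.0,
            rr_noise_sd_ms=13.7,
            artifact_rate=0.02,
        ),
    )
    trf = GroupSpec(
        name="TRF",
        activity=ActivitySimParams(
            mesor_rate=12.5,
            rel_amplitude=0.9,
            onset_jitter_sd_min=20.0,
            fragmentation_p=0.05,
            day_leak=0.7,
        ),
        sleep=SleepSimParams(
            p_sleep_rest=0.70,
            p_sleep_active=0.25,
            mean_episode_min=30.0,
            wake_onset_zt=11.9,
            wake_onset_jitter_min=24.0,
        ),
        rr=RRSimParams(
            hr_mesor_bpm=424.0,
            hr_amplitude_bpm=98.0,
            rr_noise_sd_ms=17.0,
            artifact_rate=0.02,
        ),
    )
    # plant fold changes of the magnitude seen on striatal panels
    lfc = {
        "G001": 0.23,
        "G002": 0.31,
        "G003": 0.33,
        "G004": 0.17,
        "G005": -0.47,
        "G006": 0.24,
        "G007": -0.15,
        "G008": 0.21,
        "G009": 0.26,
        "G010": -0.16,
    }
    return CohortConfig(
        groups=(ad_lib, trf),
        expression=ExpressionSimParams(group_log2fc=lfc),
        seed=seed,
    )
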