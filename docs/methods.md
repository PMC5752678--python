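# Methods

This note documents the models, conventions and numerical choices behind
chronofeed, and what the synthetic-data tests do and do not establish about
real recordings.

## Time conventions

Zeitgeber time (ZT) is hours since lights-on; ZT 0 = lights-on, ZT 12 =
lights-off under 12/12 LD. All bins and windows are half-open,
[start, start + width), which keeps the ZT 0/24 boundary unambiguous.
Analysis days are delimited at ZT 0, so the active phase ZT 12–24 falls
inside a single analysis day and phase windows (rest = [0, 12), active =
[12, 24)) partition the day exactly. Readers reject records that violate
type invariants (negative counts, partial days, non-uniform bins) rather
than coercing them; missing bins can be zero-filled only by explicit opt-in,
with a logged warning. When a recording is longer than needed, analyses use
the last *n* complete days (default 10), matching the practice of analyzing
the days immediately before terminal assays.

## χ² periodogram and rhythm power

For each trial period of *P* whole bins (every integer bin count whose
period lies in 20–28 h; 3-min bins give 0.05-h resolution), the series is
folded into *K* = ⌊N/P⌋ complete cycles, discarding the trailing remainder,
and

  Q_P = N′ · SS_between-columns / SS_total,  N′ = K·P.

Under an i.i.d. null, Q_P ~ χ²(P − 1). Two deliberate choices:

- **Significance line.** The classical per-period line χ²₁₋α(P − 1) is not
  calibrated for the *peak* over a ~161-period grid: measured on rhythm-free
  Poisson series, the peak crosses the per-period α = 0.001 line in ~2.4% of
  series. The default line is therefore Bonferroni-corrected for the grid
  size (α/n_periods per period), which brings the family-wise false-peak
  rate to ≲0.1% (0/1000 measured) at the cost of lowering %V by under one
  percentage point at 10 days of 3-min bins. The per-period line remains
  available (`correct_for_periods=False`).
- **%V definition.** Commercial tools print "power (%V)" without a formula.
  Here power = 100 · (Q_peak − sig_peak)/N′, clamped at 0, which is
  scale-free (invariant to multiplying all counts by a constant) and 0 for
  non-significant records; `raw_power_pct_v` = 100 · Q_peak/N′ is also
  reported for cross-tool comparison. Because of the subtraction, absolute
  %V values are comparable across tools only approximately; group contrasts
  are unaffected.

## Bouts and onsets

A bin is active when counts ≥ 3 counts/min × bin width; active runs
separated by sub-threshold gaps of at most 21 min merge into one bout (a
gap of exactly 21 min merges; 24 min splits). The "3 counts/min" threshold
is read as a rate and converted to the bin width. Bouts are assigned to the
phase window containing their start bin, so a bout straddling lights-off
counts once, in the rest phase.

Daily activity onset is the time maximizing the correlation of the count
series with a step template (default 6 h quiet at −1 followed by 6 h active
at +1), searched within ZT 8–16; ties break to the earliest bin. This is a
standard actigraphy construction chosen because it is deterministic and
parameter-light; commercial onset detectors are proprietary and will not
agree bin-for-bin. Onset variability is the mean |deviation| from the
least-squares line over (day, onset) — the absolute reading is deliberate,
since the signed mean is ≈ 0 by construction of the fit — which makes the
metric invariant to constant phase shifts and free-running drift.

The estimator has a detection noise floor of roughly 9 min/day at the
default synthetic count levels (Poisson noise moving the template optimum),
so recovered variability tracks the half-normal expectation σ·√(2/π) of
planted nightly jitter σ to within ±25% for σ ≳ 15 min and overestimates
below that. Real recordings with higher counts or sharper onsets will have
a lower floor.

## Immobility-defined sleep

A second is immobile when the immobile area fraction is ≥ 0.95; maximal
immobile runs strictly longer than 40 s are sleep episodes (a 40.0-s run is
not an episode — the boundary is tested explicitly). Episodes are exported
to 1-min bins by a majority rule (≥ 30 s asleep; an "any-overlap" mode
exists) chosen to minimize discretization bias. Sleep totals and bout
structure are computed per sleep–wake cycle and averaged over the analyzed
cycles — by default cycles 3 and 4 of a ≥ 5-cycle recording, so animals are
past acclimation. Sleep bouts absorb wake gaps of ≤ 10 min (configurable);
this consolidation constant is a declared convention, not an inference of
any commercial tool's rule.

The awakening time of a cycle is the end of the last consolidated sleep run
(≥ 5 sleep minutes after absorbing wake gaps of ≤ 10 min) that starts in
the rest phase. Gap absorption matters: without it, a brief arousal minutes
before the definitive awakening truncates the offset and decouples it from
the real sleep→wake transition. Deviation is again the mean |residual| from
the regression over cycles, in minutes.

## Time-domain HRV

RR intervals pass two filters: a physiological band of 50–250 ms
(240–1200 bpm — wide enough that a bradycardic trough near 330 bpm plus
Gaussian RR noise is untouched, while 3–10× artifact beats fall far
outside) and a robust local rule rejecting beats > 4 robust SDs (1.4826 ×
MAD, floored at 1 ms to keep noise-free series non-degenerate) from a
31-beat rolling median. A retained fraction below 50% raises a quality
error instead of returning numbers.

NN means are computed per 20-s segment; segment HR = 60000/mean NN, and
segments average into ZT-hour bins. SDNN per hour is the population SD of
*all* NN intervals in the hour (not the SD of segment means); a sample-SD
mode exists. The 24-h mean HR/SDNN average the 24 hourly values. The HR
rhythm amplitude is max/min of the hourly HR waveform; hourly binning
attenuates a pure sinusoid's ratio slightly (450/350 recovered to within
0.02), and the ratio refuses to compute when any hour is empty rather than
extrapolate. Empty hours are excluded from 24-h means with a warning.

## Expression panel

Counts are first scaled per sample by (cohort geometric mean of
positive-control sums)/(sample's positive-control sum). Housekeeping
scaling then multiplies each sample by target/(its housekeeping geometric
mean) with a *fixed* target level (default 1000 counts). A cohort-derived
target (e.g. the mean of the geometric means) would shift whenever any one
sample is rescaled, breaking idempotence and exact restoration of a
rescaled sample; with a fixed target the pipeline is exactly per-sample
scale-invariant, and the target's value cancels out of every fold change
and test statistic. Differential expression is log₂(mean_B/mean_A) on
normalized values with per-gene Welch t p-values, reported as −log₁₀ p; no
multiple-testing correction is applied by default (a BH-FDR column is
provided), and the significance flag defaults to raw p < 0.05. The ranked
report sorts by p, breaking ties by |log2FC| then gene id, and excludes
control probes.

## Group statistics

The summary-statistic t, t = (m₁ − m₂)/√(SEM₁² + SEM₂²) with
df = n₁ + n₂ − 2, equals the pooled raw-data t at equal n (asserted to
1e−12) and reproduces published statistics only to ~1% because printed
means/SEMs are rounded. The two-way repeated-measures ANOVA implements the
balanced mixed-design partition directly (between factor tested against
subjects-within-groups; within factor and interaction against the
residual), refuses missing cells, and is cross-checked against an
independent implementation in the test suite; sphericity is not corrected
by default. Holm–Šidák adjusts the i-th smallest p to
1 − (1 − p)^(m − i + 1) with a running maximum; it never rejects more than
unadjusted testing. Normality and variance screens are Shapiro–Wilk per
group and Brown–Forsythe (median-centered Levene) across groups; the
pipeline switches to a two-sided Mann–Whitney U when a screen fails, the
same fallback convention used in the study design this package targets. A
noncentral-t post hoc power helper is included for completeness; it is a
textbook quantity and not numerically equivalent to the "observed power"
column of commercial packages, whose formula is undocumented.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions the analyses are exercised under.

- **Activity**: per-bin Poisson counts with rate mesor × (1 + A·s), where s
  is a smoothed square wave (logistic edges, ~30-min transition) — nocturnal
  cage activity is plateau-like, and sharp edges give the onset estimator a
  real onset to find. Nightly onsets jitter by N(0, σ²). Fragmentation is a
  suppression state toggling with per-bin probability p during the active
  phase, multiplying the rate by 0.1; it resets at each onset and spares the
  first 2 h of the night (the consolidated dusk bout), because fragmentation
  that masks the onset itself would conflate two distinct phenotypes
  (fragmented activity vs. variable onset). `day_leak` scales the rest-phase
  rate.
- **Sleep**: a 1-Hz two-state Markov chain; sleep exit probability
  1/(mean episode length), entry probability set for the phase's stationary
  occupancy, simulated exactly as an inhomogeneous chain by redrawing
  sojourns at parameter boundaries (memorylessness makes this exact). At
  the per-cycle jittered wake onset the animal is forced awake — the event
  the awakening-time estimator measures. Sleep seconds emit immobile
  fractions in [0.95, 1], wake in [0, 0.90), so the 95% scoring threshold is
  genuinely exercised.
- **RR**: HR(t) = mesor + amplitude·cos(2π(ZT − acrophase)/24); beat
  intervals are 60000/HR plus Gaussian noise (the target SDNN), with an
  artifact fraction replaced by 3–10× outliers. Beat times are laid out on
  the mean-rate grid before evaluating the slow modulation; the phase error
  this introduces is negligible against the 24-h timescale.
- **Expression**: negative-binomial counts around base means × log-normal
  library factors, treated-group means shifted by per-gene log2 fold
  changes; housekeeping and positive-control probes always have zero fold
  change, and positive controls share the library factor so positive
  normalization can recover it.
- **Cohort**: one master seed expands into per-animal substreams
  (SeedSequence-based, each < 2³¹), so cohorts are reproducible and any
  animal regenerable in isolation. Animals within a group vary around the
  group's nominal parameters (log-normal with CV 0.10 on rates and scales,
  matched additive jitter on probabilities and phases) so group SEMs
  reflect biological spread, not just estimator noise. Motor scores couple
  linearly to each animal's *realized* rhythm power — computed by the
  package's own periodogram — plus Gaussian noise, which exercises the
  correlation analysis without asserting any biology. Group defaults were
  fixed once to land near the study's printed group summaries (rhythm power
  ~27 vs ~41 %V, activity ~79 vs ~158 a.u./h, onset variability ~33 vs
  ~19 min, wake onset ZT 12.35 vs 11.92, SDNN ~13 vs ~16 ms, HR amplitude
  ratio ~1.49 vs ~1.53 for ad lib vs TRF).

**What passing tests show — and don't.** The generator produces first-order
circadian structure only: no ultradian harmonics, no feeding-anticipatory
activity, no torpor, no autocorrelated HRV dynamics (RR noise is white), no
gene–gene correlation in the panel. Oracle-equivalence and calibration
results (bout merging, sleep scanning, periodogram statistics, type-I
rates) transfer to real data because they do not depend on the generator.
Parameter-recovery results (jitter, SDNN, fold changes) show the estimators
are unbiased under the generator's assumptions; on real data they bound
performance from above.

## Problem sizes and numerical details

Defaults throughout: 3-min activity bins over 10 days, 5 sleep–wake cycles
at 1 Hz with cycles 3–4 analyzed, 1 day of telemetry (~0.5 M beats),
100-gene panels with 8 housekeeping + 6 positive probes at n = 8/group.
Simulation-based tests use 10–25 replicates for recovery checks, 200 for
fold-change recovery, 1000 null series for periodogram calibration and
10,000 for t-test calibration. Ties in onset search break to the earliest
time; all-zero folds define Q_P = 0; degenerate two-group tests (zero
variance in both groups) raise rather than return numbers; Pearson
correlation requires n ≥ 3, finite values and nonzero variance. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`.

## Known limitations

- Onset variability saturates at the template detection floor for jitter
  below ~15 min at low count rates (see above).
- The awakening-time estimator reports the end of consolidated rest-phase
  sleep; definitions tied to a specific commercial tool will differ in the
  constant but not in group contrasts.
- The RM ANOVA requires a complete balanced design; unbalanced or missing
  data need a mixed-effects model, which is out of scope.
- Expression p-values assume approximate normality of normalized
  intensities within groups at n = 8; heavy overdispersion would call for
  count models instead.
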