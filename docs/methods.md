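# Methods

`desatarea` implements a unified framework for desaturation area–based
oximetry metrics and compares them as predictors of cardiovascular (CVD)
mortality. This note documents the model, the numerical choices, and what
the synthetic data do and do not establish.

## The desaturation-area family

Every metric in the family integrates the saturation deficit

    A_e = ∫_{W_e} max(0, B_e − SpO2(t)) dt        [%·s]

over a sampling window `W_e` associated with a sleep event `e`, against a
baseline `B_e`, and aggregates the per-event areas over the night. Three
published algorithms are special cases:

* **Hypoxic burden** (Azarbarzin-style): manually scored respiratory events;
  a *record-specific* window around each event end, bounded by the two peaks
  flanking the nadir of the event-locked ensemble-averaged SpO2 trace; an
  *event-specific* baseline (maximum SpO2 in the 100 s before event end);
  aggregation Σ A_e / TST, reported in %·min per hour of sleep.
* **REDTA** (respiratory event desaturation transient area, de Chazal-style):
  manual events; a *fixed* window starting at the event midpoint with length
  2.5 × event duration; a *fixed* 100% baseline; aggregation Σ A_e / 3600,
  in %·hours — independent of sleep time.
* **Desaturation severity** (Kulkas-style): automatically detected ≥3%
  desaturations; an *event-specific* window from the desaturation apex to
  its nadir (extended through a terminal plateau, capped at 180 s); an
  *event-specific* baseline equal to the maximum within the window;
  aggregation Σ A_e / TST, in %.

Crossing the two event sources with the three window families and three
baseline families gives an 18-cell method matrix (`ALL_COMBOS`). Fifteen
cells carry `in_paper_subset=True`, matching the subset evaluated in the
comparative literature; the three manual-event × event-specific-window cells
are the historically uncomputed remainder, which this package computes
anyway and flags.

The aggregation rule is keyed to the window family (record-specific →
%min/h, fixed → %hours, event-specific → %), so every fixed-window combo is
a REDTA-family metric, etc. For the event-specific rule, Σ(%·s)/TST(s)
already carries the unit %; no extra scale factor is applied.

## Desaturation detection

`detect_desaturations` scans each maximal run of valid samples left to
right. A candidate begins at the last sample before a strict fall (flats
climb to the crest). The descent tracks its running minimum and terminates
when the signal rises more than `recovery_tolerance_pct` (default 1.0%)
above that minimum, **or** above the candidate's own apex — without the
second condition, a noise wiggle encountered mid-recovery can become a
candidate apex slightly below the local resting level and "shadow" the next
genuine dip, shaving its measured drop below threshold. An event is emitted
when apex − nadir ≥ `min_drop_pct` (default 3.0%, the AASM-aligned
criterion).

Two further rules shape the emitted window:

* **Apex re-anchoring.** The apex moves forward to the latest local maximum
  that is still within the recovery tolerance of the original apex and a
  full drop above the nadir. Without this, a slow noise-level drift
  preceding a deep dip anchors the apex minutes early; the 180-s cap then
  truncates the window *before* the dip it nominally detected.
* **Plateau and cap.** The window end starts at the nadir and extends
  through samples within `plateau_tolerance_pct` (default 0.5%) of the nadir
  value; the apex-to-end span is then truncated to `max_window_s` (default
  180 s), re-locating the nadir inside the truncated window if needed.

The recovery and plateau tolerances are this package's explicit choices —
published descriptions of the reference software do not parameterize them —
and are surfaced in `DetectionParams` and in output metadata. Ties between
equal minima resolve to the earliest sample. Detection runs on the cleaned
trace without smoothing by default (`smoothing_window_s=0`). A brute-force
per-sample scan implementing the same documented semantics naively serves as
the test oracle.

## Windows and baselines

* **Ensemble window.** SpO2 segments on [end − 120 s, end + 240 s] are
  aligned at event end, averaged samplewise (invalid samples ignored), and
  smoothed with a 10-s centred moving average. The window boundaries are
  found by walking uphill from the averaged curve's nadir on each side until
  the ascent stops. With fewer than 5 events, or when either flanking peak
  is undetectable (e.g. a flat record), the conventional (−100 s, +100 s)
  fallback is used and flagged. The span, smoothing, minimum event count and
  fallback are package choices, all configurable.
* **Fixed window.** Read as: start at the event midpoint, *length* 2.5 × T
  (end at start + 3T). The alternative reading — *end* at start + 2.5T — is
  available via `fixed_window_ends_at_2p5T`.
* **Record baseline.** 99th percentile of the valid samples,
  linear-interpolation percentile definition (the percentile convention is
  documented because it is not standardized in the source methods).
* **Event baseline.** Maximum valid SpO2 in the 100 s before event end. The
  original desaturation-severity cell instead uses the maximum within the
  event window (its documented minor deviation); for all *other* auto-event
  combos the unified 100-s lookback applies. An empty lookback span falls
  back to the record baseline, logged.
* **Signal-shift emulation.** Adding (100 − p99) to every sample and
  integrating below a fixed 100% baseline is exactly equivalent to
  integrating below the p99 baseline directly (the deficit is translation
  invariant); `shifted_signal_emulation` exists to verify this equivalence
  end-to-end, mirroring how a fixed-baseline-only tool can be driven to
  produce record-baseline output.

## Area integration and overlap policy

The trace is treated as piecewise linear between sample starts. Each
segment's contribution to ∫ max(0, B − SpO2) dt is computed exactly,
splitting segments that cross the baseline (clipped-trapezoid /
triangle-at-crossing closed forms), and clipping partial segments at
fractional window bounds. Segments with an invalid endpoint contribute
zero; windows outside the recording are clipped and flagged. This makes the
integral exact for piecewise-linear traces rather than accurate to first
order, which is what the oversampled-Riemann oracle tests verify.

Overlapping windows within one method are resolved by
*truncate-earlier-at-later-start*: each later window's start truncates any
earlier window that overruns it, so every time point is counted once and the
later event owns contested time. A window nested inside a predecessor drops
the predecessor's tail with a logged warning. The policy is configurable
(`overlap: truncate|none`); `none` permits double counting for comparison
with implementations that allow it.

## Survival stage

Each metric column is z-scored (population SD, ddof=0; configurable) and
entered as the exposure in a Cox proportional-hazards model of CVD death,
fit by `lifelines.CoxPHFitter` with the Efron approximation for ties (the
lifelines default; fixed so repeated fits are bit-identical). Two covariate
sets are used: *partial* — age, sex, race (Caucasian/other), TST bins
(≤5 h reference, 5–8 h, ≥8 h), smoking (never reference, former, current),
alcohol, COPD; *full* — partial plus AHI, T90, MinSat and per-condition
cardio-metabolic flags (heart failure, stroke, angina, revascularization,
myocardial infarction). Analysis is complete-case; constant covariates are
dropped per fit; non-convergence and insufficient events (<10) yield flagged
results rather than exceptions. Hazard ratios are per SD of the metric, so
metrics with different units are directly comparable. Significance is read
at 0.05 and trend at 0.10 with no multiplicity correction — the metrics are
strongly correlated by construction, and the comparison is exploratory.

MinSat is not precisely standardized in the source material; the default
here is the minimum valid SpO2 over the union of event-associated windows,
with a mean-of-per-event-nadirs alternative (`minsat_mode`). Alcohol intake
is consumed as a numeric column (drinks/week in the generator) with no
coding semantics imposed.

## Synthetic data

`simulate_recording` emulates the structure the analysis assumes, not
polysomnography in full:

* Hypnogram of 30-s epochs hitting a target TST (default 7 h) with ~8% wake
  scattered after a short sleep-onset latency; non-wake stages drawn
  n1/n2/n3/rem at 5/50/20/25%.
* Manual respiratory events placed by a renewal process on the sleep-time
  axis with mean inter-onset interval 3600/AHI (default AHI 18/h, a
  moderate-OSA community-cohort value), durations truncated-normal
  (mean 25 s, SD 8 s, ≥10 s — the minimum scoreable event).
* Each event is followed, after a 15-s circulatory lag, by a raised-cosine
  SpO2 dip whose closed-form area (depth × half-width) is recorded in a
  truth log. Half-widths are truncated to [10, 45] s and a 90-s refractory
  gap (twice the maximum half-width) keeps planted dips disjoint; the
  renewal gap mean compensates so the target AHI holds in expectation.
  Infeasible combinations (mean footprint exceeding the mean onset
  interval) raise rather than silently under-deliver.
* A fraction `arousal_only_fraction` (default 0.8) of events are
  arousal-associated hypopneas whose dips stay below 3% (depths
  truncated-normal in [0.5, 2.5]%); the rest draw depths ≥3% (mean 6%,
  SD 3%, truncated [3, 30]%). At the default fraction, manually scored
  events outnumber detectable ≥3% desaturations roughly five-fold,
  reproducing the qualitative gap between AASM respiratory scoring and
  3%-threshold automatic detection. Additive Gaussian noise (default SD
  0.1%) completes the trace.

What this generator does **not** emulate: REM-related hypoventilation and
progressive non-resaturating drift, oximeter artifact bursts, autocorrelated
(non-white) sensor noise, overlapping desaturations from events in close
succession, and real AASM scorer variability. Passing tests therefore
establish algorithmic correctness under the stated generative assumptions,
not clinical performance on cohort recordings.

`simulate_cohort` draws per-subject conditions (TST ~ N(6.4, 0.9) h clipped
to [4, 9]; AHI log-normal around 15/h clipped to [4, 30]; demographics
loosely matching an older community cohort) and, by default, computes each
subject's burden from the closed-form planted-area model (`burden_mode=
"surrogate"`, flagged in the truth output) — the same depth × half-width
areas the recording generator logs, summed over a Poisson event count and
normalized per hour of sleep. `burden_mode="full"` instead simulates every
recording and reads the burden off the hypoxic-burden pipeline; it is
intended for small n and is cross-checked against the surrogate's scale in
tests. Survival times are exponential with rate
`baseline_hazard · exp(β·z(burden) + 0.05·(age−64) + 0.3·male)`, censored
uniformly on [0, 12] years (echoing a >10-year follow-up horizon). The
baseline hazard (0.026/y) was calibrated for ~15% deaths over the horizon at
a null linear predictor; with the exposure and covariate effects the
realized death rate is ~15–19%.

## Problem sizes and numerical conventions

* Times are seconds from recording start; intervals are half-open
  [start, end); sample-to-interval mapping uses sample start times; the
  canonical grid is 1 Hz (other rates are linearly resampled).
* Cleaning marks samples outside [50, 100]% invalid and bridges invalid runs
  ≤30 s (configurable) by linear interpolation; longer runs contribute zero
  area and zero T90 time, while their epochs still count toward TST — the
  pipeline never fabricates desaturation from dropout.
* Parameter-recovery checks use 100 seeded cohorts of n = 500 with ~75
  deaths each and a true log-HR of 0.5 per SD; recording-level checks use
  full-night traces (~7–8 h at 1 Hz) and batches of a few hundred planted
  events. These sizes give binomial/sampling error comfortably inside the
  asserted tolerances while keeping the default test run in minutes.
* Degenerate inputs are errors, not silent zeros: all-invalid traces, zero
  TST with per-TST metrics, constant predictor columns, zero-variance
  cohort burden, infeasible event packing.

## Known limitations

* The recovery/plateau tolerances and the ensemble-window parameters are
  package choices; other implementations of the same published rules can
  differ in these unspecified places, so bit-level agreement with third-party
  software is out of scope.
* Cohort-scale hazard ratios from real sleep-study data (which require
  controlled-access recordings and adjudicated outcomes) are not
  reproduced; the survival stage is validated by parameter recovery on
  synthetic cohorts only.
* EDF reading requires the optional `mne` dependency; EDF writing is not
  provided (traces are written as CSV).
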