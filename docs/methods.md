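# Methods

`eegbattery` implements a battery of rodent EEG biomarkers — paired-tone
sensory gating, social investigation-elicited gamma, the 40 Hz auditory
steady-state response (ASSR), sleep spindles, and vigilance-state spectra —
together with a synthetic-EEG generator that produces sessions with known
ground truth, so every pipeline stage can be validated end to end without
animal recordings. This note documents the models, conventions, parameter
choices and known limitations.

## Conventions

* Time is in seconds, t = 0 at recording start; amplitudes in microvolts.
* Intervals are half-open `[start, end)`; the sample holding time t is
  `floor(t * rate)`.
* Epoch-local time starts at 0 at the first epoch sample, so epochs cut with
  a pre-window of `p` seconds have their event onset at epoch-local `p`.
  Gating epochs use a 1 s pre-window, placing S1 at 1.0 s and S2 at 1.5 s,
  so the stimulus scoring windows are literally 1–1.05 s and 1.5–1.55 s.
* Analyses run per channel; the headline channel is `frontal` by default and
  any labelled channel can be selected.

## Spectral estimators

**Multitaper PSD** (`spectral.multitaper_psd`): average of K eigenspectra
from discrete prolate spheroidal tapers, one-sided, in µV²/Hz. Defaults
NW = 3, K = 5 (K ≤ 2·NW − 1 enforced); resolution half-bandwidth is NW/T Hz
for a T-second window. Long stationary stretches can be segmented
(non-overlapping) and pooled. The estimator satisfies Parseval's relation on
broadband input to within estimator variance (checked at 10 % on 8 s of
white noise).

**Morlet TFR** (`spectral.morlet_tfr`): complex Morlet convolution (via
MNE's `tfr_array_morlet`) with 7 cycles at every frequency by default; at
40 Hz the temporal SD is ≈ 28 ms, acceptable for 50 ms stimulus windows.
Power is the squared magnitude per trial; phase is retained for
phase-locking measures. Cells within half the wavelet support of an epoch
edge are flagged in `edge_mask`. For the broadband 1 Hz-binned profiles the
cycle count is tapered at low frequencies (≥ 1, ≤ 7, ∝ f · epoch length) so
the wavelet fits the epoch; bins below ~2 Hz are correspondingly
edge-contaminated and should be read with caution.

**Normalisations**: percent-of-baseline divides each frequency row by its
baseline-window mean (per epoch) × 100; percent-of-total integrates band
power over total-range power (trapezoidal, default denominator 1–100 Hz —
above DC drift, below the acquisition anti-alias filter); the 1 Hz-binned
log profile covers 0.5–100.5 Hz in exactly 100 bins of
log10(power/reference). Normalisation state is recorded on the map and
re-normalising is an error, which keeps grand averages from mixing scales.
The gamma band for the social task is 25–58 Hz exactly (the upper edge
avoids 60 Hz mains); no notch filter is applied by default.

## Sensory gating

Per subject, the ~100 paired-tone epochs are averaged after per-trial
subtraction of the 100 ms pre-stimulus baseline mean. P20 is the maximal
positive sample 15–30 ms post-tone, N40 the minimal sample 25–55 ms
(endpoints inclusive at sample resolution; ties to the earliest sample; no
peak fitting). S2 windows are the S1 windows shifted by the 500 ms
inter-stimulus interval. Gating metrics are S2/S1 and S1 − S2 per component;
N40 enters as its magnitude so all three components share the same sense.
Components are scored on each subject's own average; grand averages are for
display only.

Evoked gamma gating uses the average-then-transform order ("evoked" =
phase-locked): Morlet power of the trial-averaged waveform, 30–80 Hz,
averaged in each 50 ms stimulus window; percent reduction =
100 × (1 − S2/S1). Induced/total quantities (ASSR) use
transform-then-average instead.

Extremal-sample scoring on a noisy average is biased outward (the maximum of
signal + noise exceeds the signal maximum); at 100 trials and background
SD = 30 µV this inflates the recovered S2/S1 of a 0.25-gated kernel by
≈ +0.02, which the validation band accounts for. The bias vanishes as noise
→ 0 (tested).

## Social-investigation gamma

Investigations pass inclusion rules before analysis: minimum duration 1 s
and at least 5 s since the previous investigation ended (both
config-exposed), which guarantees the 4 s baseline is uncontaminated.
Elicited gamma: epochs of [−4, +4] s, per-epoch Morlet TFR (25–58 Hz, 2 Hz
steps, 7 cycles, decimation ×10), percent-of-baseline against [−4, 0), band
mean in two bins [0, 0.5) and [0.5, 1.0) s post-onset. Background gamma:
multitaper PSD of each [−4, 0) window, 25–58 Hz power as percent of the
1–100 Hz total. The association between the two is the repeated-measures
correlation across investigations with subject as the repeated factor
(subjects with < 3 matched investigations are dropped with a warning).
Grand-average spectrograms pool epochs across animals; binned statistics are
computed per epoch.

Three-chamber scoring consumes position traces: chamber occupancy by
point-in-polygon, an "entry" = outside→inside transition of the 5 cm circle
around a cage centre, distance = summed step lengths, velocity =
distance/duration.

## ASSR

Evoked power is the Morlet power at the stimulation frequency (default
40 Hz) of the trial average; total is the mean single-trial power; induced =
total − evoked, clipped at zero with a logged flag when estimation noise
makes it negative (the partition evoked + induced = total is exact before
clipping, by construction, and verified within 1 %). The phase-locking
factor (PLF) is the magnitude of the across-trial mean unit phase vector at
f0, time-averaged over the train window; a single trial yields PLF = 1 with
a degenerate flag. PLF is invariant to amplitude scaling and decreases
monotonically with phase jitter; for wrapped-normal jitter of SD σ the
large-n limit is e^(−σ²/2).

## Sleep spindles and state spectra

The spindle detector is a standard envelope-threshold procedure (the
published analysis this battery parallels did not print its algorithm, so a
declared detector with recovery-based validation is used): band-pass 9–16 Hz
(Butterworth order 4, zero-phase), analytic-signal envelope, threshold =
mean + 2.5 SD of the envelope over NREM samples, candidate runs intersected
with the NREM mask, gaps < 0.3 s merged, durations restricted to 0.5–3 s.
Per event: peak envelope amplitude and median instantaneous frequency.
Density is per NREM minute. All parameters are config-exposed. Because the
threshold is computed on NREM samples that include the spindles themselves,
detected durations are systematically ~15–20 % shorter than injected ones
and a ~10 % miss rate is expected at 6 events/min; the validation
tolerances (±20 % density, ±25 % median duration) reflect this.

State-specific PSDs concatenate whole scoring epochs per (state, lighting
period) and use the segmented multitaper estimator (4 s segments); bout
summaries (percent time, mean bout length, bouts per hour) come from
run-length encoding of the hypnogram.

## Statistics

All tests are implemented in `eegbattery.stats` (scipy supplies only
distribution functions); library implementations appear in the test suite as
independent oracles.

* **Welch's t**: Welch–Satterthwaite df, two-tailed. Degenerate variances:
  t = 0, p = 1 when both groups are constant and equal; error otherwise.
* **Mann–Whitney U**: exact two-tailed p by full enumeration of the null via
  the classic restricted-partition recurrence whenever there are no ties and
  C(n1+n2, n1) ≤ 10⁷; two-tailed p = 2 × min(P(U ≤ u), P(U ≥ u)) capped at
  1, which reproduces the standard printed exact values (e.g. p = 0.0451 for
  U = 6 at 8 vs 5). Ties route to the midrank/normal approximation with tie
  and continuity corrections, flagged.
* **Normality gate**: KS statistic against a normal with estimated moments;
  since parameters are estimated, p comes from a seeded Monte-Carlo null
  table (Lilliefors-style, 5000 draws per sample size, cached). The battery
  routes to Mann–Whitney when either group fails at α = 0.05 and emits both
  tests with the routing decision.
* **Holm–Sidak**: step-down, adjusted_i = 1 − (1 − p_(i))^(m − i + 1) with a
  running maximum, capped at 1. The family for binned time courses is the
  set of bins within one comparison panel.
* **Two-way ANOVA**: balanced designs only (unbalanced input is refused
  rather than silently resolved with an unstated sums-of-squares
  convention). The mixed design tests the between factor against the
  subject-within-group MS and within-factor effects against the
  subject × within MS.
* **Repeated-measures correlation**: common-slope ANCOVA with per-subject
  intercepts; r_rm = sign(b)·√(SS_x/(SS_x + SS_err)), df = N − k − 1, p from
  the slope F test. Subjects with constant x are dropped with a warning.

## The synthetic generator

The generator produces the statistical structure each biomarker assumes; it
is not a biophysical model.

* **Background**: 1/f^α noise by spectral shaping (α = 1 by default, RMS
  50 µV, plausible for epidural screw electrodes in mouse), high-passed at
  0.5 Hz to bound DC power, with a 4th-order Butterworth response at 200 Hz
  mimicking the acquisition chain's anti-alias filter. Optional tonic
  sinusoids.
* **Gating sessions**: 100 paired tones, ITI 6 s, ISI 0.5 s. The ERP kernel
  is two Gaussian-windowed cosines: P20 (latency 21 ms, σ 5 ms, +40 µV) and
  N40 (44 ms, σ 9 ms, −60 µV); widths/latencies were chosen so the
  *achieved* kernel extrema in the scoring windows match the programmed
  amplitudes (39.5/−60.0 µV). The S2 kernel is the S1 kernel times the
  gating factor g, so the programmed amplitude ratio is exactly g.
* **Social sessions**: investigation onsets ≥ 10 s apart; per event a tonic
  narrowband gamma level is drawn lognormally (median 8 µV, σ_log 0.35) and
  applied around the event. The burst occupying [onset, onset + 1 s) is
  calibrated so the *total* post-onset 25–58 Hz power equals the programmed
  percent of that event's measured [−4, 0) baseline band power (strict-band
  periodogram on both sides; a ratio of 100 % means no burst). The burst
  carrier reproduces the baseline's in-band spectral composition (1/f part
  plus tonic part, soft 8 Hz skirts) so the percent-of-baseline ratio is
  uniform across analysis frequencies; cosine ramps (100 ms) sit outside the
  analysed window. Negative elicited-vs-background coupling perturbs the
  burst amplitude by `coupling × (level − median level)`; the default −0.50
  was calibrated once so the recovered r_rm is ≈ −0.25 at the default
  conditions.
* **ASSR sessions**: 100 one-second 40 Hz click trains, ITI 5 s; each click
  evokes a damped oscillation (τ = 10 ms) whose superposition is a
  steady-state response carrying the trial's phase offset ~ N(0, σ²). The
  default background for ASSR sessions is quiet (RMS 5 µV) because
  background power at 40 Hz contaminates single-trial phase estimates and
  caps the PLF below its programmed value; the closed-form jitter→PLF
  mapping is a property of the response, not the noise.
* **Sleep sessions**: semi-Markov bouts (mean wake 120 s, NREM 240 s, REM
  60 s entered from NREM with probability 0.3; exponential durations rounded
  to 10 s scoring epochs), NREM-gated 1–4 Hz delta (40 µV), and NREM-only
  spindles: Poisson counts at 6/min of NREM, uniform durations 0.6–1.2 s,
  12 Hz, 150 µV with short Tukey ramps (8 %), placed non-overlapping inside
  their bout. Sleep sessions default to 500 Hz sampling, which resolves
  everything below the spindle band with wide margin and keeps half-hour
  sessions cheap; event-locked scenarios default to 2 kHz.

Every session's manifest (`GroundTruth`) records the injected events,
amplitudes, gating factor, jitter and seed, and the same seed reproduces the
session bit-for-bit.

### What the generator does not emulate

No movement or EMG artifacts, no electrode drift or line noise, no
non-stationary background, no volume conduction between channels, no
biophysical coupling between behaviour and oscillations. Passing recovery
tests therefore demonstrates that the pipelines measure what they claim on
data with the assumed structure — not that real recordings satisfy those
assumptions. Artifact rejection is config-exposed (amplitude threshold) but
off by default, since the battery's reference analysis applied none.

## Validation problem sizes

The validation suite uses 20 gating sessions of 100 trials; social sessions
of 40 investigations (recovery) and 100 replicates of 5 subjects × 20
investigations (coupling sign); 50 ASSR sessions of 100 trials; 40-minute
sleep sessions; and 5000-replicate calibrations for the Welch and Holm–Sidak
error rates. These sizes put Monte-Carlo error comfortably inside each
tolerance while keeping a full run to a few minutes.

## Known limitations

* EDF output is 16-bit with a shared physical range per file; round-trip
  error is bounded by the quantisation step of the recorded amplitude range.
* The exact Mann–Whitney path requires tie-free data; midranks with a
  normal approximation are used otherwise (flagged).
* The Monte-Carlo normality-gate p-values carry simulation error of order
  1/√5000 ≈ 0.014 near the α = 0.05 boundary.
* Unbalanced ANOVA designs are refused by design.
* The repeated-measures correlation between background and elicited gamma
  carries a small mechanical component from shared estimation noise in the
  per-event baseline; the top-up burst calibration keeps the zero-coupling
  null centred near r = 0 (|bias| ≲ 0.05 at 200 investigations).
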