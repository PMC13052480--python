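# Methods

`polarppg` analyses perfusion index (PI) from a dual-wavelength (655/940 nm),
polarization-gated reflectance PPG wearable, and ships a synthetic-cohort
generator so that every stage is testable with analytically known ground
truth.  This note records the models, the numerical choices, and what the
synthetic validation does and does not establish.

## Signal model and the synthetic cohort

Each participant's recording has four intensity channels — (655, 940 nm) ×
(co-, cross-polarized) — in detector counts at 25 samples/s.  The generator
emulates each channel as

```
I(t) = B + S + m · A · B · (1 − pulse(t)) + w·sin(2π f_w t + φ) + ε(t)
```

* `B` (`baseline_dc`): nonpulsatile DC level in counts.  Defaults per
  channel (46 000 / 38 500 / 45 300 / 30 500) echo the signal ranges a
  19-bit charge-integrating front end produces on light skin, with
  cross-polarized channels darker because surface reflections are gated out.
* `S` (`surface_offset`): additive nonpulsatile counts present only in
  co-polarized channels (superficial surface reflection); default 8% of `B`.
  This term is the entire phenomenological content of the polarization
  model: it inflates DC without touching AC, which is exactly how
  cross-polarized detection raises PI.  No radiative transfer is modelled.
* `m` (`melanin_atten` ∈ (0,1]): multiplicative attenuation of the
  pulsatile amplitude, standing in for pigmentation/perfusion optics.  The
  literature gives no quantitative ITA↔attenuation law, so the mapping is
  not fixed: cohort generation *solves* `m` per channel from the target PI.
* `pulse(t) ∈ [0,1]`: per-beat template, a Gaussian systolic lobe
  (σ = 0.12 s) plus a delayed (0.30 s) dicrotic lobe at 0.35 relative
  amplitude, peak-normalised — the simplest shape with a dicrotic notch.
  Beat intervals are lognormal with CV 0.03 around 72 bpm.  The signal uses
  `1 − pulse`, so intensity dips at systole (non-inverted convention).
* wander: one sinusoid (8 counts, 0.25 Hz) standing in for respiratory
  baseline drift; `ε`: white Gaussian noise (SD 2 counts).  These defaults
  are deliberately mild — published traces from such front ends are visually
  clean — and are config-exposed.

Noise-free per-beat truth is evaluated on a dense 250 Hz grid:
`PI = 100·(beat max − beat min)/(beat min)` per beat window, recorded per
channel before wander/noise are added.

Cohort generation inverts the linear structure the analysis targets:
participant `i` with ITA `t_i` (evenly spread over −25…+50°, lightest
first) gets target PIs

```
PI(co)    = β₀ + β₁ t_i + u_i
PI(cross) = PI(co) + β₂ + β₃ t_i
```

with defaults β = (0.66, 0.006, 0.83, −0.015) %PI and `u_i ~ N(0, 0.1²)`
inducing the within-participant correlation the GEE stage assumes.  Channel
amplitudes are solved from these targets through the template's pulse
excursion; targets that demand a nonpositive PI or an attenuation outside
(0,1] are rejected with a diagnostic.  The CIELAB ground truth places
participants along fixed b* = 16 with L* = 50 + b*·tan(ITA); colorimeter
scans add Gaussian noise (SD 0.2 on each coordinate, 20 scans/participant).

## Filtering

The contract is stated on the *overall* response: unity DC gain, −3 dB
(70.7%) exactly at the 5 Hz cutoff, zero net phase.  This is met with one
pass of a symmetric windowed-sinc FIR (Hamming window, transition width 25%
of the cutoff, 67 taps at fs 25; stopband ≤ −50 dB) whose integer group
delay is removed exactly.  Forward–backward filtering is deliberately *not*
used: it squares the magnitude response, which would put 5 Hz at 50% rather
than 70.7%.  Because `firwin`'s nominal cutoff is the −6 dB point, the
design cutoff is solved with Brent's method so that the gain at 5 Hz equals
1/√2 to 1e−10.  Edges are handled by reflection padding of one filter
length; signals must exceed three filter lengths.

The "assumed sampling rate" parameter reproduces a MATLAB `lowpass()`
idiom: designing for rate `f` but applying at the true 25 samples/s moves
the effective cutoff to `5·25/f` Hz.  Candidates 20–50 are swept and scored
with a quality index = (filtered-signal power in the 0.8–3 Hz cardiac
band) / (raw-signal power above 0.1 Hz).  The denominator is taken from the
raw signal on purpose: normalising by the *filtered* total would reward the
most aggressive candidate for merely discarding broadband energy, and white
noise could then score arbitrarily well.  With the raw denominator, a clean
beat train scores ≥ 0.9 for every candidate while white noise stays below
0.5 and raises a low-quality flag.  Ties go to the smallest candidate.

## Segmentation and PI extraction

The filtered 2-min record is cut into contiguous non-overlapping 10-s
windows; the three highest-quality windows (same cardiac index, computed
per window; ties to the earliest) become P1–P3 in chronological order.
Windows touching repaired NaN runs longer than 3 samples are invalid.  NaN
runs of ≤ 3 samples are linearly interpolated at read time.

Peaks (diastolic maxima) and troughs (systolic minima) are local extrema
with prominence ≥ 0.25× the segment IQR — a unit-free threshold that
behaves identically across channels and skin tones — separated by at least
one beat period at the band maximum (fs·60/100 samples).  Each peak pairs
with its nearest preceding trough; per beat, DC = trough, AC = peak −
trough, PI = 100·AC/DC.  Inter-peak intervals implying rates outside a hard
40–180 bpm band are removed as detection artifacts; the segment is valid
iff the median surviving rate lies in the configurable 60–100 bpm band.
The wider hard band keeps physiologically possible beats from being
silently deleted — they only flag the segment.  Within a segment the
per-beat PIs are averaged (a median-beat mode is available via
`segment_pi_mode`); the participant/channel PI is the mean over valid
segments, and a participant/channel with no valid segment is marked missing
and excluded downstream with a logged reason.

Outlier screening before regression uses participant mean PI > Q3 + 3·IQR
of the cohort.  This is an explicit algorithmic stand-in for a judgment
call (e.g. excluding a participant whose perfusion was elevated by recent
exercise); it is disabled by `--no-exclusion`, and a rule that would remove
more than half the cohort aborts instead.

## Skin tone

ITA = arctan((L* − 50)/b*)·180/π, undefined at b* = 0.  Repeated scans are
aggregated scan-wise (per-scan ITA first, then mean and sample SD with
n − 1), which matches per-participant "mean ± SD over 20 scans" semantics
and differs from the ITA of the mean colour for asymmetric scan clouds.
Categories: light > 23°, medium −5…23° (boundaries inclusive), brown < −5°
— cutoffs suited to cohorts with few participants below −30°; the classic
six-way scheme is available separately as `classify_classic`.

## GEE regression

Per wavelength, per-segment PI (6 observations per participant: 2
conditions × 3 segments) is regressed on ITA, a cross-polarized indicator
(co-polarized is the reference level) and their interaction, clustered by
participant.  Estimation is by Fisher scoring on the estimating equations
(identity link, Gaussian variance), with the scale and the exchangeable
correlation refreshed each iteration by moment estimators whose
denominators (N − p and n_pairs − p) match the conventional reference
formulas — the fixed point therefore coincides with established
implementations to machine precision, which the test suite verifies
against statsmodels.  Convergence: max |Δβ| < 1e−10, cap 100 iterations;
|α̂| is clamped inside the positive-definite range with a warning.
Inference is the uncorrected (CR0) cluster sandwich B⁻¹MB⁻¹; Wald =
(estimate/SE)² against χ²₁; CI = estimate ± 1.96·SE.  Under the
independence working correlation the estimates are exactly OLS.

Known limitation, measured rather than hidden: with only 8 clusters the
CR0 sandwich combined with z quantiles undercovers — nominal-95% CIs cover
≈ 80% in Monte-Carlo at the study size, rising into the 90s by 30 clusters.
No small-sample correction is applied because the reported-table
conventions (χ²₁ Wald, z CIs) define the method; users analysing
few-cluster data should treat the CIs as optimistic.

## Problem sizes used in validation

The default synthetic cohort is the full study condition (8 participants,
120 s, 25 samples/s).  The estimator Monte-Carlo uses 200 table-level
replicate cohorts (drawn directly from the marginal model — the oracle
simulator must not truncate at zero, which would bias it); the
cross-effect detection sweep uses replicate cohorts at 30 s per recording,
a size at which the three 10-s windows are exactly the forced partition;
the PI-recovery sweep uses 20 recordings of 60 s spanning true PI
0.2–3%.

## What passing tests show — and what they do not

The synthetic generator shares its beat template, noise model and effect
structure with the pipeline's assumptions, so end-to-end recovery (slope
≈ 1, intercept ≈ 0 against noise-free truth) demonstrates the *pipeline's*
internal correctness: filtering does not move landmarks, AC/DC pairing is
right, and the regression recovers the generative coefficients.  It does
not validate the device physics: real skin adds motion artifacts beyond
sinusoidal wander, melanin affects the two wavelengths differently, pulse
shape varies with age and vascular tone, and the ITA↔attenuation mapping
here is a modelling convenience.  Conclusions about real hardware require
the real recordings, for which `run_all(input_dir=...)` accepts the
documented CSV dialect.
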