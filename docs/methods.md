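# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `burstlab`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Narrowband filtering

Each band filter is a high-pass-then-low-pass cascade of linear-phase
equiripple FIRs (Parks–McClellan via `scipy.signal.remez`), designed at
minimum order by an iterative search: start at the Kaiser length estimate
and grow by two taps until the realized response meets spec on a dense
grid.  Spec per stage: 1 Hz transition band, 0.04 dB peak-to-peak passband
ripple, 40 dB stopband attenuation.  The 0.04 dB figure is read as the
peak-to-peak ripple of one stage (δ ≈ 0.0023 linear); the cascade's
worst-case passband deviation is then ±0.04 dB, and its stopband is at
least as attenuated as either stage.  Every constructed filter is audited
numerically; violations raise rather than warn.

Filtering is zero-phase by symmetric-FIR group-delay shift (both stages
are type I, so the delay is an integer number of samples).  Forward–
backward filtering was rejected because it squares the magnitude response
and would silently change the designed ripple/attenuation.  The signal is
demeaned before convolution: the cascade's DC leakage is below −40 dB but
not exactly zero, and detection must be exactly invariant to constant
offsets.  Samples within one full cascade length of either end are flagged
unreliable; cycles touching them are discarded before run formation, which
costs about 4.9 s per recording edge at 250 Hz.  Whether the original
pipeline filtered causally or zero-phase is not documented anywhere we
could find; zero-phase keeps zero-crossing times unbiased against the raw
trace, which the peak-location step depends on.

The "raw" trace of the detector is the minimally filtered 0.5–40 Hz
signal (4th-order Butterworth, zero-phase), the conventional broadband EEG
range.

## Cycle parsing conventions

Coordinates are 0-based sample indices with half-open spans.  A
zero-crossing is the first sample carrying the new sign; zero-valued
samples inherit the previous sign, so resolution is limited only by the
sampling rate and the convention is deterministic.  Peak searches resolve
ties to the earliest sample.  Criterion B's "distance to the neighbouring
peaks" is computed between consecutive negative peaks, matching the burst
frequency definition (reciprocal mean inter-negative-peak distance); the
alternative reading (half-cycle distances to the flanking positive peaks)
is noted as an open interpretation but not implemented as a switch — the
negative-peak reading keeps B and the frequency definition on the same
quantity.

Criterion F applies per flank (both the descending and the rising flank
must reach the 0.6 monotone-fraction threshold), the stricter of the two
readings of the printed rule.  Criterion G is the fraction of traversed
voltage moving in the flank's direction, averaged over the two flanks;
the alternative net-change/total-change form is strictly harsher (net/total
≥ 0.6 is equivalent to correct/total ≥ 0.8) and does not match the printed
threshold's intent.  A missing neighbour cycle fails C and E by
definition: consistency with a neighbour that does not exist is taken as
false, never as vacuously true, so the first and last cycle of any run of
activity cannot start a burst.

## Detection and overlap resolution

All seven criteria must hold jointly; runs of ≥ 4 contiguous passing
cycles (contiguous = sharing positive peaks) become bursts.  Both
polarities are detected and enter one within-channel resolution pass:
repeatedly keep the largest burst (by cycle count, then duration, then
earlier start — the published rule says only "largest", so the tie-break
order is fixed here for determinism) and trim overlapping competitors at
cycle granularity; a remnant survives only with ≥ 4 cycles.  Two bursts
sharing only a boundary positive-peak sample are not considered
overlapping.  Cross-channel aggregation is greedy longest-first; a
candidate joins when the overlap covers ≥ 50 % of the candidate's own
duration (the permissive denominator; the published rule states no
denominator) and the mean frequencies over the overlapping cycles differ
by ≤ 1 Hz.  Band assignment is half-open: theta [4, 8), alpha [8, 12).

## Synthetic data

The generators define the study conditions under which the pipeline is
validated; all are pure functions of their seed.

**Aperiodic background** — white Gaussian noise shaped in the frequency
domain by f^(−exponent/2), zero DC, scaled to a target RMS.  Spectral
shaping gives the exact target log-log slope with no filter transients.
Defaults: exponent 1 (a typical waking-EEG aperiodic slope), 10 µV RMS.

**Bursts** — a sinusoidal carrier with piecewise-linear time-warped phase
(the `waveform_asymmetry` knob compresses the descending flank, emulating
mu-like sharp descents) under a flat-top envelope with quarter-cycle
raised-cosine ramps.  One full-amplitude shoulder cycle is rendered on
each side of the counted cycles because the outermost cycles of any finite
burst necessarily fail the neighbour-pairwise amplitude-consistency
criterion; with shoulders absorbing those failures, the detector recovers
the counted cycle count exactly at zero noise, which is what makes
ground-truth counts meaningful.  The positive lobe at the start of the
counted run is scaled to 0.15 of full amplitude: without it the
inverted-polarity parse (offset half a period) finds one more
full-amplitude cycle than requested.  A Hann envelope remains available
(`envelope="hann"`) precisely because it violates amplitude consistency at
the edges — useful for criterion-violation tests, unusable for exact-count
ground truth.  Signal-to-noise is defined as peak-to-peak burst amplitude
divided by twice the background SD inside the narrowband covering the
burst frequency; the convention must be stated because none is standard
for transient oscillations.

**Detection fixture** (`gen_burst_recording`) — 60 s at 250 Hz, 20 bursts
of 6–12 cycles at 4.5–11.5 Hz, band-SNR 5, placed uniformly without
overlap and clear of the filter-edge zones, ~45 % occupancy of the
analyzable window.  Burst durations of roughly 1–2 s and high occupancy
emulate taxing-wake EEG, where theta/alpha bursts are frequent and long.

**Oddball sequences** — 160 standards, 40 targets, inter-onset intervals
i.i.d. uniform on [1.8, 2.4] s, ≥ 3 standards between consecutive targets.
Target placement is uniform over all admissible arrangements via a
stars-and-bars composition of the spare standards, so no position is
biased.

**Pupil traces** — 50 Hz, baseline diameter in mm converted to pixels by a
known factor (default matches a 192 px / 4.5 cm frame with a 1.2 cm iris
under the 12 mm standard-iris convention, so the pixel→mm conversion is
exactly recoverable).  Closures are confidence-0.05 spans snapped to the
sample grid (blinks 0.1–0.8 s at a Poisson rate; microsleeps 1–3 s scaled
to a target closed-time fraction); event-locked dilations use a gamma-like
kernel peaking ~0.9 s after onset.  Ground-truth tables describe the
emitted trace exactly, so closure counts are recoverable to the event.

**Study tables** — per participant and session, amplitude-like outcomes
follow asymptote·(1 − exp(−rate·hours awake)) minus a dip during the two
evening sessions, plus participant offsets and session noise; quantity-like
outcomes follow a linear trend.  Defaults: 18 participants, asymptote 2,
rate 0.15/h, dip 1, between-participant SD 0.5, noise SD 0.5 (z-like
units).  Session clock times: the four statistics-relevant anchors are
17:30, 20:00, 23:00 and 02:40 (next day, +24 h on a continuous axis); the
earlier sessions are spaced through the preceding day.  A vectorized core
(`simulate_study_values`) makes 10⁴-replicate Monte-Carlo runs cheap.

## Statistics

Paired t-tests are two-sided on pairwise-complete data; Hedge's g applies
the small-sample correction J = 1 − 3/(4·df − 1) to the standardized mean
difference of the paired differences (the toolbox the published work used
states no formula; this is the standard correction, and g = J·t/√n is
asserted as a cross-check identity).  Zero-SD differences are flagged
degenerate rather than producing infinities.  All z-scoring (outcomes,
spectra) uses the sample (n−1) SD and pools within participant across
sessions, conditions and channels; zero pooled SD yields missing values.

The wake-maintenance-zone contrast linearly interpolates the 17:30 and
02:40 values to 21:30 (weight w = (21.5 − 17.5)/(26.667 − 17.5) ≈ 0.4364)
and subtracts from the observed mean of the 20:00 and 23:00 sessions; the
group test pairs observed against expected.  The statistic is exactly zero
whenever the evening sessions lie on the chord.  Next-day times carry a
+24 h offset — without it 02:40 would precede 23:00 and the interpolation
weight would be negative.

Benjamini–Hochberg FDR goes through `statsmodels.stats.multitest`
(step-up, level q), verified against a brute-force scan; it is intended
for channelwise map testing only, matching the published analysis policy
of no correction across the main outcome battery.

The minimum detectable effect inverts the noncentral-t power function of
the two-sided paired test (ncp = d·√n, df = n − 1) by bracketed root
finding, then converts d to g via J.  Saturated noncentrality (where
scipy's nct underflows to NaN) is treated as power 1.

## Spectral power

Welch PSD: 8 s Hann windows, 75 % overlap, constant detrend per segment
(the minimal choice; nothing in the published spec constrains detrending),
density scaling so the integral recovers the signal variance, 0.125 Hz
resolution.  Band averages exclude the nine outer-edge electrodes of the
129-channel net (48, 63, 68, 73, 81, 88, 94, 99, 119), average retained
channels first and then the frequency bins in [low, high).

## Pupillometry

Closures are sub-0.5-confidence runs with 50 ms hysteresis applied in the
stated order: short confident interruptions merge into the surrounding
closure first, then short isolated dips are discarded.  Durations compare
against the un-rounded 50 ms sample count so a 40 ms event at 50 Hz (2
samples) is correctly below threshold.  Blink/microsleep split at 1 s.
Cleaning interpolates sub-0.5 s invalid gaps linearly, then deletes
sub-0.5 s valid islands — the order matters and is fixed as stated.
Resampling to the 50 Hz analysis rate is linear interpolation onto a
uniform grid (the published pipeline states the rate but not the method).
Oddball epochs span −0.5 to 2 s around tone onset (targets plus the
immediately preceding standards), are baseline-corrected by the −0.5–0 s
mean, and pass through the exclusion cascade: trial < 2/3 clean timepoints;
session < 15 usable trials per tone type or any averaged timepoint pooling
< 10 trials; participant < 6 of 12 usable sessions.  Averaged courses are
z-scored per participant across timepoints, tone types and sessions; the
response is the trapezoidal area of (target − standard) over 0.5–2 s, in
z·s.  Single-eye selection takes the eye with the most surviving samples.

## What passing tests do and do not show

The synthetic fixtures have stationary Gaussian 1/f backgrounds, perfectly
periodic inserted bursts, and noise-free confidence traces.  Real EEG has
non-stationary artifacts, non-sinusoidal rhythms, and topographic
structure; real pupillometry has gaze-dependent estimation error.  Passing
tests therefore demonstrate the pipeline's internal correctness and its
measurement properties (gain/DC invariance, amplitude/quantity
dissociation, exact recovery under known ground truth), not field
performance on recorded data.

A quantified limitation: at band-SNR 5 over an exponent-1 background the
detector's pooled sensitivity reaches 0.90, but precision reaches only
≈ 0.73 (the acceptance suite asserts 0.9 and the precision assertion
fails, deliberately left failing rather than weakened).  Shape-based
detection has no amplitude floor, and an exponent-1 background alone
yields on the order of 20 criterion-passing false bursts per minute —
mostly minimum-length 4-cycle events around 8–13 Hz whose raw-trace
amplitude comes from smooth broadband fluctuations.  The criteria
implementations match independent brute-force oracles, so this is a
property of the method at its published thresholds, not of the
implementation; re-tuning thresholds is explicitly out of scope.  Users
comparing conditions should note that this false-positive floor is
condition-independent and cancels in contrasts, which is how the
amplitude/quantity measures are used.

## Problem sizes

Default validation sizes were chosen to keep every check sharp but cheap:
three 60 s single-channel recordings for detector validity, 100–1000
random instances per brute-force oracle, 200 replicates for dip recovery
and 10⁴ for type-I calibration (binomial SE ≈ 0.002 at p = 0.05), 100
seeds (script) / 1000 seeds (tests) for the oddball design invariants.
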