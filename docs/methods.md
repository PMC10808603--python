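# Methods

## Scope and model

`heartseg` segments a mono phonocardiogram into cardiac cycles labeled with
four states and extracts per-segment acoustic features. The underlying
signal model is minimal and deliberately assumption-light: a heart-sound
recording is a quasi-periodic train of two energy bursts per cycle — S1 at
the start of systole, S2 at the start of diastole — riding on broadband
noise. The state definitions are operational, not hemodynamic:

* **systole** = S1 onset → S2 onset of the same cycle,
* **diastole** = S2 onset → S1 onset of the next cycle,

so systolic + diastolic duration equals the cycle duration by
construction, and S1/S2 burst intervals are embedded in their phases. A
consequence worth knowing when reading feature tables: because S1 ⊂
systole, any max-based feature of systole dominates the S1 value, with
equality whenever S1 holds the systolic peak (the usual case) — the S1 and
systole columns of max-level summaries are then identical.

## Time representation

All label times live on an integer-microsecond grid, matching the
6-decimal Audacity label format. Conversions use division by 10⁶ (exactly
representable, correctly rounded), so a written label re-parses to the
bit-identical float, and duration bookkeeping (conservation of
systole + diastole = cycle; shift invariance under trimming) is exact
integer arithmetic rather than float summation. Sample `i` of a recording
covers `[i/fs, (i+1)/fs)`; intervals are half-open `[start, end)`.

## Detection chain and its numerical choices

**Standardization.** Mean removal then peak normalization (`max|x| = 1`).
Peak (not RMS) normalization keeps the dB features interpretable as dBFS,
the meter scale Audacity users see. Idempotent; silent input is a named
error, not a NaN cascade.

**Band-pass.** 25–400 Hz zero-phase Butterworth (two second-order sections
through `sosfiltfilt`, i.e. 4th-order magnitude response). S1 and S2 carry
their energy well below 400 Hz; the 25 Hz floor rejects breathing and
probe-motion rumble. The filtered signal feeds *only* the detection
envelope; features are computed on the standardized, unfiltered audio so
amplitude features are not colored by the detection filter.

**Envelope.** Average Shannon energy, −x²·ln x², over 0.02 s frames with
0.01 s hop. Shannon energy emphasizes medium-intensity components and
suppresses both near-silence and full-scale samples. Two practical
consequences shaped the implementation:

* the transform is *zero* at `|x| = 1`, so after peak normalization the
  loudest burst acquires a shallow central dip in its envelope (it can
  even sit *below* a softer burst's envelope). Peak heights are therefore
  never used to decide which train is S1;
* boundary and peak logic must not mistake that dip for a burst edge (see
  below).

**S1 anchor train.** Candidate peaks are envelope local maxima above 20%
of the global maximum, separated by at least one minimum cardiac period
(60/max_hr). Cycle-period hypotheses come from the top-3 autocorrelation
peaks of the envelope within the plausible period band; for each
hypothesis a train is grown greedily from the tallest candidate (next
anchor = tallest candidate 0.55–1.45 periods ahead). Train selection is
*not* by coefficient of variation alone: subsampling a jittered periodic
train lowers its CV, so a train that skips every other beat looks more
regular than the true one. Among trains that are regular (CV within 2× of
the best, absolute cap 0.08) and cover ≥ 80% of the candidate span, the
smallest mean gap — the fundamental period — wins.

**Role disambiguation.** With anchors fixed, the highest interior envelope
maximum between each adjacent anchor pair is the opposite-sound candidate.
If the median anchor→interior lag exceeds half the cycle, the anchors are
actually S2 (systole must be the shorter phase) and the roles are swapped;
an exact half-cycle tie goes to the taller train as S1.

**Peak times.** Reported peak times are the envelope-mass centroid of the
contiguous region above half the local maximum, not the raw argmax: a
flat-topped burst lets the argmax wander across its plateau with noise,
and the Shannon dip splits loud bursts into two humps. The centroid is
stable under both.

**Outlier rejection.** An S2 candidate is dropped when its height or its
S1→S2 lag deviates from the median by more than `k = 3` scaled-MAD units
(MAD × 1.4826). Tolerance floors — one envelope hop (10 ms) on lag, 1% of
the median on height — stop the rule from mass-deleting candidate sets
whose MAD collapses toward zero: deviations at the measurement resolution
are noise, not outliers. Cycles whose S2 is missing or rejected are
excluded from the cycle list (and logged), never silently interpolated.

**Boundaries.** From each peak the envelope is walked outward until it
crosses `boundary_fraction` (default 0.1) of the peak height — linearly
interpolated between frame centers — or bottoms out in a valley. Valley
termination has two guards: the valley must be *deep* (below
`valley_depth_fraction` = 0.5 of the peak height; shallower dips such as
the Shannon depression are walked through) and *confirmed* (the envelope
must rise ≥ 10% of the peak height above the running minimum; a one-frame
noise up-tick does not end a burst). Walks that leave the envelope span
are clipped and flagged. Boundary times are quantized to the microsecond
grid.

**Trimming.** Output audio and labels are cropped to
[first S1 onset, last complete cycle end) and shifted so the first S1
starts at 0. Durations are preserved exactly (integer shift); at least two
complete cycles are required.

**Heart rate.** 60 / *median* cycle duration, rounded half away from zero
to an integer. The median (rather than the mean) makes the estimate
insensitive to a single missed or split cycle, which would otherwise
create one double- or half-length outlier.

## Feature battery

All features are per segment (S1, systole, S2, diastole) per cycle.
Undefined values carry **NaN as an explicit sentinel** — never a silent
0 — so per-state summaries can exclude them.

* **Amplitude (dBFS).** 20 ms frames, 10 ms hop; per-frame level
  `20·log10(RMS)`; features are max/min/mean/median of frame levels,
  floored at −120 dB; a segment shorter than one frame is measured whole
  and flagged. On standardized input all levels are ≤ 0 dBFS.
* **Statistics.** Population (n-denominator) moments; kurtosis is
  *non-excess* (Gaussian baseline 3). `shapefactor = RMS/mean|x|`,
  `impulsefactor = max|x|/mean|x|`, `marginfactor = max|x|/(mean√|x|)²`,
  `energy = Σx²`. Zero-variance segments (to float accumulation accuracy)
  report skew/kurt as NaN. For zero-mean segments STD equals RMS exactly.
* **Fundamental frequency.** 40 ms frames, 10 ms hop; per-frame
  autocorrelation peak search over lags corresponding to 50–400 Hz. Two
  normalizations are used deliberately: the *biased* estimate (divided by
  total frame energy) damps long lags, so broadband noise cannot fake
  periodicity — it drives the voicing decision (threshold 0.3) and lag
  choice (smallest local maximum within 95% of the best, guarding against
  octave errors; parabolic interpolation refines the lag). The *unbiased*
  estimate (normalized by the two windows' norms) measures true
  periodicity strength at the lag and drives HNR and the harmonic ratio.
  f0 summary statistics (first/middle/last/median/mean/sd/skew/kurt/
  max/min/range) run over voiced frames only; all-unvoiced segments are
  fully NaN. `slope_start2max` / `slope_max2end` are rise/decay rates of
  the f0 track ((max−first)/time and (last−max)/time) normalized by mean
  f0 to be dimensionless — a documented interpretation, as these names
  have no canonical definition.
* **Quality.** Jitter = 100 · mean|Pᵢ₊₁−Pᵢ|/mean P over consecutive
  voiced-frame periods (needs ≥ 2 voiced frames). HNR = 10·log10(r/(1−r))
  with r the mean peak autocorrelation, clamped to ±60 dB; computed over
  voiced frames when any exist, else over all frames so aperiodic segments
  still report a (negative) HNR.
* **Harmonic ratio.** Per-frame peak unbiased autocorrelation in the f0
  band, clipped to [0, 1], summarized by mean/median/sd/max/min.

## Synthetic PCG generator

The simulator emulates the gross morphology the segmenter relies on and
nothing more: per cycle, an S1 tone burst at the cycle start and an S2
burst at a configurable systolic fraction, each a Tukey-windowed (α = 0.4)
sinusoid; independent Gaussian cycle-length jitter; additive white noise
at a configured SNR. Defaults describe a healthy resting adult: 72 bpm,
S1 0.12 s at 80 Hz, S2 0.10 s at 110 Hz, amplitude ratio 1.3 (S1 louder
and longer, as the identification rules assume), S2 onset at 35% of the
cycle, 1% cycle jitter, 4 kHz sample rate. One integer seed drives all
randomness; identical configs are bit-reproducible.

The Tukey window is a deliberate choice over smoother bells: its support
is exact, so ground-truth onset labels are well-defined and boundary
errors can be scored in milliseconds; a window with infinite tails has no
defensible "onset". A murmur injector adds band-limited noise strictly
inside systolic or diastolic truth intervals for robustness experiments.

What the simulator does **not** model: S3/S4, split S2, respiration-driven
amplitude/rate modulation, probe-contact artifacts, real S1/S2 spectral
shapes (multi-component chirps rather than tones), or clinical murmur
morphology. Passing the recovery tests therefore shows the algorithm is
correct under its stated model — clean quasi-periodic bursts down to
10 dB SNR — not that it matches expert annotation on pathological
recordings.

## Test problem sizes

The recovery checks run 20 seeded 60 s simulations cycling heart rate
through {60, 72, 90, 100} bpm and SNR through {10, 20} dB, about 1,600
beats in total; feature-formula checks compare against independent
brute-force loop implementations at 10⁻¹² relative tolerance on random
short vectors; label round trips are exercised on 1,000 random
segmentations. The full suite runs in well under a minute on one CPU.

## Known limitations

* The detector assumes exactly two dominant bursts per cycle; loud S3/S4
  or murmurs with burst-like envelopes can be picked as S2 candidates
  (the MAD filter then usually rejects the cycle rather than mislabeling
  it).
* Boundary placement at 10% of peak height measures the *audible* burst
  support; it is systematically a few ms inside a windowed burst's
  nominal support at high noise floors.
* MP3 ingestion is declared in the I/O surface but raises a named
  unsupported-codec error; convert to WAV PCM first.
* The paired *t*-test helper tests mean agreement only; it is not a full
  Bland–Altman agreement analysis.
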