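# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic test battery does and does not
demonstrate.

## Signal model and normalization

All analysis runs on uniformly sampled traces sharing one session rate
(default 200 Hz). Wearable devices sample far faster, but every algorithmic
quantity here lives below 10 Hz, so resampling at load (linear
interpolation) loses nothing; file I/O preserves float values bit-exactly
(shortest-repr formatting on write, round-trip parsing on read).

Both the gyro and the sEMG are normalized to the recording's absolute
maximum so that the fixed thresholds (T₁, T₂) are subject-independent. Two
guards keep this well defined on degenerate inputs:

* a recording with no locomotion at all (rest only) would blow sensor noise
  up to full scale; when a session carries a full-scale reference
  (`gyro_full_scale_dps` in its meta, emitted by the generator) and the
  recorded maximum stays below 20% of it, the reference is used instead;
* an sEMG trace that vanishes after the 3 Hz high-pass (pure DC or drift)
  is not normalized — the near-zero rectified trace is smoothed as-is, so
  the envelope is ≈ 0 rather than amplified numerical dust. All-zero traces
  are rejected outright.

Offline analysis normalizes over the full recording. The streaming path
freezes the constant on a calibration prefix (default 10 s); when that
prefix contains the subject's normal walking, the constant coincides with
the recording maximum and the two paths agree exactly.

## Preprocessing

Envelope chain, in this order: high-pass 3 Hz → full-wave rectification →
normalization to the rectified maximum → low-pass 10 Hz. Filters are
4th-order Butterworth, applied forward-backward (zero phase) offline so
envelope maxima stay aligned with gyro events, or single-pass in causal
mode. Low-pass ringing outside [0, 1] is clipped. Because normalization
precedes the low-pass, the envelope peak is typically slightly below 1.

The smoothed gyro uses a centered moving average of 0.1 s (well below the
~200 ms FOG window scale, well above the sensor noise scale), shrink-to-
valid at the edges; for even windows the kernel leans one sample into the
past. A separate zero-phase 3 Hz low-pass ("gait view") exists for visual
inspection only.

## Detection

Windowing semantics are exact and half-open: a window opens at the first
sample with ABS > T₁ following a sample at or below T₁ (or at sample 0),
closes at the next sample at or below T₁, and an unterminated trailing
window is dropped offline (held open in streaming). Windows shorter than
50 ms are threshold chatter and discarded — hardware noise floors make this
pruning implicit on real devices.

Stance rejection: min(gyro̅) ≤ T₂ = −0.4 marks the deep stance lobe of a
regular step; R is not computed there. R's denominator is floored at 1e−6
(normalized units) so a silent muscle gives a finite, very large R instead
of a division by zero. A tie at the demarcation level (R = 3) counts as
regular: the detector's smaller error class is false alarms, and an
explicit rule is needed either way.

Episode aggregation (our addition — per-step classification is the primary
output): maximal runs of FOG windows with inter-window gaps ≤ 1 s and at
least 2 members. Note that when distinct freeze phenotypes follow each
other without a 1 s gap they merge into one episode, whose pooled spectrum
then reflects the mixture.

The streaming detector is a sample-by-sample state machine over the
normalized (ABS, gyro̅, envelope) streams; every per-window quantity uses
only samples inside the window (order 200 ms during FOG), so streamed and
offline results are identical on identical normalized input, chunking
aside. Filter causality and normalization provenance are configured
independently of chunked replay.

## Phenotype stage

Pipeline per episode and leg: envelope × normalized gyro product → 2 Hz
linear-phase FIR (group delay compensated, unity DC gain) → right − left →
one-sided PSD → PI = max / geometric mean over (0, 2] Hz. The FIR and the
subtraction are both linear and time-invariant, so their order is
irrelevant; the tests assert this.

Numerical choices:

* FIR: 301 taps at 200 Hz. This keeps sub-1 Hz content within 1% of unity
  gain while attenuating 5 Hz by over 40 dB; a ~100-tap design at this rate
  smears its transition band across several hertz and meets neither figure.
* PSD: Welch (4 s Hann segments, 50% overlap) when the episode holds at
  least two segments, otherwise a plain boxcar periodogram without
  detrending — the latter satisfies Parseval exactly, which the tests use.
* The index band excludes the DC bin: the product has a systematic offset
  (envelope ≥ 0) that would otherwise dominate the maximum and deflate PI.
  Bins are floored at 1e−12 inside the logarithm.
* Episodes shorter than 2 s are refused (PI on a handful of spectral bins
  is noise); the agenda report leaves PI blank for them.
* Decision level PI ≥ 20 → shuffling: roughly the geometric midpoint of
  the two class scales (shuffling of order 10², trembling of order 3),
  rounded, and exposed in the config.
* The TA device feeds this stage; the phenotype information lives in the
  leg kinematics and the TA burst pattern.

## Muscle activity stage

The type trace is the zero-phase 10 Hz low-pass of the *raw* sEMG (the
hardware band of such devices starts low enough that the 0.5–10 Hz content
survives), normalized by its interior absolute maximum — the first and last
250 ms are excluded so filter edge transients cannot set the scale — and
clipped to [−1, 1]. Labels use a ±0.05 deadband: above it contraction,
below it stretching, inside it quiescent; the raw sign alone is
noise-fragile at zero crossings. If the sub-10 Hz band carries less than
1% of the signal power there is no physiological low-frequency component to
sign — only filtered noise, which normalization would push past any
deadband — and the trace is labelled quiescent throughout.

Ensemble averaging cuts [anchor, anchor + 1 s) segments (1 s covers a full
cycle at pathological cadence), time-normalizes them to 200 points by
linear interpolation, and reports the pointwise mean ± SD. Anchors default
to detector window starts; anchors too close to the trace end are skipped
and counted.

## Synthetic generator

The generator encodes described signal morphology, not biomechanics; its
defaults are the study conditions of the test battery and are never tuned
per test.

* **Regular gait** (cycle 1.2 s, legs half a cycle apart): per cycle one
  positive raised-cosine swing lobe (nominal 250 dps, width 0.35 s), a
  0.1 s near-zero gap, then a negative stance lobe at 65% of the swing
  amplitude (width 0.4 s). The gaps matter: ABS must fall below T₁ between
  the lobes for the swing and stance windows to separate, which on real
  signals happens during double support. With stance at ≥ half the swing
  amplitude the normalized stance minima stay below T₂ even under the
  ±10% per-cycle amplitude jitter. TA sEMG: bursts at swing onset and
  termination framing a quiet mid-swing (modulation floor 0.05), plus
  moderate toe-off activity; GC: one toe-off burst under the stance lobe.
* **Shuffling** (1.6 Hz): sinusoidal gyro at 15% of full scale (minima far
  above T₂), one sEMG burst per shuffle peaking at the gyro minimum
  (modulation 0.35 → 0.7 of the regular burst — the muscle stays partly
  active between bursts, which is what keeps R below 3 even in the
  positive gyro half-cycles), legs in antiphase; TA type component
  positive-oscillating, GC mildly negative.
* **Trembling**: band-limited (2–6 Hz) aperiodic zero-mean gyro noise at
  8% of full scale, independent per leg; sustained moderate TA activity
  with an alternating-sign 1.5 Hz type component; GC at very low intensity
  with a tonically negative type component (the toe-off deficit).
* **Rest**: gyro sensor noise (0.12 dps RMS) and an sEMG noise floor.

Raw sEMG is an amplitude-modulated 20–80 Hz Gaussian carrier plus the
additive low-frequency type component; the envelope chain recovers the
modulation, the type filter the signed component. Segment edges carry 50 ms
cosine ramps so concatenation creates no discontinuities. Everything is
drawn from one seeded generator in fixed order, so sessions are
bit-reproducible.

What the generator does **not** emulate: inter-subject amplitude diversity,
electrode placement effects, motion artifacts, hum, turning, festination,
gradual freeze onset/offset, or any biomechanical coupling between the
legs beyond the scripted phase relations. Passing tests therefore show
that the algorithms implement their contracts and separate the scripted
morphologies with margin — not clinical performance on patients.

## Problem sizes in tests and acceptance

The step-level statistics pool 10 freeze-heavy sessions (~31 s of freezing
each, ≈ 2000 FOG step attempts over both legs) and 10 one-minute walks
(≈ 1000 regular steps); phenotype separation uses 30 shuffling and 20
trembling annotated episodes of 8–14 s. Oracle equivalence checks the
window segmentation against a per-sample linear scan on 1000 random traces
of 2 s each. The whole suite and the acceptance script each run in seconds
on one CPU.

## Known limitations

* Global normalization is inherently offline; the calibration-prefix
  streaming variant assumes the prefix captures the subject's full dynamic
  range, and under-scaled constants inflate every downstream threshold
  comparison.
* Episode aggregation can merge adjacent distinct phenotypes (see above);
  a changepoint split of long episodes is future work.
* The contraction/stretching sign convention for the low-frequency sEMG
  component is adopted as given, not re-validated physiologically.
* The turning annotation label exists in the vocabulary but the generator
  does not synthesize turning; turning windows in real data fall into the
  evaluation's "unassigned" tally rather than either error class.
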