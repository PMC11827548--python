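# Methods

This note documents the models, estimators and numerical choices behind
`caninesleep`, and what the synthetic-data generator does and does not
emulate.

## Sleep scoring and macrostructure

Hypnograms are ordered stage labels on fixed epochs (20 s offline). The
canine scoring scheme has four stages — wakefulness (W), drowsiness (D),
non-REM (N), REM (R) — with drowsiness scored in its own right because the
wake/sleep transition is gradual in carnivores. That ambiguity motivates
the dual anchoring used throughout: variables suffixed `1` anchor sleep
onset at the first drowsiness epoch, variables suffixed `2` at the first
non-REM epoch.

The nine exported variables are sleep efficiency, relative wake duration,
WASO1, WASO2, Sleep Latency 1, Sleep Latency 2, and relative drowsiness /
non-REM / REM durations. Conventions:

* **Sleep efficiency** counts D, N and R epochs as sleep by default.
  Typical afternoon dog naps spend a quarter of the recording in
  drowsiness; excluding it would push reported efficiencies far below the
  values conventionally reported for this protocol. The switch
  `drowsiness_is_sleep=False` gives the stricter reading.
* **WASO** counts only W epochs strictly after the anchor; drowsiness after
  sleep onset is not wake.
* Latencies are minutes from recording start (epoch 0). The denominator of
  all relative durations is the full recording; no setup time is excised.
* A stage that never occurs yields NaN for its latency and its WASO (REM
  can be genuinely absent from a nap); NaN is deliberately distinct from 0.

## Stage-restricted spectra

Power spectral densities use 4-s windows with 50 % overlap and a Hann
taper; the 4-s length makes the FFT grid exactly 0.25 Hz, so a "bin" is a
single FFT coefficient. The analysis grid is 1.00–30.00 Hz inclusive
(117 bins). Relative power divides each bin by the summed power over the
grid; band fractions sum bins over delta [1, 4), theta [4, 8), alpha
[8, 12) and beta [12, 30] Hz — half-open left edges so the four bands
partition the grid (the shared-endpoint notation "1–4 / 4–8 Hz" is
otherwise ambiguous).

Windows must lie wholly inside a contiguous run of same-stage epochs
(stage purity: windows straddling transitions are discarded) and wholly
outside artifact intervals. Artifact intervals are snapped outward to the
4-s subepoch grid aligned to recording start, matching the granularity of
manual rejection. Each window is mean-removed before tapering (recording
hardware high-passes at 0.016 Hz, which leaves near-DC drift). Wake is
never analyzed spectrally (muscle-tone artifact). With zero eligible
windows the profile is all-NaN with `n_windows = 0` rather than an error.

**Hann leakage is a physical property of this estimator, not a defect**: a
sinusoid centered on bin k carries amplitude weights (¼, ½, ¼) on bins
(k−1, k, k+1), i.e. exactly 2/3 of its relative power in its own bin and
1/6 in each neighbor. Localization claims should therefore be made at the
mainlobe (bin ± 1 neighbor, > 0.999) or band level, never at the
single-coefficient level; the test suite pins both numbers.

## Adaptive spindle detection

Spindles are sigma-band bursts of non-REM EEG lasting at least 0.5 s. The
detector operates on one channel at a time and only ever looks at
artifact-free non-REM samples:

1. Band-pass 9–16 Hz (4th-order Butterworth, forward–backward), then an
   RMS envelope over a 0.125-s sliding window.
2. **Initial detection**: maximal eligible runs where the envelope exceeds
   mean + 2 SD of the eligible-non-REM envelope, lasting ≥ 0.5 s. On
   spindle-free noise this criterion fires essentially never (sustained
   half-second excursions above 2 SD of a ~0.15-s-correlated envelope),
   which is why zero initial detections simply returns an empty list.
3. **Criterion refit**: Gaussian means and SDs of event peak amplitude and
   event frequency are fitted by maximum likelihood. The first amplitude
   fit corrects for truncation (initial detections only ever show
   amplitudes above threshold) by maximizing the left-truncated-normal
   likelihood; without the correction the fitted SD is biased low and the
   acceptance window rejects genuine low-amplitude events. Event frequency
   is the reciprocal of twice the mean zero-crossing interval of the
   band-passed signal, measured over the run's core (envelope ≥ half its
   peak) so the estimate is not diluted by background at the run's skirts.
4. **Re-detection**: candidate runs are taken above a lower boundary
   threshold (mean + 0.5 SD) — so an event's full extent counts toward the
   0.5-s minimum, not merely its supra-threshold peak — and accepted iff
   peak amplitude AND frequency fall within mean ± 2.5 SD of the fitted
   distributions. Steps 3–4 iterate (≤ 10 times) until the run set is
   stable (relative symmetric difference < 0.01). Runs closer than 0.1 s
   are merged before feature extraction; runs are clipped at
   non-REM/artifact boundaries and kept if ≥ 0.5 s survives.

Parameter defaults (all exposed in `DetectorParams`) are a documented
reconstruction of this family of detectors, not a replication of any
specific implementation: sigma band 9–16 Hz, envelope window 0.125 s,
initial k = 2.0, boundary k = 0.5, acceptance z = 2.5, merge gap 0.1 s.
The acceptance width of ±2.5 SD was chosen over the textbook ±2 SD
because a two-sided 2-SD window on two features discards ~9 % of genuine
events even under perfect fits, biasing density low; at ±2.5 SD background
runs remain excluded by a wide margin (their amplitudes sit > 5 SD below
the fitted spindle distribution in all synthetic conditions tested). There
is no upper duration limit.

Classification is fast iff mean frequency ≥ 13 Hz (boundary inclusive).
Density is events per minute of **artifact-free** non-REM (the artifact
exclusion applies to both numerator and denominator); trait density is the
unweighted mean of a dog's per-recording densities.

## Cue scheduling

The online rule is replayed deterministically over 30-s stage estimates:
a bout starts at the first instant after two consecutive non-REM epochs;
cues lie on a 5-s grid anchored at bout onset (first cue at t + 0 — "every
5 s" leaves the phase free and onset anchoring is the simplest
deterministic reading); any non-NREM epoch aborts the bout instantaneously
at the epoch boundary; the criterion must then be met afresh, and cueing
may resume. The "~5 min" of stimulation is a hard 300-s cumulative cap
across bouts (each cue accrues one inter-cue interval). The online stream
is a separate, coarser timeline from the offline 20-s hypnogram; no
resampling is performed between them — `validate_schedule` audits cue
times against the offline scoring after the fact.

## Behavioral statistics

* **Cueing benefit** = (proportion correct among cued test trials) −
  (proportion correct among cued baseline trials); cued trials of both
  sides pooled. Undefined (NaN) if a phase has no cued trials.
* **Latency reduction**, per correctness class, = mean baseline latency /
  mean test latency. The ratio of per-class means (not a mean of
  per-trial ratios) because baseline and test trials are unpaired.
* **Relative latency reduction** = correct-class reduction /
  incorrect-class reduction; invariant under a global rescaling of all
  latencies. Dogs with an empty class in either phase are NaN and dropped
  from correlations (with a logged count).
* The ratio-of-means estimator is upward biased at small class counts
  (Jensen: E[1/x̄] > 1/E[x̄]); at ~6 trials per class with lognormal
  sd_log 0.5 the bias on the relative reduction is ≈ +10 %. The test
  suite checks the generator's Monte-Carlo mean against an independent
  simulation of the same estimator rather than against the naive
  generative ratio.
* **Bin-by-bin scan**: Pearson r of a per-subject outcome against relative
  power at each bin, two-sided p from the t transform with n − 2 df,
  missing subjects excluded bin-wise, per-bin n recorded (critical r then
  varies by bin); zero-variance bins yield NaN.
* **Rüger areas**: maximal runs of contiguous bins with p < α (grid edges
  and NaN bins act as boundaries). An n-bin area is significant iff
  #(p < α/2) ≥ n/2 and #(p < α/3) ≥ n/3 — "these results" read as all
  members of the area; comparisons are exact (integer cross-
  multiplication, strict inequalities at the p thresholds), so a single
  bin with p < α/3 forms a significant area by itself.

## Synthetic-data generator

The generator is the package's ground-truth instrument; its defaults are
the study conditions it emulates (16 dogs, 2-h recordings at 1,024 Hz on
Fz/Cz/F7/F8, 20-s epochs), and every output is a pure function of
(parameters, seed) — sub-seeds are spawned per dog from one NumPy
`SeedSequence`, signals are stored at float32 precision so disk round-trips
are bit-exact.

* **Hypnograms**: semi-Markov chain with exponential dwell (means in
  minutes per stage, rounded to whole epochs, minimum one) and a
  transition matrix under which wake always enters drowsiness first and
  non-REM is reached only through drowsiness. Default dwells
  (W 7, D 5, N 11, R 5 min) put the dwell-weighted stationary occupancy at
  roughly 17/24/51/8 %, matching afternoon-nap dog polysomnography.
  Stages with zero dwell mass are unreachable (an all-wake chain is the
  degenerate case).
* **EEG**: per-channel 1/f-amplitude Gaussian background (flat below 1 Hz)
  normalized to 10 µV RMS, plus stage oscillations as amplitude-modulated
  sinusoids — drowsiness 7.5 Hz at 0.8× RMS, non-REM 1.5 Hz delta at
  1.5× RMS, REM 5 Hz at 0.3× RMS. Spindles are Hann-windowed sinusoids:
  duration uniform on [0.5, 1.5] s, frequency Gaussian per subtype
  (slow 11 ± 0.5 Hz, fast 14.5 ± 0.5 Hz, redrawn if a draw crosses the
  13 Hz split so injected subtype labels stay consistent), peak amplitude
  3× background RMS. Exactly round(density × non-REM minutes) events per
  subtype are placed uniformly in non-REM runs, non-overlapping with a
  0.5-s margin, clear of artifacts, independently for Fz and Cz. Artifact
  subepochs (4 s, flagged i.i.d. at rate 0.05) carry 5×-RMS noise.
* **Behavior**: 15 baseline + 15 test trials per dog; baited locations
  cycle the fixed semirandom blocks ABC, ACB, CAB, CBA, BAC (each location
  baited exactly five times per phase, never twice in a row; A = left,
  B = center, C = right). The cued side alternates with dog parity.
  Accuracy is Bernoulli on a logistic scale (baseline log-odds −0.4,
  ≈ 0.40; cued shift +0.5 applied to cued test trials). Latencies are
  lognormal (mean 5.25 s, sd_log 0.5) with post-sleep draws divided by the
  correct/incorrect factors (defaults 2.0 / 1.25) and floored at 0.3 s for
  physical plausibility.
* **Study coupling**: in `gen_study`, each dog's trait fast density and
  correct-trial latency factor are jointly lognormal — log-density spread
  0.35, log-effect spread 0.8, correlation 0.6. The effect spread was set
  from the reported heterogeneity of this measure in real dogs (relative
  reductions ranging well below and above 1, with only ~2/3 of animals
  showing the majority direction); `gen_behavior` called on its own keeps
  the shared factors so its marginal behavior is exactly the configured
  effect.
* The TMR recording's cue log is produced by running the real scheduler on
  a 30-s stream read off the hypnogram at epoch midpoints; adaptation
  recordings carry empty cue logs.

**What the generator does not emulate**: EMG/ECG/respiration channels and
their artifacts, eye movements, spindle waveform asymmetries or
frequency chirps, within-night density dynamics, first-night effects, and
any dependence of real dogs' spindle amplitude distributions (the
amplitude settings are placeholders, not calibrated claims). Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated signal model, not field performance on real recordings.

## Problem sizes and I/O

Tests and the acceptance script run the same code paths at reduced problem
sizes chosen as package defaults for validation work: detector-recovery
runs use 45-min recordings at 256 Hz (~40 non-REM minutes, so the lowest
injected density still yields ~20 events), and the 200-replicate
end-to-end study uses 16 dogs × two 4-min recordings at 128 Hz (the lowest
rate that resolves the sigma band). The full-scale defaults remain on
`SimParams`.

Signals are written either as EDF (16-bit, one 1-s record per second,
per-channel symmetric physical range, so quantization error is bounded by
range/2¹⁶) or as a float32 matrix + JSON header pair. The EDF writer is
minimal by design and is validated in the tests against MNE's independent
EDF reader; hypnograms, artifact intervals, cue logs and trial tables are
plain CSV (trials are re-read with round-trip float parsing so latencies
survive exactly).

## Known limitations

* The detector's absolute event boundaries depend on the envelope
  smoothing width; durations near the 0.5-s minimum are measured slightly
  short, so a few events with true duration just above 0.5 s are lost
  (visible as the residual −5 to −10 % density bias).
* Rüger's procedure controls error at the area level only; per-bin
  inference inside an accepted area is not corrected.
* The GLMM analyses used alongside these statistics in practice are out of
  scope by design: the package exports tidy per-trial and per-dog tables
  for any external mixed-model tool.
* `validate_schedule` audits cue times against the offline hypnogram but
  cannot model scorer disagreement between the online and offline
  timelines; flags are expected when the two disagree.
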