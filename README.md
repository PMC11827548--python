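# caninesleep

Analysis pipeline for canine polysomnography and targeted memory
reactivation (TMR) experiments: sleep-macrostructure scoring variables,
stage-restricted EEG spectra, adaptive sleep-spindle detection,
non-REM-gated cue scheduling, and the behavioral statistics of a two-phase
visuospatial learning task — together with a fully seeded synthetic-data
generator so every stage can be validated against known ground truth.

It is written for sleep/cognition researchers working with dog EEG
(family-dog polysomnography protocols with electrodes Fz, Cz, F7, F8
referenced to G2, sampled at 1,024 Hz and scored on 20-s epochs into
wakefulness, drowsiness, non-REM and REM), but every component takes plain
NumPy arrays, `Hypnogram` objects and pandas tables, so it applies to any
four-stage scoring scheme.

## What it computes

**Macrostructure** (`caninesleep.hypnogram`) — the nine standard variables
from a 20-s-epoch hypnogram: sleep efficiency (%), relative wake duration
(%), WASO1/WASO2 (wakefulness after sleep onset anchored at first
drowsiness / first non-REM, min), Sleep Latency 1/2 (min), and relative
drowsiness / non-REM / REM durations (%). Drowsiness counts as sleep in the
efficiency numerator (configurable), reflecting its status as a scored
stage in carnivores.

**Spectra** (`caninesleep.spectral`) — per-stage power spectral densities of
a bipolar derivation (e.g. Fz−Cz) from 50 %-overlapping, Hann-tapered 4-s
windows lying wholly inside same-stage runs and outside artifact intervals
(snapped to the 4-s manual-rejection grid). Relative power per 0.25 Hz bin
on the 1–30 Hz grid (117 bins),

&nbsp;&nbsp;&nbsp;&nbsp;relP(f) = P(f) / Σ_{1–30 Hz} P(f′),

with band fractions over delta 1–4, theta 4–8, alpha 8–12 and beta
12–30 Hz.

**Spindles** (`caninesleep.spindles`) — adaptive amplitude–frequency
detection restricted to artifact-free non-REM: an initial threshold on the
9–16 Hz RMS envelope (mean + 2 SD, sustained ≥ 0.5 s) seeds maximum-
likelihood Gaussian fits of event amplitude and frequency, which define the
acceptance windows for a re-detection pass, iterated to convergence.
Events are split at 13 Hz (fast ≥ 13 Hz), summarized as densities in
events per minute of artifact-free non-REM, and averaged across a dog's
recordings into a trait density.

**Cue scheduling** (`caninesleep.cueing`) — deterministic replay of the
online TMR rule over 30-s stage estimates: cueing starts after two
consecutive non-REM epochs, repeats every 5 s, aborts on any non-NREM
epoch, and cumulative stimulation is capped at 300 s; plus an offline audit
against the scored hypnogram.

**Behavior and inference** (`caninesleep.stats`) — cueing benefit
(post-sleep − baseline accuracy of cued trials), latency reduction per
correctness class (mean pre / mean post latency), relative latency
reduction (correct / incorrect class ratio — scale-invariant), bin-by-bin
Pearson scans of an outcome against relative power, and Rüger's area
correction: maximal runs of p < 0.05 bins accepted as a whole iff at least
half the members are below α/2 and a third below α/3.

**Synthetic studies** (`caninesleep.simulate`) — semi-Markov hypnograms,
1/f EEG with stage oscillations, Hann-windowed spindle bursts at known
densities, artifact subepochs, cue logs and per-dog behavior with
configurable latency effects, including a study-level coupling between
trait spindle density and the latency effect for end-to-end power checks.

## Worked example

```bash
python examples/spindle_detection_example.py
```

```
artifact-free non-REM: 19.7 min
injected events: 82, detected: 75
  slow: injected 2.00/min, recovered 1.93/min (38 events)
  fast: injected 2.00/min, recovered 1.88/min (37 events)
```

25 minutes of synthetic mostly-non-REM EEG carry 82 injected spindle bursts
(11 Hz slow and 14.5 Hz fast, ≥ 0.5 s, peak amplitude 3× the background
RMS). The detector recovers both densities within a few percent; each
recovered value is events per minute of artifact-free non-REM sleep, the
denominator used for all density comparisons. The other scripts in
`examples/` walk through macrostructure, spectra, cue scheduling, behavior
statistics and a full 16-dog study in the same style.

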