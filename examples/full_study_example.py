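"""End-to-end synthetic TMR study: spindle trait density vs learning.

Generates a 16-dog study (one adaptation and one TMR recording per dog, plus
behavior) in which each dog's trait fast-spindle density and its correct-trial
latency speed-up are coupled at r = 0.6 on the log scale.  The full pipeline
— detect spindles, compute per-recording densities, average within dog, score
behavior — then estimates that correlation from the data alone.

Recordings are kept short (4 min at 128 Hz, mostly non-REM) so the example
runs in about a second; the generator's defaults emulate the full 2-h,
1,024 Hz protocol.
"""

import numpy as np
from scipy.stats import pearsonr

from caninesleep import (
    ArtifactMask,
    averaged_density,
    behavior_summary,
    density,
    detect_spindles,
    stage_minutes,
)
from caninesleep.hypnogram import NREM
from caninesleep.simulate import SimParams, gen_study

params = SimParams(
    n_dogs=16, recording_minutes=4.0, sample_rate_hz=128.0,
    channels=("Fz",), spindle_channels=("Fz",),
    stage_dwell_means={"W": 0.2, "D": 0.2, "N": 30.0, "R": 0.0},
    artifact_rate=0.02, seed=123,
)
bundle = gen_study(params)

trait = []
for dog in bundle.dogs:
    per_recording = []
    for rec, truth in (dog.adaptation, dog.tmr):
        mask = ArtifactMask(tuple(truth.artifact_intervals))
        events = detect_spindles(rec.channel("Fz"), params.sample_rate_hz,
                                 truth.hypnogram, mask, channel="Fz")
        nrem_min = stage_minutes(truth.hypnogram, NREM, mask)
        per_recording.append(density(events, nrem_min, subtype="fast").events_per_min)
    trait.append(averaged_density(per_recording))

beh = behavior_summary(bundle.trials)
rll = beh["relative_latency_reduction"].to_numpy()
r, p = pearsonr(trait, rll)

print(f"dogs: {len(bundle.dogs)}; TMR cues per dog: "
      f"{np.mean([d.cue_schedule.n_cues for d in bundle.dogs]):.0f} on average")
print("trait fast density (events/min):", np.round(trait, 2))
print("relative latency reduction:     ", np.round(rll, 2))
print(f"\nPearson r(trait density, relative latency reduction) = {r:.3f} (p = {p:.3f})")
print(
    "\nThe injected coupling is r = 0.6 on the log scale; detection noise and\n"
    "behavioral sampling attenuate the estimate, but across replicate studies\n"
    "its sign is recovered essentially always (see scripts/acceptance.py)."
)
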