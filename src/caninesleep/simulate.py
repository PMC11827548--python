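"""Synthetic canine polysomnography and behavior with known ground truth.

Everything downstream — macrostructure, spectra, spindle detection, cue
scheduling, behavior statistics — is exercised on data generated here, so
each generator records the ground truth it injected (hypnogram, spindle
event list, artifact intervals, per-dog trait densities and latency effects)
for parameter-recovery tests.

The model is deliberately minimal: 1/f background noise per channel, stage
oscillations as amplitude-modulated sinusoids (alpha-theta in drowsiness,
delta in non-REM, low-amplitude mixed activity in REM), sleep spindles as
Hann-windowed sinusoids whose per-event frequency is drawn from the slow or
fast subtype's Gaussian, hypnograms from a semi-Markov chain over
wake/drowsiness/NREM/REM with configurable dwell means, artifacts as flagged
4-s subepochs carrying high-amplitude noise, and behavior as Bernoulli
accuracy plus lognormal latencies with a configurable post-sleep speed-up
that is larger for correct trials.

Determinism: the full output is a pure function of (params, seed); per-dog
sub-seeds are spawned from one NumPy SeedSequence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .cueing import CueParams, CueSchedule, schedule_cues
from .hypnogram import DROWSINESS, NREM, REM, STAGES, WAKE, Hypnogram, write_hypnogram
from .io import Recording, write_artifacts_csv, write_cue_log, write_edf, write_raw_pair, write_trials
from .spindles import FAST_THRESHOLD_HZ, SpindleEvent

__all__ = [
    "SimParams",
    "GroundTruth",
    "DogData",
    "StudyBundle",
    "DEFAULT_TRANSITIONS",
    "DEFAULT_DWELL_MIN",
    "BAIT_BLOCKS",
    "gen_hypnogram",
    "gen_eeg",
    "gen_behavior",
    "gen_study",
]


class SimulationError(ValueError):
    pass


#: semi-Markov stage transition probabilities (wake always enters drowsiness
#: first; non-REM is reached only through drowsiness)
DEFAULT_TRANSITIONS: dict[str, dict[str, float]] = {
    WAKE: {DROWSINESS: 1.0},
    DROWSINESS: {NREM: 0.8, WAKE: 0.2},
    NREM: {REM: 0.35, DROWSINESS: 0.4, WAKE: 0.25},
    REM: {NREM: 0.5, DROWSINESS: 0.3, WAKE: 0.2},
}

#: mean stage dwell times in minutes, tuned so stationary occupancy roughly
#: matches afternoon-nap dog polysomnography (wake ~17 %, drowsiness ~24 %,
#: non-REM ~51 %, REM ~8 %)
DEFAULT_DWELL_MIN: dict[str, float] = {WAKE: 7.0, DROWSINESS: 5.0, NREM: 11.0, REM: 5.0}

#: fixed semirandom baited-location order: five 3-trial blocks, each location
#: baited exactly five times per 15-trial phase, never twice in a row
BAIT_BLOCKS = ("ABC", "ACB", "CAB", "CBA", "BAC")
_LOCATION = {"A": "left", "B": "center", "C": "right"}


@dataclass(frozen=True)
class SimParams:
    """Generator configuration (defaults are the study conditions).

    A recording is a 2-h afternoon polysomnography session sampled at
    1,024 Hz on four EEG channels referenced to G2 and scored on 20-s
    epochs.  ``spindle_amp_factor`` scales spindle peak amplitude in
    multiples of the broadband background RMS; ``cueing_latency_effect`` is
    the multiplicative pre/post latency speed-up for (correct, incorrect)
    trials; ``density_effect_corr`` couples each dog's trait fast-spindle
    density to its correct-trial latency effect on the log scale.
    """

    n_dogs: int = 16
    recording_minutes: float = 120.0
    epoch_s: float = 20.0
    sample_rate_hz: float = 1024.0
    channels: tuple[str, ...] = ("Fz", "Cz", "F7", "F8")
    spindle_channels: tuple[str, ...] = ("Fz", "Cz")
    stage_dwell_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DWELL_MIN)
    )
    transitions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRANSITIONS.items()}
    )
    background_rms_uv: float = 10.0
    spindle_density_slow: float = 2.0
    spindle_density_fast: float = 2.0
    spindle_freq_means: tuple[float, float] = (11.0, 14.5)  # (slow, fast) Hz
    spindle_freq_sds: tuple[float, float] = (0.5, 0.5)
    spindle_amp_factor: float = 3.0
    spindle_dur_range: tuple[float, float] = (0.5, 1.5)
    artifact_rate: float = 0.05
    cueing_latency_effect: tuple[float, float] = (2.0, 1.25)  # (correct, incorrect)
    latency_effect_sd_log: float = 0.8
    density_spread_sd_log: float = 0.35
    density_effect_corr: float = 0.6
    accuracy_logit_params: tuple[float, float] = (-0.4, 0.5)  # base log-odds, cued shift
    latency_mean_s: float = 5.25
    latency_sd_log: float = 0.5
    latency_floor_s: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recording_minutes <= 0:
            raise SimulationError("recording_minutes must be positive")
        if self.epoch_s <= 0:
            raise SimulationError("epoch_s must be positive")
        if self.spindle_dur_range[0] < 0.5:
            raise SimulationError("minimum spindle duration is 0.5 s")
        if self.spindle_density_slow < 0 or self.spindle_density_fast < 0:
            raise SimulationError("spindle densities must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise SimulationError("artifact_rate must lie in [0, 1]")
        if self.n_dogs < 1:
            raise SimulationError("need at least one dog")

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """What one generated recording actually contains."""

    hypnogram: Hypnogram
    spindle_events: list[SpindleEvent]
    artifact_intervals: list[tuple[float, float]]
    nrem_minutes: float
    injected_density_slow: float
    injected_density_fast: float


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

def gen_hypnogram(params: SimParams, seed: int) -> Hypnogram:
    """Semi-Markov hypnogram on 20-s epochs.

    Dwell times are exponential with the configured per-stage means (rounded
    to whole epochs, minimum one); transitions follow ``params.transitions``
    restricted to stages with positive dwell mass.  The chain starts awake,
    so wake precedes the first drowsiness and (under the default transitions)
    drowsiness precedes the first non-REM epoch.
    """
    rng = np.random.default_rng(seed)
    n_epochs = int(round(params.recording_minutes * 60.0 / params.epoch_s))
    if n_epochs < 1:
        raise SimulationError("recording too short for a single epoch")
    dwell = params.stage_dwell_means
    labels: list[str] = []
    state = WAKE if dwell.get(WAKE, 0) > 0 else next(s for s in STAGES if dwell.get(s, 0) > 0)
    while len(labels) < n_epochs:
        mean_min = dwell[state]
        n_dwell = max(1, int(round(rng.exponential(mean_min) * 60.0 / params.epoch_s)))
        labels.extend([state] * n_dwell)
        targets = {
            s: p for s, p in params.transitions.get(state, {}).items() if dwell.get(s, 0) > 0
        }
        if not targets:
            # absorbing state (e.g. all dwell mass on wake)
            labels.extend([state] * (n_epochs - len(labels)))
            break
        names = sorted(targets)
        probs = np.array([targets[s] for s in names])
        state = rng.choice(names, p=probs / probs.sum())
    return Hypnogram(labels=tuple(labels[:n_epochs]), epoch_s=params.epoch_s)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, fs: float, rms: float) -> np.ndarray:
    """1/f amplitude-shaped Gaussian noise with the requested RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(f, 1.0))  # flat below 1 Hz
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x * (rms / np.sqrt(np.mean(x * x)))


_STAGE_OSC = {
    # stage -> (frequency Hz, amplitude in multiples of background RMS)
    DROWSINESS: (7.5, 0.8),  # alpha-theta
    NREM: (1.5, 1.5),  # delta
    REM: (5.0, 0.3),  # mixed low-amplitude
}


def _place_events(
    rng: np.random.Generator,
    n_events: int,
    durations: np.ndarray,
    nrem_runs_s: list[tuple[float, float]],
    blocked: list[tuple[float, float]],
    margin_s: float = 0.5,
) -> np.ndarray:
    """Uniformly place non-overlapping events inside NREM runs, away from
    blocked (artifact) intervals.  Returns onsets aligned to durations."""
    run_lens = np.array([b - a for a, b in nrem_runs_s])
    onsets = np.empty(n_events)
    placed: list[tuple[float, float]] = list(blocked)
    for i in np.argsort(durations)[::-1]:  # longest first eases packing
        dur = durations[i]
        for _ in range(10_000):
            w = np.maximum(run_lens - dur, 0.0)
            if w.sum() == 0:
                raise SimulationError("not enough non-REM time to place spindles")
            k = rng.choice(len(nrem_runs_s), p=w / w.sum())
            t0 = nrem_runs_s[k][0] + rng.uniform(0.0, run_lens[k] - dur)
            t1 = t0 + dur
            if all(t1 + margin_s <= a or b + margin_s <= t0 for a, b in placed):
                onsets[i] = t0
                placed.append((t0, t1))
                break
        else:
            raise SimulationError("could not place all spindle events (too dense)")
    return onsets


def gen_eeg(
    hypnogram: Hypnogram, params: SimParams, seed: int
) -> tuple[Recording, GroundTruth]:
    """Generate a multi-channel recording for one scored hypnogram.

    Each channel gets independent 1/f background plus stage oscillations;
    spindle bursts (Hann-windowed sinusoids) are injected independently into
    the midline channels (``params.spindle_channels``) at the configured
    slow/fast densities, wholly inside non-REM and clear of artifacts.  The
    returned ground truth lists every injected event.
    """
    if params.sample_rate_hz < 128:
        raise SimulationError(
            "sample rate below 128 Hz cannot resolve the spindle band"
        )
    if len(hypnogram) == 0:
        raise SimulationError("empty hypnogram")
    rng = np.random.default_rng(seed)
    fs = params.sample_rate_hz
    n = int(round(hypnogram.duration_s * fs))
    t = np.arange(n) / fs
    rms = params.background_rms_uv

    # artifact subepochs (4 s grid), shared by all channels
    n_sub = int(np.ceil(hypnogram.duration_s / 4.0))
    flags = rng.random(n_sub) < params.artifact_rate
    artifacts = [(4.0 * i, min(4.0 * (i + 1), hypnogram.duration_s)) for i in np.nonzero(flags)[0]]

    # non-REM runs in seconds, with artifact intervals blocked for placement
    nrem_runs = [
        (i0 * hypnogram.epoch_s, i1 * hypnogram.epoch_s) for i0, i1 in hypnogram.runs(NREM)
    ]
    nrem_minutes = sum(b - a for a, b in nrem_runs) / 60.0

    stage_masks = {s: hypnogram.sample_mask(s, fs, n) for s in (DROWSINESS, NREM, REM)}

    samples = np.empty((len(params.channels), n))
    events: list[SpindleEvent] = []
    for ci, ch in enumerate(params.channels):
        x = _pink_noise(rng, n, fs, rms)
        for stage, (f_osc, rel_amp) in _STAGE_OSC.items():
            m = stage_masks[stage]
            if m.any():
                am = 0.6 + 0.4 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
                x[m] += (rel_amp * rms) * am[m] * np.sin(
                    2 * np.pi * f_osc * t[m] + rng.uniform(0, 2 * np.pi)
                )

        if ch in params.spindle_channels and nrem_minutes > 0:
            for subtype, dens, f_mu, f_sd in (
                ("slow", params.spindle_density_slow, params.spindle_freq_means[0], params.spindle_freq_sds[0]),
                ("fast", params.spindle_density_fast, params.spindle_freq_means[1], params.spindle_freq_sds[1]),
            ):
                n_ev = int(round(dens * nrem_minutes))
                if n_ev == 0:
                    continue
                durs = rng.uniform(*params.spindle_dur_range, size=n_ev)
                freqs = rng.normal(f_mu, f_sd, size=n_ev)
                # keep each draw on its subtype's side of the 13 Hz split
                for k in range(n_ev):
                    while (freqs[k] >= FAST_THRESHOLD_HZ) != (subtype == "fast"):
                        freqs[k] = rng.normal(f_mu, f_sd)
                onsets = _place_events(
                    rng, n_ev, durs, nrem_runs,
                    blocked=artifacts + [(e.onset_s, e.end_s) for e in events if e.channel == ch],
                )
                for onset, dur, f_ev in zip(onsets, durs, freqs):
                    lo = int(round(onset * fs))
                    m_len = int(round(dur * fs))
                    tt = np.arange(m_len) / fs
                    burst = (
                        params.spindle_amp_factor
                        * rms
                        * hann(m_len)
                        * np.sin(2 * np.pi * f_ev * tt + rng.uniform(0, 2 * np.pi))
                    )
                    x[lo : lo + m_len] += burst[: max(0, n - lo)]
                    events.append(
                        SpindleEvent(
                            channel=ch,
                            onset_s=float(onset),
                            duration_s=float(dur),
                            mean_freq_hz=float(f_ev),
                            peak_amp_uv=float(params.spindle_amp_factor * rms),
                            subtype="fast" if f_ev >= FAST_THRESHOLD_HZ else "slow",
                        )
                    )

        # artifact segments carry high-amplitude noise
        for a, b in artifacts:
            lo, hi = int(round(a * fs)), min(int(round(b * fs)), n)
            x[lo:hi] += 5.0 * rms * rng.standard_normal(hi - lo)
        samples[ci] = x

    # storage precision: signals are float32 on disk, keep memory identical
    samples = samples.astype(np.float32).astype(np.float64)
    rec = Recording(
        channel_labels=list(params.channels), sample_rate_hz=fs, samples=samples
    )
    truth = GroundTruth(
        hypnogram=hypnogram,
        spindle_events=sorted(events, key=lambda e: (e.channel, e.onset_s)),
        artifact_intervals=artifacts,
        nrem_minutes=nrem_minutes,
        injected_density_slow=params.spindle_density_slow,
        injected_density_fast=params.spindle_density_fast,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _bait_order() -> list[str]:
    return [_LOCATION[c] for block in BAIT_BLOCKS for c in block]


def gen_behavior(
    params: SimParams, seed: int, latency_effects: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-dog behavioral trials: 15 baseline + 15 post-sleep test trials.

    Baited locations cycle the fixed semirandom blocks (each location baited
    exactly five times per phase); the cued side alternates with dog parity.
    Accuracy is Bernoulli on a logistic scale with a cued-trial shift applied
    post-sleep; latencies are lognormal with post-sleep values divided by the
    correct/incorrect speed-up factors (``latency_effects`` rows override the
    shared ``params.cueing_latency_effect`` per dog).
    """
    rng = np.random.default_rng(seed)
    base_logit, cued_shift = params.accuracy_logit_params
    sigma = params.latency_sd_log
    mu = np.log(params.latency_mean_s) - sigma**2 / 2.0
    order = _bait_order()
    rows = []
    for d in range(params.n_dogs):
        cued_side = "left" if d % 2 == 0 else "right"
        eff_c, eff_i = (
            latency_effects[d] if latency_effects is not None else params.cueing_latency_effect
        )
        for phase in ("baseline", "test"):
            for trial_index, loc in enumerate(order, start=1):
                if loc == "center":
                    cue_class = "center"
                else:
                    cue_class = ("cued_" if loc == cued_side else "uncued_") + loc
                is_cued = cue_class.startswith("cued_")
                logit = base_logit + (cued_shift if (is_cued and phase == "test") else 0.0)
                p = 1.0 / (1.0 + np.exp(-logit))
                correct = int(rng.random() < p)
                lat = rng.lognormal(mu, sigma)
                if phase == "test":
                    lat /= eff_c if correct else eff_i
                rows.append(
                    {
                        "dog_id": f"dog{d:02d}",
                        "phase": phase,
                        "trial_index": trial_index,
                        "cue_class": cue_class,
                        "correct": correct,
                        "latency_s": max(lat, params.latency_floor_s),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class DogData:
    dog_id: str
    cued_side: str
    trait_density_fast: float  # injected events/min, the dog's latent trait
    latency_effect_correct: float
    latency_effect_incorrect: float
    adaptation: tuple[Recording, GroundTruth]
    tmr: tuple[Recording, GroundTruth]
    cue_schedule: CueSchedule
    trials: pd.DataFrame


@dataclass
class StudyBundle:
    params: SimParams
    dogs: list[DogData]
    trials: pd.DataFrame


def gen_study(
    params: SimParams,
    out_dir: str | Path | None = None,
    edf: bool = False,
) -> StudyBundle:
    """Generate a full TMR study: per dog one adaptation recording (no cues)
    and one TMR recording with a cue log, plus the behavior table.

    Each dog's trait fast-spindle density and correct-trial latency effect
    are drawn jointly lognormal with correlation ``density_effect_corr`` on
    the log scale, so the pipeline's density-vs-latency-effect correlation
    has a known injected value.  With ``out_dir`` set, all external formats
    are written (float32+JSON signal pairs — EDF too when ``edf=True`` —
    hypnogram / artifact / cue-log CSVs per recording and one trials CSV).
    """
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(params.n_dogs + 1)
    rho = params.density_effect_corr
    sig_d = params.density_spread_sd_log
    tau = params.latency_effect_sd_log

    dogs: list[DogData] = []
    effects = np.empty((params.n_dogs, 2))
    for d in range(params.n_dogs):
        crng = np.random.default_rng(children[d])
        z1 = crng.standard_normal()
        z2 = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * crng.standard_normal()
        dens_fast = params.spindle_density_fast * np.exp(sig_d * z1 - sig_d**2 / 2.0)
        eff_c = params.cueing_latency_effect[0] * np.exp(tau * z2)
        eff_i = params.cueing_latency_effect[1]
        effects[d] = (eff_c, eff_i)

        dog_params = params.replace(spindle_density_fast=float(dens_fast))
        seeds = crng.integers(0, 2**31 - 1, size=4)
        rec_a = gen_eeg(gen_hypnogram(dog_params, int(seeds[0])), dog_params, int(seeds[1]))
        hyp_t = gen_hypnogram(dog_params, int(seeds[2]))
        rec_t = gen_eeg(hyp_t, dog_params, int(seeds[3]))

        # online 30-s stage stream read off at epoch midpoints
        n_online = int(hyp_t.duration_s // 30)
        stream = [hyp_t.stage_of_time(30.0 * k + 15.0) for k in range(n_online)]
        cued_side = "left" if d % 2 == 0 else "right"
        schedule = schedule_cues(stream, CueParams(), cue_label=f"cued_{cued_side}")

        dogs.append(
            DogData(
                dog_id=f"dog{d:02d}",
                cued_side=cued_side,
                trait_density_fast=float(dens_fast),
                latency_effect_correct=float(eff_c),
                latency_effect_incorrect=float(eff_i),
                adaptation=rec_a,
                tmr=rec_t,
                cue_schedule=schedule,
                trials=pd.DataFrame(),
            )
        )

    behavior_seed = int(children[-1].generate_state(1)[0] % (2**31))
    trials = gen_behavior(params, behavior_seed, latency_effects=effects)
    for dog in dogs:
        dog.trials = trials[trials["dog_id"] == dog.dog_id].reset_index(drop=True)

    bundle = StudyBundle(params=params, dogs=dogs, trials=trials)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), edf=edf)
    return bundle


def _write_bundle(bundle: StudyBundle, out_dir: Path, edf: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_trials(bundle.trials, out_dir / "trials.csv")
    for dog in bundle.dogs:
        ddir = out_dir / dog.dog_id
        ddir.mkdir(exist_ok=True)
        for name, (rec, truth), schedule in (
            ("adaptation", dog.adaptation, None),
            ("tmr", dog.tmr, dog.cue_schedule),
        ):
            write_raw_pair(rec, ddir / name)
            if edf:
                write_edf(rec, ddir / f"{name}.edf")
            write_hypnogram(truth.hypnogram, ddir / f"{name}_hypnogram.csv")
            write_artifacts_csv(truth.artifact_intervals, ddir / f"{name}_artifacts.csv")
            times = schedule.cue_times_s if schedule is not None else ()
            label = schedule.cue_label if schedule is not None else f"cued_{dog.cued_side}"
            write_cue_log(times, label, ddir / f"{name}_cues.csv")
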