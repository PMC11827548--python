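"""Adaptive amplitude-frequency sleep-spindle detection.

Spindles are transient sigma-band (~9-16 Hz) bursts of non-REM EEG lasting at
least 0.5 s.  The detector is adaptive: an initial amplitude criterion on the
sigma envelope seeds a set of candidate events, Gaussian distributions of
event amplitude and event frequency are fitted to those candidates by maximum
likelihood, and detection is then repeated accepting only events whose
amplitude and frequency fall inside the fitted distributions, iterating until
the event set stabilizes.  Detections are restricted to artifact-free non-REM
samples throughout.  Events are split into slow (< 13 Hz) and fast (>= 13 Hz)
subtypes, and summarized as densities in events per minute of artifact-free
non-REM sleep; a dog's trait density is the unweighted mean of its
per-recording densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .hypnogram import Hypnogram, NREM
from .spectral import ArtifactMask

__all__ = [
    "SpindleEvent",
    "DetectorParams",
    "SpindleDensity",
    "detect_spindles",
    "classify",
    "density",
    "averaged_density",
    "FAST_THRESHOLD_HZ",
]

logger = logging.getLogger(__name__)

#: slow/fast split: fast spindles are >= 13 Hz
FAST_THRESHOLD_HZ = 13.0

MIN_DURATION_S = 0.5


class SpindleError(ValueError):
    pass


@dataclass(frozen=True)
class SpindleEvent:
    """One detected spindle burst."""

    channel: str
    onset_s: float
    duration_s: float
    mean_freq_hz: float
    peak_amp_uv: float
    subtype: str = ""  # "slow" or "fast" once classified

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class DetectorParams:
    """Tunable detector parameters.

    Defaults are a documented reconstruction of a standard adaptive detector,
    not a replication of any specific prior implementation: sigma band
    9-16 Hz, RMS envelope over a 0.125-s sliding window, initial threshold
    mean + 2 SD of the non-REM envelope, acceptance window mean +/- 2 SD of
    the fitted amplitude and frequency Gaussians, at most 10 refinement
    iterations, and events closer than 0.1 s merged.
    """

    sigma_band_hz: tuple[float, float] = (9.0, 16.0)
    envelope_window_s: float = 0.125
    init_threshold_k: float = 2.0
    boundary_k: float = 0.5
    accept_z: float = 2.5
    max_iter: int = 10
    convergence_tol: float = 0.01
    merge_gap_s: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.sigma_band_hz
        if not (lo < FAST_THRESHOLD_HZ < hi):
            raise SpindleError(
                f"sigma band {self.sigma_band_hz} must straddle the 13 Hz slow/fast split"
            )
        if self.max_iter < 1:
            raise SpindleError("max_iter must be >= 1")


@dataclass(frozen=True)
class SpindleDensity:
    """Spindle occurrence per minute of artifact-free non-REM sleep."""

    channel: str
    subtype: str
    events_per_min: float
    n_events: int
    nrem_minutes: float


# ---------------------------------------------------------------------------
# detection internals
# ---------------------------------------------------------------------------

def _sigma_filter(signal: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, signal)


def _rms_envelope(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    n = max(1, int(round(window_s * fs)))
    return np.sqrt(uniform_filter1d(x * x, size=n, mode="nearest"))


def _runs_above(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open index runs where ``above`` is True."""
    d = np.diff(above.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _fit_truncated_normal(x: np.ndarray, lower: float) -> tuple[float, float]:
    """ML estimates of (mu, sd) of a Gaussian observed left-truncated at
    ``lower``.  Initial detections only ever show amplitudes above the
    detection threshold, so a plain sample fit underestimates the true
    spread; this corrects for the truncation."""
    from scipy.optimize import minimize
    from scipy.stats import norm

    x = np.asarray(x, dtype=float)
    m0, s0 = x.mean(), max(x.std(), 1e-6)
    if x.size < 5:
        return float(m0), float(s0)

    def nll(theta):
        mu, log_sd = theta
        sd = np.exp(log_sd)
        z = (x - mu) / sd
        tail = norm.sf((lower - mu) / sd)
        if tail <= 1e-12:
            return 1e12
        return float(x.size * (log_sd + np.log(tail)) + 0.5 * np.sum(z * z))

    res = minimize(nll, x0=(m0, np.log(s0)), method="Nelder-Mead")
    if not res.success:
        return float(m0), float(s0)
    mu, log_sd = res.x
    # keep the corrected fit within a sane range of the raw sample fit
    if not (m0 - 3 * s0 <= mu <= m0 + s0) or not (0.5 * s0 <= np.exp(log_sd) <= 5 * s0):
        return float(m0), float(s0)
    return float(mu), float(np.exp(log_sd))


def _event_features(
    run: tuple[int, int], sigma: np.ndarray, env: np.ndarray, fs: float
) -> tuple[float, float]:
    """(peak envelope amplitude, mean frequency) of one candidate run.

    Frequency is the reciprocal of the mean zero-crossing interval of the
    sigma-filtered signal (each half-cycle is one interval), measured over
    the run's core — the span where the envelope is at least half its peak —
    so the estimate is not diluted by background at the run's skirts.
    """
    a, b = run
    seg_env = env[a:b]
    amp = float(seg_env.max())
    core = np.nonzero(seg_env >= 0.5 * amp)[0]
    ca, cb = a + core[0], a + core[-1] + 1
    seg = sigma[ca:cb]
    sign = np.signbit(seg)
    crossings = np.nonzero(sign[1:] != sign[:-1])[0]
    if crossings.size >= 2:
        mean_interval = (crossings[-1] - crossings[0]) / (crossings.size - 1) / fs
        freq = 1.0 / (2.0 * mean_interval)
    else:
        freq = crossings.size / (2.0 * ((cb - ca) / fs))
    return amp, freq


def detect_spindles(
    signal: np.ndarray,
    sample_rate_hz: float,
    h: Hypnogram,
    mask: ArtifactMask,
    params: DetectorParams | None = None,
    channel: str = "",
) -> list[SpindleEvent]:
    """Detect sleep spindles in one channel, restricted to artifact-free NREM.

    Pipeline: (1) band-pass to the sigma band and compute the RMS envelope;
    (2) initial detections are maximal runs of eligible samples where the
    envelope exceeds mean + ``init_threshold_k`` SD of the eligible-NREM
    envelope, lasting at least 0.5 s; (3) Gaussians are fitted (ML) to the
    detected event amplitudes and frequencies; (4) re-detection: candidate
    runs are taken above the lower boundary threshold mean +
    ``boundary_k`` SD (so an event's full extent counts toward the 0.5-s
    minimum, not just its supra-threshold peak), and a run is accepted iff
    its peak amplitude AND mean frequency fall within mean +/- ``accept_z``
    SD of the fitted distributions; (5) steps 3-4 iterate until the run set
    is stable or ``max_iter`` is reached.  Runs separated by less than
    ``merge_gap_s`` are merged before feature extraction, and runs are
    clipped at NREM/artifact boundaries (kept if >= 0.5 s remains).
    """
    if params is None:
        params = DetectorParams()
    signal = np.asarray(signal, dtype=np.float64)
    fs = float(sample_rate_hz)
    n = signal.size

    eligible = h.sample_mask(NREM, fs, n) & ~mask.sample_mask(fs, n)
    if not eligible.any():
        raise SpindleError("no artifact-free non-REM samples to search")

    sigma = _sigma_filter(signal, fs, params.sigma_band_hz)
    env = _rms_envelope(sigma, fs, params.envelope_window_s)
    env_mean = float(env[eligible].mean())
    env_sd = float(env[eligible].std())

    min_len = int(round(MIN_DURATION_S * fs))
    gap = max(1, int(round(params.merge_gap_s * fs)))

    def candidate_runs(threshold: float) -> list[tuple[int, int]]:
        above = (env > threshold) & eligible
        if not above.any():
            return []
        runs = _merge_runs(_runs_above(above), gap)
        return [(a, b) for a, b in runs if b - a >= min_len]

    current = candidate_runs(env_mean + params.init_threshold_k * env_sd)
    if not current:
        logger.info("no initial spindle detections; refinement skipped")
        return []

    init_threshold = env_mean + params.init_threshold_k * env_sd
    boundary = env_mean + params.boundary_k * env_sd
    for it in range(params.max_iter):
        feats = np.array([_event_features(r, sigma, env, fs) for r in current])
        if it == 0:
            # initial detections are amplitude-truncated at the threshold
            amp_mu, amp_sd = _fit_truncated_normal(feats[:, 0], init_threshold)
        else:
            amp_mu, amp_sd = feats[:, 0].mean(), feats[:, 0].std()
        frq_mu, frq_sd = feats[:, 1].mean(), feats[:, 1].std()
        # numerical floors so a near-degenerate fit cannot collapse the
        # acceptance window to a point
        amp_sd = max(amp_sd, 0.05 * amp_mu)
        frq_sd = max(frq_sd, 0.25)

        accepted = []
        for r in candidate_runs(boundary):
            amp, frq = _event_features(r, sigma, env, fs)
            if (
                abs(amp - amp_mu) <= params.accept_z * amp_sd
                and abs(frq - frq_mu) <= params.accept_z * frq_sd
            ):
                accepted.append(r)
        sym_diff = len(set(accepted) ^ set(current))
        converged = sym_diff / max(1, len(current)) < params.convergence_tol
        current = accepted
        if not current or converged:
            break

    events = []
    for a, b in current:
        amp, frq = _event_features((a, b), sigma, env, fs)
        events.append(
            SpindleEvent(
                channel=channel,
                onset_s=a / fs,
                duration_s=(b - a) / fs,
                mean_freq_hz=frq,
                peak_amp_uv=amp,
            )
        )
    return classify(events)


def classify(events: list[SpindleEvent]) -> list[SpindleEvent]:
    """Assign slow/fast subtype: fast iff mean frequency >= 13 Hz."""
    return [
        replace(e, subtype="fast" if e.mean_freq_hz >= FAST_THRESHOLD_HZ else "slow")
        for e in events
    ]


def density(
    events: list[SpindleEvent],
    nrem_minutes: float,
    subtype: str | None = None,
    channel: str | None = None,
) -> SpindleDensity:
    """Events per minute of (artifact-free) non-REM sleep."""
    if nrem_minutes <= 0:
        raise SpindleError("density undefined for zero non-REM minutes")
    sel = [
        e
        for e in events
        if (subtype is None or e.subtype == subtype)
        and (channel is None or e.channel == channel)
    ]
    return SpindleDensity(
        channel=channel or "",
        subtype=subtype or "all",
        events_per_min=len(sel) / nrem_minutes,
        n_events=len(sel),
        nrem_minutes=nrem_minutes,
    )


def averaged_density(densities) -> float:
    """Trait density: unweighted mean of per-recording densities.

    Accepts :class:`SpindleDensity` objects or plain numbers.
    """
    values = [
        d.events_per_min if isinstance(d, SpindleDensity) else float(d)
        for d in densities
    ]
    if not values:
        raise SpindleError("averaged density of an empty collection")
    return float(np.mean(values))
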