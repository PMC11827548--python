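"""Stage-restricted EEG power spectra on the Fz-Cz derivation.

Average power spectral densities are computed per sleep stage (drowsiness,
non-REM, REM; never wake, which is dominated by muscle artifact) from 4-s,
50 %-overlapping, Hann-tapered windows.  A 4-s window gives exactly 0.25 Hz
resolution, so each "0.25 Hz bin" is the single FFT coefficient at that
frequency; the analysis grid runs 1.00-30.00 Hz inclusive (117 bins).
Relative power is each bin's power divided by the summed power over the grid,
and the four classic bands are delta 1-4, theta 4-8, alpha 8-12 and beta
12-30 Hz (half-open on the left edges so they partition the grid).

Windows must lie wholly inside a contiguous run of same-stage 20-s epochs and
wholly outside artifact intervals; artifact intervals are normalized to the
4-s subepoch grid on which manual rejection is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

from .hypnogram import Hypnogram, WAKE
from .io import Recording

__all__ = [
    "ArtifactMask",
    "SpectralProfile",
    "BIN_FREQS",
    "BANDS",
    "derive_channel",
    "stage_psd",
    "band_powers",
    "eligible_window_starts",
]

#: analysis grid: 1.00, 1.25, ..., 30.00 Hz
BIN_FREQS = np.round(np.arange(4, 121) * 0.25, 2)

#: half-open band edges [low, high) except beta which includes 30 Hz
BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (12.0, 30.0)}

WINDOW_S = 4.0
OVERLAP = 0.5
ARTIFACT_EPOCH_S = 4.0


class SpectralError(ValueError):
    pass


@dataclass(frozen=True)
class ArtifactMask:
    """Artifact intervals, canonically snapped to 4-s subepochs.

    Input intervals are half-open ``[start_s, end_s)``; on construction each
    is expanded outward to the enclosing 4-s subepochs (aligned to recording
    start) and overlapping intervals are merged.
    """

    intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        snapped = []
        for a, b in self.intervals:
            if b <= a:
                raise SpectralError(f"empty artifact interval [{a}, {b})")
            lo = np.floor(a / ARTIFACT_EPOCH_S) * ARTIFACT_EPOCH_S
            hi = np.ceil(b / ARTIFACT_EPOCH_S) * ARTIFACT_EPOCH_S
            snapped.append((float(lo), float(hi)))
        snapped.sort()
        merged: list[list[float]] = []
        for a, b in snapped:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        object.__setattr__(self, "intervals", tuple((a, b) for a, b in merged))

    def overlaps(self, start_s: float, end_s: float) -> bool:
        return any(a < end_s and start_s < b for a, b in self.intervals)

    def sample_mask(self, sample_rate_hz: float, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask, True where artifact-flagged."""
        m = np.zeros(n_samples, dtype=bool)
        for a, b in self.intervals:
            lo = max(0, int(round(a * sample_rate_hz)))
            hi = min(n_samples, int(round(b * sample_rate_hz)))
            if lo < n_samples:
                m[lo:hi] = True
        return m


@dataclass(frozen=True)
class SpectralProfile:
    """Per-stage relative power on the 0.25 Hz grid plus band summaries."""

    stage: str
    bin_freqs: np.ndarray
    relative_power: np.ndarray
    band_relative: dict[str, float]
    n_windows: int


def derive_channel(rec: Recording, spec: str) -> np.ndarray:
    """Bipolar derivation ``"A-B"``: pointwise difference of channels A and B."""
    parts = spec.replace("−", "-").split("-")
    if len(parts) != 2:
        raise SpectralError(f"derivation spec must be 'A-B', got {spec!r}")
    a, b = (p.strip() for p in parts)
    return rec.channel(a) - rec.channel(b)


def eligible_window_starts(
    h: Hypnogram, mask: ArtifactMask, stage: str, duration_s: float | None = None
) -> list[float]:
    """Start times (s) of 4-s windows wholly inside same-stage runs and
    wholly artifact-free; consecutive windows overlap by 50 %."""
    step = WINDOW_S * (1.0 - OVERLAP)
    starts: list[float] = []
    for i0, i1 in h.runs(stage):
        run_a = h.start_offset_s + i0 * h.epoch_s
        run_b = h.start_offset_s + i1 * h.epoch_s
        if duration_s is not None:
            run_b = min(run_b, duration_s)
        t = run_a
        while t + WINDOW_S <= run_b + 1e-9:
            if not mask.overlaps(t, t + WINDOW_S):
                starts.append(t)
            t += step
    return starts


def stage_psd(
    signal: np.ndarray,
    sample_rate_hz: float,
    h: Hypnogram,
    mask: ArtifactMask,
    stage: str,
) -> SpectralProfile:
    """Average relative power spectrum of one stage.

    Periodograms of the eligible windows (mean-removed, Hann-tapered, FFT)
    are averaged, the grid bins 1.00-30.00 Hz extracted, and the spectrum
    normalized to sum to one over the grid.  With zero eligible windows an
    all-NaN profile with ``n_windows = 0`` is returned.
    """
    if stage == WAKE:
        raise SpectralError("no spectral analysis is defined for the wake stage")
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise SpectralError("signal must be one-dimensional")
    if signal.size < h.duration_s * sample_rate_hz - 0.5:
        raise SpectralError("signal shorter than the hypnogram it is scored by")

    nwin = int(round(WINDOW_S * sample_rate_hz))
    if abs(nwin - WINDOW_S * sample_rate_hz) > 1e-9:
        raise SpectralError("sampling rate must yield an integer 4-s window")
    taper = hann(nwin, sym=False)
    bin_idx = np.arange(4, 121)  # k / 4 s = 1.00 ... 30.00 Hz

    starts = eligible_window_starts(h, mask, stage, duration_s=signal.size / sample_rate_hz)
    if not starts:
        nanvec = np.full(BIN_FREQS.size, np.nan)
        return SpectralProfile(
            stage=stage,
            bin_freqs=BIN_FREQS.copy(),
            relative_power=nanvec,
            band_relative={b: float("nan") for b in BANDS},
            n_windows=0,
        )

    acc = np.zeros(bin_idx.size)
    for t in starts:
        lo = int(round(t * sample_rate_hz))
        seg = signal[lo : lo + nwin]
        seg = (seg - seg.mean()) * taper
        spec = np.fft.rfft(seg)
        acc += np.abs(spec[bin_idx]) ** 2
    psd = acc / len(starts)
    rel = psd / psd.sum()
    prof = SpectralProfile(
        stage=stage,
        bin_freqs=BIN_FREQS.copy(),
        relative_power=rel,
        band_relative={},
        n_windows=len(starts),
    )
    object.__setattr__(prof, "band_relative", band_powers(prof))
    return prof


def band_powers(profile: SpectralProfile) -> dict[str, float]:
    """Relative power summed over the four bands (delta/theta/alpha/beta).

    Left edges are half-open: the 4.00 Hz bin belongs to theta, 8.00 to
    alpha, 12.00 to beta; 30.00 Hz closes beta, so the bands partition the
    grid and the four fractions sum to one.
    """
    rel = profile.relative_power
    f = profile.bin_freqs
    out: dict[str, float] = {}
    for name, (lo, hi) in BANDS.items():
        if name == "beta":
            sel = (f >= lo) & (f <= hi)
        else:
            sel = (f >= lo) & (f < hi)
        out[name] = float(rel[sel].sum())
    return out
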