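"""Hypnogram representation and sleep-macrostructure variables.

Canine polysomnography is scored on 20-s epochs into four stages: wakefulness,
drowsiness (a transitional stage scored in its own right in carnivores),
non-REM and REM sleep.  Because drowsiness blurs the wake/sleep boundary,
sleep onset is anchored two ways: at the first drowsiness epoch (suffix ``1``)
and at the first non-REM epoch (suffix ``2``), yielding two sleep latencies
and two WASO (wakefulness after sleep onset) variables.

Nine macrostructure variables are computed from a hypnogram: sleep efficiency
(%), relative wake duration (%), WASO1 and WASO2 (min), Sleep Latency 1 and 2
(min), and relative drowsiness / non-REM / REM durations (%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WAKE",
    "DROWSINESS",
    "NREM",
    "REM",
    "STAGES",
    "Hypnogram",
    "MacrostructureSummary",
    "macrostructure",
    "stage_minutes",
    "read_hypnogram",
    "write_hypnogram",
]

WAKE = "W"
DROWSINESS = "D"
NREM = "N"
REM = "R"
STAGES = (WAKE, DROWSINESS, NREM, REM)


class HypnogramError(ValueError):
    """Raised for malformed hypnograms or hypnogram files."""


@dataclass(frozen=True)
class Hypnogram:
    """Ordered fixed-length-epoch stage labels.

    Parameters
    ----------
    labels : tuple of str
        Stage symbols, one per epoch, each in ``{"W", "D", "N", "R"}``.
    epoch_s : float
        Epoch length in seconds (20 s for offline canine scoring).
    start_offset_s : float
        Recording-time of epoch 0 (usually 0).
    """

    labels: tuple[str, ...]
    epoch_s: float = 20.0
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise HypnogramError("hypnogram must contain at least one epoch")
        if self.epoch_s <= 0:
            raise HypnogramError(f"epoch_s must be positive, got {self.epoch_s}")
        bad = sorted(set(self.labels) - set(STAGES))
        if bad:
            raise HypnogramError(f"unknown stage symbol(s): {bad}")
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.epoch_s

    def stage_of_time(self, t_s: float) -> str | None:
        """Stage at recording time ``t_s`` (None outside the hypnogram)."""
        i = int(math.floor((t_s - self.start_offset_s) / self.epoch_s))
        if 0 <= i < len(self.labels):
            return self.labels[i]
        return None

    def sample_mask(self, stage: str, sample_rate_hz: float, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask of the given stage on a signal timeline."""
        mask = np.zeros(n_samples, dtype=bool)
        spe = int(round(self.epoch_s * sample_rate_hz))
        for i, lab in enumerate(self.labels):
            if lab == stage:
                lo = i * spe
                hi = min((i + 1) * spe, n_samples)
                if lo < n_samples:
                    mask[lo:hi] = True
        return mask

    def runs(self, stage: str) -> list[tuple[int, int]]:
        """Maximal runs of ``stage`` as half-open epoch-index intervals."""
        out: list[tuple[int, int]] = []
        start = None
        for i, lab in enumerate(self.labels):
            if lab == stage and start is None:
                start = i
            elif lab != stage and start is not None:
                out.append((start, i))
                start = None
        if start is not None:
            out.append((start, len(self.labels)))
        return out


@dataclass(frozen=True)
class MacrostructureSummary:
    """The nine exported hypnogram variables.

    Latencies and WASO values are NaN when their anchoring stage never
    occurs (a stage can be genuinely absent from a nap recording).
    """

    sleep_efficiency: float  # %
    relative_wake: float  # %
    waso1_min: float
    waso2_min: float
    sleep_latency1_min: float
    sleep_latency2_min: float
    relative_drowsiness: float  # %
    relative_nrem: float  # %
    relative_rem: float  # %

    def as_dict(self) -> dict[str, float]:
        return {
            "sleep_efficiency": self.sleep_efficiency,
            "relative_wake": self.relative_wake,
            "waso1_min": self.waso1_min,
            "waso2_min": self.waso2_min,
            "sleep_latency1_min": self.sleep_latency1_min,
            "sleep_latency2_min": self.sleep_latency2_min,
            "relative_drowsiness": self.relative_drowsiness,
            "relative_nrem": self.relative_nrem,
            "relative_rem": self.relative_rem,
        }


def macrostructure(h: Hypnogram, drowsiness_is_sleep: bool = True) -> MacrostructureSummary:
    """Compute the nine macrostructure variables from a hypnogram.

    ``drowsiness_is_sleep`` controls the sleep-efficiency numerator: by
    default drowsiness counts toward time asleep (with drowsiness, NREM and
    REM all counted, a 120-min canine nap with ~95 min of scored sleep gives
    the ~79 % efficiencies typical of afternoon dog polysomnography).

    Latencies are measured from recording start in minutes; WASO1/WASO2 count
    WAKE epochs strictly after the first drowsiness / first NREM epoch.
    """
    labels = h.labels
    n = len(labels)
    epoch_min = h.epoch_s / 60.0

    counts = {s: labels.count(s) for s in STAGES}
    sleep_stages = {DROWSINESS, NREM, REM} if drowsiness_is_sleep else {NREM, REM}
    n_sleep = sum(counts[s] for s in sleep_stages)

    def first_index(stage: str) -> int | None:
        try:
            return labels.index(stage)
        except ValueError:
            return None

    i_d = first_index(DROWSINESS)
    i_n = first_index(NREM)

    def latency_min(i: int | None) -> float:
        return float("nan") if i is None else i * epoch_min

    def waso_min(anchor: int | None) -> float:
        if anchor is None:
            return float("nan")
        return sum(1 for lab in labels[anchor + 1 :] if lab == WAKE) * epoch_min

    return MacrostructureSummary(
        sleep_efficiency=100.0 * n_sleep / n,
        relative_wake=100.0 * counts[WAKE] / n,
        waso1_min=waso_min(i_d),
        waso2_min=waso_min(i_n),
        sleep_latency1_min=latency_min(i_d),
        sleep_latency2_min=latency_min(i_n),
        relative_drowsiness=100.0 * counts[DROWSINESS] / n,
        relative_nrem=100.0 * counts[NREM] / n,
        relative_rem=100.0 * counts[REM] / n,
    )


def stage_minutes(h: Hypnogram, stage: str, artifact_mask=None) -> float:
    """Minutes spent in ``stage``, optionally excluding artifact time.

    ``artifact_mask`` is an :class:`~caninesleep.spectral.ArtifactMask` (or
    any object with flagged half-open ``intervals`` in seconds).  Flagged time
    inside epochs of the stage is subtracted; the mask must lie within the
    recording.
    """
    if stage not in STAGES:
        raise HypnogramError(f"unknown stage {stage!r}")
    total_s = h.labels.count(stage) * h.epoch_s
    if artifact_mask is not None:
        for a, b in artifact_mask.intervals:
            if a < h.start_offset_s - 1e-9 or b > h.start_offset_s + h.duration_s + 1e-9:
                raise HypnogramError(
                    f"artifact interval [{a}, {b}) extends outside the recording"
                )
            # clip the interval against every epoch of the stage
            for i, lab in enumerate(h.labels):
                if lab != stage:
                    continue
                lo = h.start_offset_s + i * h.epoch_s
                hi = lo + h.epoch_s
                total_s -= max(0.0, min(b, hi) - max(a, lo))
    return total_s / 60.0


# ---------------------------------------------------------------------------
# CSV I/O: columns epoch_index (0-based, contiguous), stage in {W,D,N,R}
# ---------------------------------------------------------------------------

def read_hypnogram(path: str | Path, epoch_s: float = 20.0) -> Hypnogram:
    """Read a hypnogram CSV (columns ``epoch_index``, ``stage``)."""
    df = pd.read_csv(path)
    for col in ("epoch_index", "stage"):
        if col not in df.columns:
            raise HypnogramError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise HypnogramError(f"{path}: no epochs")
    idx = df["epoch_index"].to_numpy()
    expected = np.arange(len(df))
    if not np.array_equal(idx, expected):
        row = int(np.nonzero(idx != expected)[0][0])
        raise HypnogramError(
            f"{path}: non-contiguous epoch_index at row {row} "
            f"(found {idx[row]}, expected {expected[row]})"
        )
    labels = []
    for row, s in enumerate(df["stage"].astype(str)):
        if s not in STAGES:
            raise HypnogramError(f"{path}: unknown stage {s!r} at row {row}")
        labels.append(s)
    return Hypnogram(labels=tuple(labels), epoch_s=epoch_s)


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(len(h)), "stage": list(h.labels)}
    ).to_csv(path, index=False)
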