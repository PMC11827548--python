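"""Recording container and file I/O.

Signals travel either as EDF (European Data Format, 16-bit) or as a plain
pair ``{<stem>.f32, <stem>.json}`` holding a float32 channels-by-time matrix
plus a JSON header (channel labels, sampling rate, reference).  Tabular
side-car files (hypnograms, artifact intervals, cue logs, behavioral trials)
are CSV.

EDF reading goes through :func:`mne.io.read_raw_edf`; the writer here emits
minimal EDF+C-compatible 16-bit EDF (one 1-s data record per second, physical
range spanning each channel's data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "read_raw_pair",
    "write_raw_pair",
    "read_edf",
    "write_edf",
    "read_artifacts_csv",
    "write_artifacts_csv",
    "read_cue_log",
    "write_cue_log",
    "read_trials",
    "write_trials",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = ["dog_id", "phase", "trial_index", "cue_class", "correct", "latency_s"]


@dataclass
class Recording:
    """Multi-channel EEG recording in microvolts.

    ``samples`` is a ``(n_channels, n_times)`` float array; ``channel_labels``
    gives one label per row (e.g. Fz, Cz, F7, F8 referenced to G2).
    """

    channel_labels: list[str]
    sample_rate_hz: float
    samples: np.ndarray
    reference: str = "G2"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not present (have {self.channel_labels})"
            ) from None
        return self.samples[i]


# ---------------------------------------------------------------------------
# float32 + JSON header pair
# ---------------------------------------------------------------------------

def write_raw_pair(rec: Recording, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.f32`` (float32 C-order matrix) and ``<stem>.json``."""
    stem = Path(stem)
    bin_path = stem.with_suffix(".f32")
    hdr_path = stem.with_suffix(".json")
    data = np.ascontiguousarray(rec.samples, dtype=np.float32)
    data.tofile(bin_path)
    hdr = {
        "channels": rec.channel_labels,
        "sample_rate_hz": rec.sample_rate_hz,
        "n_samples": rec.n_samples,
        "reference": rec.reference,
        "dtype": "float32",
        "units": "uV",
    }
    hdr_path.write_text(json.dumps(hdr, indent=1))
    return bin_path, hdr_path


def read_raw_pair(stem: str | Path) -> Recording:
    stem = Path(stem)
    hdr = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".f32"), dtype=np.float32)
    n_ch = len(hdr["channels"])
    data = data.reshape(n_ch, hdr["n_samples"])
    return Recording(
        channel_labels=list(hdr["channels"]),
        sample_rate_hz=float(hdr["sample_rate_hz"]),
        samples=data.astype(np.float64),
        reference=hdr.get("reference", ""),
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a 16-bit EDF file (1-s data records, per-channel physical range).

    The recording is zero-padded to a whole number of seconds.  Physical
    minima/maxima are each channel's data range (symmetric, non-degenerate),
    so quantization error is bounded by range / 2^16.
    """
    path = Path(path)
    if int(rec.sample_rate_hz) != rec.sample_rate_hz:
        raise ValueError("EDF export requires an integer sampling rate")
    rate = int(rec.sample_rate_hz)
    n_ch = len(rec.channel_labels)
    n_rec = int(np.ceil(rec.n_samples / rate))
    padded = np.zeros((n_ch, n_rec * rate), dtype=np.float64)
    padded[:, : rec.n_samples] = rec.samples

    # symmetric physical range per channel with short ASCII representation
    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    phys_max = np.array([float(f"{v:.5g}") * 1.001 for v in phys_max])
    phys_max = np.array([float(f"{v:.5g}") for v in phys_max])
    dig_max, dig_min = 32767, -32768

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii(f"Startdate X X X X ref {rec.reference}", 80),
            _ascii("01.01.20", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (1 + n_ch), 8),
            _ascii("EDF+C", 44),
            _ascii(n_rec, 8),
            _ascii(1, 8),
            _ascii(n_ch, 4),
        ]
    )
    sig = b"".join(_ascii(lab, 16) for lab in rec.channel_labels)
    sig += b"".join(_ascii("AgAgCl electrode", 80) for _ in range(n_ch))
    sig += b"".join(_ascii("uV", 8) for _ in range(n_ch))
    sig += b"".join(_ascii(f"{-m:.6g}"[:8], 8) for m in phys_max)
    sig += b"".join(_ascii(f"{m:.6g}"[:8], 8) for m in phys_max)
    sig += b"".join(_ascii(dig_min, 8) for _ in range(n_ch))
    sig += b"".join(_ascii(dig_max, 8) for _ in range(n_ch))
    sig += b"".join(_ascii("HP:0.016Hz LP:70Hz", 80) for _ in range(n_ch))
    sig += b"".join(_ascii(rate, 8) for _ in range(n_ch))
    sig += b"".join(_ascii("", 32) for _ in range(n_ch))

    scale = (dig_max - dig_min) / (2.0 * phys_max)
    digital = np.empty((n_ch, n_rec * rate), dtype="<i2")
    for c in range(n_ch):
        d = np.rint((padded[c] + phys_max[c]) * scale[c] + dig_min)
        digital[c] = np.clip(d, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        f.write(sig)
        for r in range(n_rec):
            for c in range(n_ch):
                f.write(digital[c, r * rate : (r + 1) * rate].tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_v = raw.get_data()  # volts
    return Recording(
        channel_labels=list(raw.ch_names),
        sample_rate_hz=float(raw.info["sfreq"]),
        samples=data_v * 1e6,
    )


# ---------------------------------------------------------------------------
# CSV side-cars
# ---------------------------------------------------------------------------

def write_artifacts_csv(intervals, path: str | Path) -> None:
    """Write half-open artifact intervals as CSV columns start_s, end_s."""
    df = pd.DataFrame(intervals, columns=["start_s", "end_s"]) if len(intervals) else \
        pd.DataFrame({"start_s": [], "end_s": []})
    df.to_csv(path, index=False)


def read_artifacts_csv(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return [(float(a), float(b)) for a, b in zip(df["start_s"], df["end_s"])]


def write_cue_log(cue_times_s, cue_label: str, path: str | Path) -> None:
    pd.DataFrame(
        {"cue_time_s": list(cue_times_s), "cue_label": [cue_label] * len(cue_times_s)}
    ).to_csv(path, index=False)


def read_cue_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        return pd.DataFrame({"cue_time_s": [], "cue_label": []})
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trials table missing columns {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
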