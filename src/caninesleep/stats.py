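"""Behavioral learning statistics and the Rüger-area correction.

Per-dog behavioral measures from a two-phase (baseline / post-sleep test)
two-choice task with a cued side:

* cueing benefit — post-sleep accuracy minus baseline accuracy of the cued
  trials;
* latency reduction — the ratio mean(baseline latency) / mean(test latency),
  computed separately for correct and incorrect trials, so larger values mean
  a larger speed-up after sleep;
* relative latency reduction — the correct-trial reduction divided by the
  incorrect-trial reduction, an index of learning-specific speed-up that is
  invariant to a global rescaling of all latencies.

Spectral association scans correlate a per-subject outcome against relative
EEG power bin by bin on the 0.25 Hz grid, and the resulting p-value vector is
corrected for multiple comparisons with Rüger's area procedure: maximal runs
of conventionally significant (p < 0.05) bins form areas, and an area is
accepted as a whole only if at least half its members are below 0.025 and at
least one third are below 0.0167.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "cueing_benefit",
    "latency_reduction",
    "relative_latency_reduction",
    "behavior_summary",
    "PValueGrid",
    "RugerArea",
    "binwise_scan",
    "ruger_areas",
]

logger = logging.getLogger(__name__)

CUED_CLASSES = ("cued_left", "cued_right")


def _require_one_dog(trials: pd.DataFrame) -> None:
    if "dog_id" in trials.columns and trials["dog_id"].nunique() > 1:
        raise ValueError("expected trials of a single dog; got several dog_id values")


def cueing_benefit(trials: pd.DataFrame) -> float:
    """Post-sleep minus baseline proportion correct among cued trials.

    NaN when either phase has no cued trials.
    """
    _require_one_dog(trials)
    cued = trials[trials["cue_class"].isin(CUED_CLASSES)]
    base = cued[cued["phase"] == "baseline"]["correct"]
    test = cued[cued["phase"] == "test"]["correct"]
    if len(base) == 0 or len(test) == 0:
        return float("nan")
    return float(test.mean() - base.mean())


def latency_reduction(trials: pd.DataFrame, correct: int) -> float:
    """Mean baseline latency / mean test latency for one correctness class.

    Values above 1 indicate faster responses after sleep.  NaN when the class
    is absent from either phase.
    """
    _require_one_dog(trials)
    cls = trials[trials["correct"] == correct]
    pre = cls[cls["phase"] == "baseline"]["latency_s"]
    post = cls[cls["phase"] == "test"]["latency_s"]
    if len(pre) == 0 or len(post) == 0:
        return float("nan")
    return float(pre.mean() / post.mean())


def relative_latency_reduction(trials: pd.DataFrame) -> float:
    """Correct-trial latency reduction divided by incorrect-trial reduction.

    NaN (dog excluded) when either class reduction is undefined.
    """
    rc = latency_reduction(trials, correct=1)
    ri = latency_reduction(trials, correct=0)
    if np.isnan(rc) or np.isnan(ri):
        logger.info("relative latency reduction undefined (a correctness class is missing)")
        return float("nan")
    return rc / ri


def behavior_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-dog summary table over a multi-dog trials table."""
    rows = []
    for dog_id, sub in trials.groupby("dog_id", sort=True):
        rows.append(
            {
                "dog_id": dog_id,
                "cueing_benefit": cueing_benefit(sub),
                "lat_reduction_correct": latency_reduction(sub, 1),
                "lat_reduction_incorrect": latency_reduction(sub, 0),
                "relative_latency_reduction": relative_latency_reduction(sub),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bin-by-bin correlation scan + Rüger areas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PValueGrid:
    """Per-bin Pearson r, two-sided p, and per-bin n on the frequency grid."""

    bin_freqs: np.ndarray
    r_values: np.ndarray
    p_values: np.ndarray
    n: np.ndarray


def binwise_scan(spectra: pd.DataFrame, outcome: pd.Series) -> PValueGrid:
    """Correlate a per-subject outcome against relative power, bin by bin.

    ``spectra`` is a subjects x bins table whose columns are bin frequencies
    (Hz); ``outcome`` is indexed like the rows of ``spectra``.  Each bin's
    Pearson r gets a two-sided p-value from the t transform with n - 2
    degrees of freedom; subjects missing either value are excluded bin-wise,
    and zero-variance bins (or outcome) yield NaN at that bin.
    """
    spectra, outcome = spectra.align(outcome, join="inner", axis=0)
    if len(spectra) < 4:
        raise ValueError("need at least 4 subjects with both spectrum and outcome")
    freqs = np.asarray([float(c) for c in spectra.columns])
    y_all = outcome.to_numpy(dtype=float)
    r = np.full(freqs.size, np.nan)
    p = np.full(freqs.size, np.nan)
    n = np.zeros(freqs.size, dtype=int)
    for j, col in enumerate(spectra.columns):
        x = spectra[col].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y_all))
        n[j] = int(ok.sum())
        if n[j] < 3:
            continue
        xo, yo = x[ok], y_all[ok]
        if np.ptp(xo) == 0 or np.ptp(yo) == 0:
            continue
        res = sps.pearsonr(xo, yo)
        r[j], p[j] = res.statistic, res.pvalue
    return PValueGrid(bin_freqs=freqs, r_values=r, p_values=p, n=n)


@dataclass(frozen=True)
class RugerArea:
    """One maximal run of contiguous conventionally significant bins."""

    start_freq: float
    end_freq: float
    p_values: tuple[float, ...]
    n_bins: int
    n_below_half_alpha: int
    n_below_third_alpha: int
    significant: bool


def ruger_areas(grid: PValueGrid | None = None, alpha: float = 0.05,
                p_values=None, bin_freqs=None) -> list[RugerArea]:
    """Rüger's area correction over an ordered p-value grid.

    Areas are maximal runs of contiguous bins with p < ``alpha`` (grid edges
    and NaN bins act as boundaries).  An area of n bins is significant as a
    whole iff at least n/2 of its p-values are below alpha/2 AND at least n/3
    are below alpha/3 — both counts compared on exact fractions (strict
    inequality on the p thresholds, >= on the counts).
    """
    if grid is not None:
        p_values = grid.p_values
        bin_freqs = grid.bin_freqs
    p = np.asarray(p_values, dtype=float)
    f = np.asarray(bin_freqs, dtype=float) if bin_freqs is not None else np.arange(p.size, dtype=float)
    if f.size != p.size:
        raise ValueError("p_values and bin_freqs must be aligned")
    sig = np.where(np.isnan(p), False, p < alpha)
    areas: list[RugerArea] = []
    i = 0
    while i < p.size:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j < p.size and sig[j]:
            j += 1
        member = p[i:j]
        n_bins = j - i
        n_half = int((member < alpha / 2).sum())
        n_third = int((member < alpha / 3).sum())
        # exact-fraction comparisons: n_half >= n_bins/2, n_third >= n_bins/3
        significant = (2 * n_half >= n_bins) and (3 * n_third >= n_bins)
        areas.append(
            RugerArea(
                start_freq=float(f[i]),
                end_freq=float(f[j - 1]),
                p_values=tuple(float(x) for x in member),
                n_bins=n_bins,
                n_below_half_alpha=n_half,
                n_below_third_alpha=n_third,
                significant=significant,
            )
        )
        i = j
    return areas
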