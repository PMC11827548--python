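"""Non-REM-gated cue scheduling for targeted memory reactivation (TMR).

During the TMR session a learning-associated sound cue is replayed while the
dog sleeps: once the online monitor has judged the dog to be in non-REM sleep
for two consecutive 30-s epochs, the cue is played every 5 s for as long as
non-REM persists, and playback is interrupted the moment any sign of
awakening, arousal or REM appears.  Total stimulation is capped at ~5 min.

The scheduler here replays that protocol deterministically over a stream of
30-s online stage estimates.  Cue times lie on a 5-s grid anchored at bout
onset (first cue at the bout's first instant); any non-NREM epoch ends the
bout immediately and the NREM criterion must be met afresh before cueing
resumes; the ~5-min limit is a hard cumulative cap across bouts.  The online
stream is independent of the offline 20-s hypnogram — no resampling between
the two happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hypnogram import Hypnogram, NREM

__all__ = ["CueParams", "CueSchedule", "ScheduleReport", "schedule_cues", "validate_schedule"]


@dataclass(frozen=True)
class CueParams:
    online_epoch_s: float = 30.0
    consec_nrem_epochs_required: int = 2
    inter_cue_s: float = 5.0
    stim_cap_s: float = 300.0

    def __post_init__(self) -> None:
        for name in ("online_epoch_s", "consec_nrem_epochs_required", "inter_cue_s", "stim_cap_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CueSchedule:
    """Cue times produced by one TMR session."""

    cue_label: str
    cue_times_s: tuple[float, ...]
    bouts: tuple[tuple[float, float, int], ...]  # (start_s, end_s, n_cues)
    total_stim_s: float

    @property
    def n_cues(self) -> int:
        return len(self.cue_times_s)


def schedule_cues(
    stage_stream, params: CueParams | None = None, cue_label: str = "cue"
) -> CueSchedule:
    """Replay the online cueing rule over 30-s stage estimates.

    ``stage_stream`` is an ordered sequence of stage symbols ("W", "D", "N",
    "R"), one per online epoch.  A bout starts at the first instant after
    ``consec_nrem_epochs_required`` consecutive NREM epochs; cues then fire
    every ``inter_cue_s`` seconds (first cue at bout start) while the stream
    stays NREM.  Each cue accrues ``inter_cue_s`` of stimulation; scheduling
    stops permanently once accrued stimulation reaches ``stim_cap_s``.
    """
    if params is None:
        params = CueParams()
    stages = list(stage_stream)
    if not stages:
        raise ValueError("empty stage stream")
    ep = params.online_epoch_s

    cue_times: list[float] = []
    bouts: list[tuple[float, float, int]] = []
    total_stim = 0.0
    consec = 0
    i = 0
    capped = False
    while i < len(stages) and not capped:
        if stages[i] != NREM:
            consec = 0
            i += 1
            continue
        consec += 1
        if consec < params.consec_nrem_epochs_required:
            i += 1
            continue
        # criterion met at the end of epoch i: bout starts there
        bout_start = (i + 1) * ep
        # extent of the ongoing NREM run
        j = i + 1
        while j < len(stages) and stages[j] == NREM:
            j += 1
        run_end = j * ep
        n_in_bout = 0
        t = bout_start
        while t < run_end - 1e-9:
            if total_stim + params.inter_cue_s > params.stim_cap_s + 1e-9:
                capped = True
                break
            cue_times.append(t)
            total_stim += params.inter_cue_s
            n_in_bout += 1
            t += params.inter_cue_s
        if n_in_bout:
            bouts.append((bout_start, min(t, run_end), n_in_bout))
        consec = 0
        i = j  # next epoch after the NREM run (or stream end)
    return CueSchedule(
        cue_label=cue_label,
        cue_times_s=tuple(cue_times),
        bouts=tuple(bouts),
        total_stim_s=total_stim,
    )


@dataclass(frozen=True)
class ScheduleReport:
    """Offline audit of a cue schedule against the scored 20-s hypnogram."""

    n_cues: int
    n_flagged: int
    flagged_times_s: tuple[float, ...]
    total_stim_s: float


def validate_schedule(schedule: CueSchedule, h: Hypnogram) -> ScheduleReport:
    """Flag cues that fall in a non-NREM epoch of the offline hypnogram."""
    flagged = tuple(
        t for t in schedule.cue_times_s if h.stage_of_time(t) != NREM
    )
    return ScheduleReport(
        n_cues=schedule.n_cues,
        n_flagged=len(flagged),
        flagged_times_s=flagged,
        total_stim_s=schedule.total_stim_s,
    )
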