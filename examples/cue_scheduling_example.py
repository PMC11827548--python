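"""Replaying the non-REM-gated TMR cueing rule over online stage estimates.

The online monitor reports one stage estimate per 30 s.  Cueing starts after
two consecutive non-REM epochs, repeats every 5 s, aborts the moment the
stream leaves non-REM, and total stimulation is capped at 300 s.
"""

from caninesleep import Hypnogram, schedule_cues, validate_schedule

stream = ["W", "D"] + ["N"] * 10  # 6 min: wake, drowsy, then 5 min non-REM
schedule = schedule_cues(stream, cue_label="cued_left")

print("online stream:", " ".join(stream))
print(f"cues: {schedule.n_cues}, first at {schedule.cue_times_s[0]:.0f} s, "
      f"last at {schedule.cue_times_s[-1]:.0f} s, "
      f"stimulation {schedule.total_stim_s:.0f} s")

# audit against an offline 20-s hypnogram covering the same session
offline = Hypnogram(("W",) * 3 + ("N",) * 15, epoch_s=20.0)
report = validate_schedule(schedule, offline)
print(f"offline audit: {report.n_flagged} of {report.n_cues} cues fall "
      "outside scored non-REM")

print(
    "\nThe non-REM criterion is met after epochs 2-3 (t = 120 s), so cues\n"
    "fire at 120, 125, ..., 355 s (48 cues) and stop when the stream ends;\n"
    "the offline audit confirms every cue lies in scored non-REM."
)
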