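"""Sleep-macrostructure variables from a scored hypnogram.

Builds the nine-epoch hypnogram W,W,D,N,N,R,N,W,W (20-s epochs: 40 s awake,
drowsiness, non-REM, REM, more non-REM, then waking) and prints the nine
exported variables.
"""

from caninesleep import Hypnogram, macrostructure

h = Hypnogram(tuple("WWDNNRNWW"), epoch_s=20.0)
m = macrostructure(h)

print("hypnogram:", " ".join(h.labels), f"({len(h)} x {h.epoch_s:.0f} s epochs)")
for name, value in m.as_dict().items():
    print(f"  {name:24s} {value:8.3f}")
print(
    "\nSleep efficiency counts drowsiness, non-REM and REM as sleep (5 of 9\n"
    "epochs = 55.6 %).  Latency 1 anchors sleep onset at first drowsiness\n"
    "(2 epochs = 0.667 min), latency 2 at first non-REM (3 epochs = 1 min);\n"
    "WASO counts wake epochs after each anchor (2 epochs = 0.667 min)."
)
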