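"""APD restitution by the S1S2 protocol.

After a conditioning S1 train (10 beats at PCL 500 ms) a single premature
S2 probes each diastolic interval; APD is the time above -75 mV.  Without
Ito the curve rises monotonically with DI and saturates at long DI.
"""

from lr1spiral import ModelParams, PacingProtocol, S1S2Schedule, run_s1s2, restitution_slope

sched = S1S2Schedule(PacingProtocol(500.0, 10),
                     (50.0, 100.0, 150.0, 250.0, 400.0, 800.0, 1500.0))
pts = run_s1s2(ModelParams(), sched)
print(f"{'DI ms':>8} {'APD ms':>8} {'captured':>9}")
for p in pts:
    print(f"{p.di:8.1f} {p.apd:8.1f} {str(p.captured):>9}")
mid, slope = restitution_slope(pts)
print("max restitution slope:", f"{slope.max():.2f}",
      "(slopes above 1 at short DI predispose to alternans)")
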