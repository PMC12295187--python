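"""Conduction velocity on a 1D cable.

Stimulates one end of a 400-site cable (dx = 0.0125 cm, D = 0.001 cm^2/ms)
and times the -40 mV upstroke at two interior sensors.  The defaults give
about 0.55 m/s; quartering D roughly halves the speed (CV ~ sqrt(D)).
"""

from lr1spiral import measure_cv

r = measure_cv()
print(f"default D = 0.001 cm^2/ms : CV = {r.cv:.3f} m/s "
      f"(sensors {r.sensors}, upstrokes {r.t_first:.2f} / {r.t_second:.2f} ms)")
r4 = measure_cv(D=0.00025)
print(f"quarter D               : CV = {r4.cv:.3f} m/s "
      f"(ratio {r4.cv / r.cv:.2f}, sqrt scaling predicts 0.50)")
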