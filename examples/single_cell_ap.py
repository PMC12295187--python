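"""Action-potential morphology with and without the transient-outward current.

Elicits one AP from rest at three Gto levels and prints the notch/dome
metrics.  Without Ito the phase-1 notch sits around +9 mV; at
Gto = 0.24 mS/uF it deepens to about -28 mV with a clear dome (spike and
dome); past the critical Gto (~0.30 here) the dome fails and the APD
collapses (early repolarization).
"""

from lr1spiral import ModelParams, morphology_at

ref = morphology_at(ModelParams(Gtof=0.0))
print(f"{'Gto':>5} {'APD ms':>8} {'peak mV':>8} {'notch mV':>9} {'dome':>5} {'early':>6}")
for gtof in (0.0, 0.24, 0.32):
    m = morphology_at(ModelParams(Gtof=gtof), reference_apd=ref.apd)
    notch = "-" if m.notch_v is None else f"{m.notch_v:.1f}"
    print(f"{gtof:5.2f} {m.apd:8.1f} {m.peak_v:8.1f} {notch:>9} "
          f"{str(m.dome_present):>5} {str(m.early_repolarization):>6}")
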