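# lr1spiral

Simulation and analysis of cardiac action potentials and spiral-wave
dynamics in the 1991 Luo–Rudy (LR1) ventricular model extended with a fast
transient-outward potassium current (Ito,f), for computational
electrophysiologists studying how calcium- and potassium-current
modulation destabilizes reentry.

The model: a single cell obeys

    dV/dt = -(I_Na + I_Si + I_K + I_K1 + I_Kp + I_b + I_to,f - I_stim) / C_m

with Hodgkin–Huxley gating `dy/dt = (y∞(V) - y)/τ_y(V)`;
`I_to,f = G_to,f · x_tof · y_tof · (V - E_K)` follows the Mahajan et al.
formulation.  Two experimental handles matter throughout: the slow-inward
(L-type-like) conductance `Gsi` and the Ito conductance `Gtof`, plus the
gate-speed factors `kd, kf` that scale τ_d and τ_f (kd = kf = 0.3 means
"calcium kinetics accelerated to 30% of the control time constants").
Tissue is the monodomain sheet `∂V/∂t = -I_ion/C_m + D ∇²V` with
D = 0.001 cm²/ms, Δx = 0.0125 cm, Δt = 0.01 ms, no-flux boundaries —
conduction velocity ≈ 0.55 m/s at GNa = 16 mS/cm².

Capabilities (see `examples/`, one script per capability):

* single-cell APs, pacing trains, rest-state and diastolic-threshold search
* APD extraction (V > −75 mV), S1S2 and dynamic restitution, alternans
* spike-and-dome morphology metrics (notch voltage, dome, early
  repolarization) and dome-loss threshold bisection over Gtof
* 1D cable conduction velocity; 2D cross-field spiral induction
* phase-singularity (tip) detection and stable / quasi-periodic / breakup
  classification; parameter sweeps for phase diagrams
* pseudo-ECGs at four standard probe placements with a sample-entropy
  irregularity score

## Worked example

```
$ python examples/single_cell_ap.py
  Gto   APD ms  peak mV  notch mV  dome  early
 0.00    372.9     37.5       8.5 False  False
 0.24    342.7     36.9     -28.0  True  False
 0.32    138.2     36.7         - False   True
```

Without Ito the phase-1 notch aborts around +9 mV and the plateau carries a
long (≈ 373 ms) AP (the `dome` flag asks for a rebound of ≥ 5 mV above the
notch, which the smooth control plateau does not need).  At Gto = 0.24 mS/µF
the notch dives to −28 mV and the AP recovers into a dome (spike-and-dome
morphology).  By Gto = 0.32 the
dome fails: the cell repolarizes straight from the notch and the APD
collapses — early repolarization.  `examples/alternans.py` shows the same
current producing long–short APD alternans at PCL 600 ms that disappears
at PCL 1200 ms, and `examples/spiral_demo.py` induces a spiral by the
cross-field protocol and classifies its dynamics.

A thin CLI wraps the long-running jobs:
`lr1spiral cable-cv --out cv.json`,
`lr1spiral sweep --config sweep.yaml --out phase.json`, etc.

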