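# Methods

## Model

The membrane model is the 1991 Luo–Rudy guinea-pig ventricular action
potential (LR1) extended with a fast transient-outward potassium current
(Ito,f).  The transmembrane potential of an isolated cell obeys

    dV/dt = -(Iion - Istim) / Cm,
    Iion  = INa + ISi + IK + IK1 + IKp + Ib + Ito,f

with Cm = 1 µF/cm².  Every gated current has the Hodgkin–Huxley form
`I = G · (gates) · (V − E)` and each gate relaxes as
`dy/dt = (y∞(V) − y)/τy(V)`.  The rate functions of the six LR1 gates
(m, h, j for INa; d, f for the slow-inward calcium-like current ISi; x for
the time-dependent IK) and the IK1/IKp/Ib formulations are the published
LR1 ones; intracellular calcium follows LR1's single-pool balance

    dCai/dt = -1e-4 · ISi + 0.07 · (1e-4 − Cai),   ESi = 7.7 − 13.0287 ln Cai.

Ito,f is the fast transient-outward current of the Mahajan et al. rabbit
model: `Ito,f = Gto,f · xtof · ytof · (V − EK)` with

    xtof∞ = 1/(1+exp(−(V+3)/15)),    τx = 3.5·exp(−(V/30)²) + 1.5
    ytof∞ = 1/(1+exp((V+33.5)/10)),  τy = 20/(1+exp((V+33.5)/10)) + 20.

Two deliberately exposed handles drive all experiments:

* `Gsi`, `Gtof` — maximum conductances of the calcium-like and
  transient-outward currents (mS/cm²; identical to mS/µF at Cm = 1).
* `kd`, `kf` — multiplicative scale factors on τd and τf.  Values below 1
  accelerate the calcium-gate kinetics ("τd,τf = 0.3" in the figure
  conventions means kd = kf = 0.3); steady states are untouched.

In 2D the monodomain equation `∂V/∂t = −Iion/Cm + D ∇²V` is solved with
D = 0.001 cm²/ms on a square lattice, Δx = Δy = 0.0125 cm, no-flux
boundaries.  `GNa = 16 mS/cm²` (reduced from LR1's 23) gives a plane-wave
conduction velocity of ≈ 0.55 m/s at these settings.

### Choice of the Ito reversal potential

The source model for Ito,f uses a pure-Nernst potassium reversal
(≈ −88 mV); LR1's named constant `EK` is the IK reversal −77 mV (it
includes a sodium-permeability correction).  The package default is
`EK_tof = −77 mV`.  The choice was made by phenomenology: with −77 mV the
model reproduces the documented Ito behaviours as a set — spike-and-dome
with a notch near −30 mV at Gtof = 0.24, APD alternans at Gtof = 0.268
sustained at PCL 600 ms and eliminated at PCL 1200 ms — whereas with the
Nernst value the stronger driving force moves dome loss below
Gtof = 0.25 and removes the alternans window at 0.268 entirely.  The
constant is an ordinary `ModelParams` field; both conventions are a
one-line change apart.  The measured dome-loss threshold is ≈ 0.303 mS/µF
with −77 mV and ≈ 0.251 with the Nernst value; a reference threshold of
0.278 would correspond to a (non-physical) reversal near −82 mV, so some
residual formulation difference with the original Ito transcription is
likely and the threshold should be quoted with that caveat.

## Numerics

* **Integration.**  Explicit forward Euler for V and Cai, Rush–Larsen
  exponential update for all eight gates, Δt = 0.01 ms.  The exponential
  update is exact under voltage clamp and keeps every gate in [0, 1]
  unconditionally.  Halving Δt changes a paced APD by < 1 ms.
* **Lookup tables.**  All voltage-dependent quantities (y∞, exp(−Δt/τ),
  and the purely voltage-dependent K currents) are tabulated on a
  0.05 mV grid over [−110, +70] mV and linearly interpolated inside the
  numba kernels; tables are rebuilt for every (parameter set, Δt) pair.
  The exact scalar path (`lr1spiral.ionic`) is kept alongside and the two
  are cross-checked in the tests (sub-0.1 ms APD agreement).
* **Diffusion.**  5-point Laplacian; no-flux boundaries are imposed by
  edge-replicated ghost nodes, which conserves the spatial mean of V
  exactly in diffusion-only mode.  The explicit stability bound
  Δt < Δx²/(4D) ≈ 0.039 ms is enforced at call time.
* **Rest state.**  Found by stimulus-free relaxation (chunked, with a
  |dV/dt| tolerance), then the gates are pinned to y∞(Vrest).
* **Conduction velocity.**  Upstroke times are the linearly interpolated
  −40 mV crossings at two sensors in the middle half of the cable;
  CV = distance / Δt.  Explicit finite differences make CV mildly
  Δx-dependent; at the defaults the 400-site cable gives 0.553 m/s.

## Protocols

* **Pacing.**  Rectangular pulses, 1 ms × 57 µA/cm² (≈ 2× the diastolic
  threshold of 28.6 µA/cm² measured once by bisection at control
  parameters).  The standard conditioning train is 1000 beats at
  PCL 500 ms; a 50-beat train reproduces the final-beat APD within 2 ms
  (verified in the tests), and is the default depth for desk-scale work.
* **Representative AP for morphology.**  One beat elicited from the
  quiescent rest state.  At the Gtof values of interest the paced steady
  state at PCL 500 ms is a period-2 alternans (long dome beats alternating
  with short dome-less beats), so "the" steady-state AP does not exist
  there; the beat from rest is unique, matches the documented morphology
  values, and is what the notch/dome metrics and the dome-loss bisection
  use.  Notch = first local minimum after the upstroke peak within the
  first half of the AP; dome = a later maximum ≥ 5 mV above the notch;
  early repolarization = no dome and APD under half the Ito-free
  reference.
* **Restitution.**  S1S2 by default: the S1 train is restarted per point,
  one S2 after the last S1 repolarizes through −75 mV; DI = S2 onset −
  interpolated −75 mV crossing.  A dynamic-protocol mode
  (`run_dynamic_restitution`) is provided as well.
* **Spiral induction (cross-field).**  All cells start from the pre-paced
  single-cell state (tissue figures use PCL 2000 ms conditioning); a
  5-column strip on the left edge is paced once; when the center cell has
  depolarized above −55 mV and fallen back below it, the bottom half of
  the sheet (rows ≥ ny/2, y downward in array order) is clamped to exactly
  −30 mV for 2 ms, shearing the wave tail into a spiral.
* **Tip detection and run classification.**  Phase
  φ = atan2(V(t−τ)−V*, V(t)−V*) with V* = −30 mV, τ = 2 ms; tips are
  plaquettes with ±2π winding.  A run is classified after a 500 ms
  transient: *no_wave* if no tips remain; *breakup* if ≥ 4 tips persist
  through any 500 ms window; *stable* if a single tip wanders (RMS) less
  than 0.5 cm; *quasi-periodic* otherwise.  The constants are explicit
  config values standing in for what the source figures decided visually.

## Scales used by the shipped tests

Full-scale tissue experiments (1024² sites, multi-second horizons,
PCL 2000 conditioning) are supported by the same code paths but are
multi-hour jobs; the shipped test suite and examples run reduced versions
(cables of 400 sites; sheets of 96²–256²; horizons ≤ 2–4 s) chosen as the
smallest domains on which the induction and classification machinery
operates cleanly.  On domains much smaller than a wavelength a spiral may
terminate on the boundary instead of breaking up, so phase-diagram labels
from reduced grids must be read with their evidence records (tip-count
series), and threshold positions quoted from them carry a scale caveat.

Concretely, at accelerated kinetics (kd = kf = 0.3, PCL-2000 conditioning)
the paced APDs at Gsi = 0.01/0.03/0.08/0.09 are ≈ 62/98/193/219 ms, i.e.
wavelengths of ≈ 3.4/5.4/10.6/12.0 cm against the full study domain of
12.8 cm.  Measured consequences of reduction: the Gsi = 0.01 spiral is
sustained and stable from 192² up; at 192²–256² the Gsi ≥ 0.03 spirals
terminate on the boundary (no_wave); at 384² the Gsi = 0.03 spiral is
sustained but does not break up within a 1200 ms horizon, and Gsi = 0.08
still terminates.  The Gsi ≥ 0.09 regimes (where tissue APDs reach
0.5–1.1 s at kd = kf = 0.1–0.2) are deeper still into the long-wavelength
regime.  The breakup phase diagrams therefore require domains near the
full 1024² and multi-second horizons; the reduced-grid spiral checks in
the shipped suite assert the full-scale labels and fail where the physics
does not survive the reduction — the evidence records say which way.

## Known limitations

* The LR1/Mahajan rate transcriptions were verified against an
  independently written in-repo transcription; no external reference
  implementation is bundled.
* Ion concentrations other than Cai are fixed; no homeostasis, no
  anisotropy, no 3D.
* Pseudo-ECG amplitudes are arbitrary units (K = 1, infinite homogeneous
  medium); only shape and regularity are comparable across runs.
* The dome-loss threshold sits ≈ +9% of the reference value discussed
  above; all Gtof-indexed phenomena inherit that shift.
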