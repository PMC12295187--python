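"""Stimulation protocols: pacing trains, S1S2 restitution schedules and the
cross-field spiral-induction sequence.

The study is simulation-only, so this module generates every input the
experiments need.  Everything here is deterministic: identical parameters
and grids reproduce identical stimulus sequences bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import analysis
from .ionic import CellState, resting_state
from .kernels import CellKernel
from .params import ModelParams

#: rectangular pacing pulse defaults: ~2x the diastolic threshold measured
#: once for the control parameter set (threshold ~28.6 uA/cm^2 at 1 ms).
DEFAULT_PULSE_AMPLITUDE = 57.0   # uA/cm^2, depolarizing
DEFAULT_PULSE_DURATION = 1.0     # ms


@dataclass(frozen=True)
class PacingProtocol:
    """Periodic pacing train."""

    pcl: float                      # pacing cycle length, ms
    n_beats: int
    pulse_amplitude: float = DEFAULT_PULSE_AMPLITUDE
    pulse_duration: float = DEFAULT_PULSE_DURATION

    def __post_init__(self):
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if not (self.pcl > self.pulse_duration > 0):
            raise ValueError("need pcl > pulse_duration > 0")

    def stim_starts(self) -> np.ndarray:
        return np.arange(self.n_beats) * self.pcl


@dataclass(frozen=True)
class S1S2Schedule:
    """S1 conditioning train plus one premature S2 per diastolic interval."""

    s1: PacingProtocol
    di_list: tuple

    def __post_init__(self):
        di = tuple(float(d) for d in self.di_list)
        if not di or any(d <= 0 for d in di) or list(di) != sorted(di):
            raise ValueError("di_list must be non-empty, positive, ascending")
        object.__setattr__(self, "di_list", di)


@dataclass(frozen=True)
class CrossFieldProtocol:
    """Plane wave from the left edge, then a timed bottom-half voltage clamp.

    The center cell is monitored; once it has depolarized above
    ``trigger_v`` and then fallen back below it, every cell in the bottom
    half of the sheet is forced to exactly ``clamp_voltage`` for
    ``clamp_duration`` ms, which shears the repolarization tail of the plane
    wave into a free spiral tip.
    """

    trigger_v: float = -55.0        # mV
    clamp_voltage: float = -30.0    # mV
    clamp_duration: float = 2.0     # ms
    strip_width: int = 5            # columns paced at the left edge
    pulse_amplitude: float = DEFAULT_PULSE_AMPLITUDE
    pulse_duration: float = DEFAULT_PULSE_DURATION
    max_wait: float = 1500.0        # ms to wait for the trigger before erroring
                                    # (must exceed the tissue APD: the center
                                    # cell only re-crosses -55 mV downward at
                                    # the end of its AP)

    def __post_init__(self):
        if self.clamp_duration <= 0:
            raise ValueError("clamp_duration must be positive")
        if self.strip_width < 1:
            raise ValueError("strip_width must be >= 1")


@dataclass(frozen=True)
class RestitutionPoint:
    """One (DI, APD) restitution measurement; ``captured`` is False when the
    premature stimulus failed to elicit a propagated-size AP."""

    di_requested: float
    di: float
    apd: float
    captured: bool


def prepace_cell(params: ModelParams, protocol: PacingProtocol,
                 dt: float = 0.01, initial: CellState | None = None) -> CellState:
    """Pace a single cell for ``protocol.n_beats`` beats and return the state
    at the end of the last cycle (the standard initial condition for tissue).

    Raises ``FloatingPointError`` naming the beat index on numerical blow-up.
    """
    kern = CellKernel(params, dt)
    y = (initial or resting_state(params)).as_array()
    # chunk by groups of beats so a blow-up can be located cheaply
    group = 50
    done = 0
    while done < protocol.n_beats:
        n = min(group, protocol.n_beats - done)
        try:
            y = kern.run(y, n * protocol.pcl,
                         stim_starts=np.arange(n) * protocol.pcl,
                         stim_duration=protocol.pulse_duration,
                         stim_amplitude=protocol.pulse_amplitude)
        except FloatingPointError as e:
            raise FloatingPointError(
                f"numerical blow-up during pre-pacing, beats {done + 1}-{done + n}"
            ) from e
        done += n
    return CellState.from_array(y)


def paced_trace(params: ModelParams, protocol: PacingProtocol,
                record_beats: int = 1, dt: float = 0.01,
                record_dt: float = 0.05,
                initial: CellState | None = None):
    """Pace and record the last ``record_beats`` cycles.

    Returns ``(t, V, final_state)`` with t = 0 at the start of the first
    recorded beat.
    """
    if record_beats > protocol.n_beats:
        raise ValueError("record_beats exceeds n_beats")
    lead = protocol.n_beats - record_beats
    y0 = initial
    if lead > 0:
        y0 = prepace_cell(params, PacingProtocol(
            protocol.pcl, lead, protocol.pulse_amplitude, protocol.pulse_duration),
            dt=dt, initial=initial)
    kern = CellKernel(params, dt)
    y = (y0 or resting_state(params)).as_array()
    t, v, yf = kern.run_trace(
        y, record_beats * protocol.pcl,
        stim_starts=np.arange(record_beats) * protocol.pcl,
        stim_duration=protocol.pulse_duration,
        stim_amplitude=protocol.pulse_amplitude, record_dt=record_dt)
    return t, v, CellState.from_array(yf)


def single_ap_from_rest(params: ModelParams, duration: float = 500.0,
                        dt: float = 0.01, record_dt: float = 0.05,
                        pulse_amplitude: float = DEFAULT_PULSE_AMPLITUDE,
                        pulse_duration: float = DEFAULT_PULSE_DURATION):
    """Trace of one AP elicited from the quiescent rest state.

    This is the representative AP used for morphology readings: where the
    paced steady state alternates (dome / no-dome period-2), "the" steady AP
    is ill-defined, while the first beat from rest is unique.
    """
    rest = resting_state(params)
    kern = CellKernel(params, dt)
    t, v, _ = kern.run_trace(rest.as_array(), duration, stim_starts=[0.0],
                             stim_duration=pulse_duration,
                             stim_amplitude=pulse_amplitude,
                             record_dt=record_dt)
    return t, v


def run_s1s2(params: ModelParams, schedule: S1S2Schedule,
             dt: float = 0.01, record_dt: float = 0.05,
             s2_window: float = 900.0) -> list[RestitutionPoint]:
    """S1S2 restitution: for each requested DI, restart the S1 train, deliver
    one S2 after the last S1 repolarizes, and measure the S2 APD.

    DI is measured from the (interpolated) -75 mV repolarization crossing of
    the last S1 beat to the S2 onset.  Failed captures are flagged, not
    dropped.  Raises ``RuntimeError`` if no DI captures at all.
    """
    s1 = schedule.s1
    # state at the start of the last S1 beat
    if s1.n_beats > 1:
        y_pre = prepace_cell(params, PacingProtocol(
            s1.pcl, s1.n_beats - 1, s1.pulse_amplitude, s1.pulse_duration), dt=dt)
    else:
        y_pre = resting_state(params)
    kern = CellKernel(params, dt)

    # last S1 beat: find its repolarization time (same for every DI)
    t1, v1, _ = kern.run_trace(y_pre.as_array(), s2_window, stim_starts=[0.0],
                               stim_duration=s1.pulse_duration,
                               stim_amplitude=s1.pulse_amplitude,
                               record_dt=record_dt)
    eps = analysis.extract_apds(t1, v1, include_clipped=True)
    if not eps or eps[0].peak_v < 0.0:
        raise RuntimeError("last S1 beat did not elicit an AP")
    t_rep = eps[0].t_end

    points: list[RestitutionPoint] = []
    for di in schedule.di_list:
        t_s2 = round((t_rep + di) / dt) * dt
        y = kern.run(y_pre.as_array(), t_s2, stim_starts=[0.0],
                     stim_duration=s1.pulse_duration,
                     stim_amplitude=s1.pulse_amplitude)
        t2, v2, _ = kern.run_trace(y, s2_window, stim_starts=[0.0],
                                   stim_duration=s1.pulse_duration,
                                   stim_amplitude=s1.pulse_amplitude,
                                   record_dt=record_dt)
        eps2 = [e for e in analysis.extract_apds(t2, v2, include_clipped=True)
                if e.t_start < 2 * s1.pulse_duration + 5.0]
        di_actual = t_s2 - t_rep
        if eps2 and eps2[0].peak_v > 0.0:
            points.append(RestitutionPoint(di, di_actual, eps2[0].apd, True))
        else:
            points.append(RestitutionPoint(di, di_actual, 0.0, False))
    if not any(p.captured for p in points):
        raise RuntimeError("S2 failed to capture at every requested DI")
    return points


def run_dynamic_restitution(params: ModelParams, pcl_list,
                            n_beats: int = 20, dt: float = 0.01,
                            record_dt: float = 0.05) -> list[RestitutionPoint]:
    """Dynamic-protocol restitution: pace to the local steady state at each
    PCL and read (DI, APD) off the last two beats."""
    points: list[RestitutionPoint] = []
    for pcl in pcl_list:
        proto = PacingProtocol(float(pcl), n_beats)
        t, v, _ = paced_trace(params, proto, record_beats=2, dt=dt,
                              record_dt=record_dt)
        eps = analysis.extract_apds(t, v)
        if len(eps) >= 2:
            di = eps[-1].t_start - eps[-2].t_end
            points.append(RestitutionPoint(float(pcl), di, eps[-1].apd, True))
        else:
            points.append(RestitutionPoint(float(pcl), 0.0, 0.0, False))
    return points


def apply_cross_field(field, protocol: CrossFieldProtocol, dt: float = 0.01,
                      monitor_chunk: float = 0.1) -> list[tuple[str, float]]:
    """Run the cross-field induction sequence on a tissue sheet, in place.

    Launches a plane wave from the left edge, waits for the center cell to
    cross above then below ``trigger_v``, then clamps the bottom half
    (rows >= ny//2, y increasing downward in array order) to exactly
    ``clamp_voltage`` for ``clamp_duration`` ms.  Returns the event log as
    ``(event, t_ms)`` pairs.  Raises ``RuntimeError`` if the plane wave never
    triggers within ``protocol.max_wait``.
    """
    from .tissue import step_tissue  # local import to avoid a module cycle

    ny, nx = field.shape
    ci, cj = ny // 2, nx // 2
    events: list[tuple[str, float]] = [("pace_left_edge", field.t)]

    stim = np.zeros((ny, nx))
    stim[:, :protocol.strip_width] = protocol.pulse_amplitude
    step_tissue(field, dt, duration=protocol.pulse_duration, stim=stim)

    t0 = field.t
    armed = False
    while field.t - t0 < protocol.max_wait:
        step_tissue(field, dt, duration=monitor_chunk)
        vc = field.V[ci, cj]
        if not armed and vc > protocol.trigger_v:
            armed = True
            events.append(("center_above_trigger", field.t))
        elif armed and vc < protocol.trigger_v:
            events.append(("trigger", field.t))
            break
    else:
        raise RuntimeError("no plane wave detected at the center cell "
                           f"within {protocol.max_wait} ms")

    clamp = np.zeros((ny, nx), dtype=np.uint8)
    clamp[ny // 2:, :] = 1
    step_tissue(field, dt, duration=protocol.clamp_duration,
                clamp_mask=clamp, clamp_v=protocol.clamp_voltage)
    events.append(("clamp_released", field.t))
    return events


def find_diastolic_threshold(params: ModelParams,
                             pulse_duration: float = DEFAULT_PULSE_DURATION,
                             dt: float = 0.01, bracket=(1.0, 200.0),
                             resolution: float = 0.25) -> float:
    """Smallest rectangular-pulse amplitude (uA/cm^2) that elicits an AP from
    rest, found by bisection."""
    rest = resting_state(params).as_array()
    kern = CellKernel(params, dt)

    def elicits(amp: float) -> bool:
        _, v, _ = kern.run_trace(rest, 50.0, stim_starts=[0.0],
                                 stim_duration=pulse_duration,
                                 stim_amplitude=amp, record_dt=0.1)
        return v.max() > 0.0

    lo, hi = bracket
    if elicits(lo) or not elicits(hi):
        raise RuntimeError("threshold bracket invalid")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if elicits(mid):
            hi = mid
        else:
            lo = mid
    return hi
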