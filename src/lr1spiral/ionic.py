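"""Single-cell ionic model: LR1 currents plus a fast transient-outward K current.

The membrane obeys ``dV/dt = -(Iion - Istim)/Cm`` with a positive stimulus
parameter representing depolarizing current.  The total ionic current is

    Iion = INa + ISi + IK + IK1 + IKp + Ib + Itof

where every gated current has the Hodgkin-Huxley form
``I = G * (gates) * (V - E)`` and every gate y relaxes as
``dy/dt = (y_inf(V) - y) / tau_y(V)``.

The slow-inward gates d and f optionally have their time constants scaled by
the factors ``kd`` and ``kf`` of :class:`~lr1spiral.params.ModelParams`
(values below 1 accelerate the Ca kinetics); the steady states are untouched.

This module is the exact scalar/vector reference implementation.  The fast
table-driven kernels in :mod:`lr1spiral.kernels` are built from these same
rate functions and are cross-checked against it in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import ModelParams

GATE_NAMES = ("m", "h", "j", "d", "f", "x", "xtof", "ytof")

#: state-vector layout used by the array kernels
STATE_FIELDS = ("V", "m", "h", "j", "d", "f", "x", "xtof", "ytof", "Cai")
N_STATE = len(STATE_FIELDS)


@dataclass
class CellState:
    """Full dynamical state of one cell.

    Gates are dimensionless in [0, 1]; ``Cai`` is the intracellular calcium
    concentration in mM and must stay positive; ``V`` is in mV.
    """

    V: float
    m: float
    h: float
    j: float
    d: float
    f: float
    x: float
    xtof: float
    ytof: float
    Cai: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in STATE_FIELDS], dtype=np.float64)

    @classmethod
    def from_array(cls, a) -> "CellState":
        a = np.asarray(a, dtype=np.float64)
        if a.shape != (N_STATE,):
            raise ValueError(f"expected shape ({N_STATE},), got {a.shape}")
        return cls(*(float(v) for v in a))

    def validate(self) -> None:
        if not np.isfinite(self.V) or not (-120.0 <= self.V <= 80.0):
            raise ValueError(f"V out of physiological range: {self.V}")
        for g in GATE_NAMES:
            v = getattr(self, g)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"gate {g} outside [0, 1]: {v}")
        if not self.Cai > 0:
            raise ValueError(f"Cai must be positive: {self.Cai}")

    def copy(self) -> "CellState":
        return replace(self)


#: a conventional diastolic starting point; use :func:`resting_state` for the
#: exact rest state of a given parameter set.
DEFAULT_INITIAL = CellState(
    V=-84.5, m=0.0017, h=0.983, j=0.995, d=0.003, f=0.999,
    x=0.0057, xtof=0.004, ytof=0.95, Cai=2.0e-4,
)


@dataclass(frozen=True)
class GateKinetics:
    """Steady state and time constant of one gate at one voltage."""

    y_inf: float | np.ndarray
    tau_y: float | np.ndarray


@dataclass(frozen=True)
class CurrentBreakdown:
    """All membrane current densities (uA/cm^2) and their sum."""

    INa: float
    ISi: float
    IK: float
    IK1: float
    IKp: float
    Ib: float
    Itof: float

    @property
    def Iion(self) -> float:
        return self.INa + self.ISi + self.IK + self.IK1 + self.IKp + self.Ib + self.Itof


# ---------------------------------------------------------------------------
# rate functions
# ---------------------------------------------------------------------------

def _safe_ratio(num, den, limit):
    """num/den with a removable singularity replaced by its limit."""
    den = np.asarray(den, dtype=np.float64)
    small = np.abs(den) < 1.0e-9
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


def _alpha_beta(gate: str, V):
    V = np.asarray(V, dtype=np.float64)
    if gate == "m":
        u = V + 47.13
        am = 0.32 * _safe_ratio(u, 1.0 - np.exp(-0.1 * u), 1.0 / 0.1)
        bm = 0.08 * np.exp(-V / 11.0)
        return am, bm
    if gate == "h":
        low = V < -40.0
        ah = np.where(low, 0.135 * np.exp(-(V + 80.0) / 6.8), 0.0)
        bh = np.where(
            low,
            3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
            1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
        )
        return ah, bh
    if gate == "j":
        low = V < -40.0
        aj = np.where(
            low,
            (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
            * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
            0.0,
        )
        bj = np.where(
            low,
            0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
            0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
        )
        return aj, bj
    if gate == "d":
        ad = 0.095 * np.exp(-0.01 * (V - 5.0)) / (1.0 + np.exp(-0.072 * (V - 5.0)))
        bd = 0.07 * np.exp(-0.017 * (V + 44.0)) / (1.0 + np.exp(0.05 * (V + 44.0)))
        return ad, bd
    if gate == "f":
        af = 0.012 * np.exp(-0.008 * (V + 28.0)) / (1.0 + np.exp(0.15 * (V + 28.0)))
        bf = 0.0065 * np.exp(-0.02 * (V + 30.0)) / (1.0 + np.exp(-0.2 * (V + 30.0)))
        return af, bf
    if gate == "x":
        ax = 0.0005 * np.exp(0.083 * (V + 50.0)) / (1.0 + np.exp(0.057 * (V + 50.0)))
        bx = 0.0013 * np.exp(-0.06 * (V + 20.0)) / (1.0 + np.exp(-0.04 * (V + 20.0)))
        return ax, bx
    raise KeyError(f"unknown gate {gate!r}")


def gate_kinetics(gate: str, V, params: ModelParams | None = None) -> GateKinetics:
    """Steady state ``y_inf(V)`` and time constant ``tau_y(V)`` of one gate.

    ``gate`` is one of ``m h j d f x xtof ytof``.  The tau-scale factors
    ``params.kd``/``params.kf`` multiply tau_d and tau_f only.
    Accepts scalar or array V (must be finite).
    """
    if params is None:
        params = ModelParams()
    Va = np.asarray(V, dtype=np.float64)
    if not np.all(np.isfinite(Va)):
        raise ValueError("V must be finite")
    scalar = Va.ndim == 0

    if gate == "xtof":
        y_inf = 1.0 / (1.0 + np.exp(-(Va + 3.0) / 15.0))
        tau = 3.5 * np.exp(-((Va / 30.0) ** 2)) + 1.5
    elif gate == "ytof":
        y_inf = 1.0 / (1.0 + np.exp((Va + 33.5) / 10.0))
        tau = 20.0 / (1.0 + np.exp((Va + 33.5) / 10.0)) + 20.0
    elif gate in ("m", "h", "j", "d", "f", "x"):
        a, b = _alpha_beta(gate, Va)
        y_inf = a / (a + b)
        tau = 1.0 / (a + b)
        if gate == "d":
            tau = params.kd * tau
        elif gate == "f":
            tau = params.kf * tau
    else:
        raise KeyError(f"unknown gate {gate!r}")

    if scalar:
        return GateKinetics(float(y_inf), float(tau))
    return GateKinetics(y_inf, tau)


# ---------------------------------------------------------------------------
# currents
# ---------------------------------------------------------------------------

def _xi_factor(V):
    """Voltage-dependent inactivation-like factor of the time-dependent IK."""
    V = np.asarray(V, dtype=np.float64)
    u = V + 77.0
    xi_mid = 2.837 * _safe_ratio(
        np.exp(0.04 * u) - 1.0, u * np.exp(0.04 * (V + 35.0)),
        0.04 / np.exp(0.04 * (-77.0 + 35.0)),
    )
    return np.where(V > -100.0, xi_mid, 1.0)


def _k1_inf(V, EK1):
    dv = np.asarray(V, dtype=np.float64) - EK1
    ak1 = 1.02 / (1.0 + np.exp(0.2385 * (dv - 59.215)))
    bk1 = (
        0.49124 * np.exp(0.08032 * (dv + 5.476))
        + np.exp(0.06175 * (dv - 594.31))
    ) / (1.0 + np.exp(-0.5143 * (dv + 4.753)))
    return ak1 / (ak1 + bk1)


def esi_reversal(Cai, params: ModelParams) -> float:
    """Slow-inward reversal potential, mV; Cai in mM (must be > 0)."""
    Cai = np.asarray(Cai, dtype=np.float64)
    if np.any(Cai <= 0):
        raise ValueError("Cai must be positive")
    return params.ESi_a - params.ESi_b * np.log(Cai)


def total_current(state: CellState, params: ModelParams) -> CurrentBreakdown:
    """Instantaneous breakdown of all membrane currents for one cell."""
    V = state.V
    esi = float(esi_reversal(state.Cai, params))
    ina = params.GNa * state.m ** 3 * state.h * state.j * (V - params.ENa)
    isi = params.Gsi * state.d * state.f * (V - esi)
    ik = params.GK * state.x * float(_xi_factor(V)) * (V - params.EK)
    ik1 = params.GK1 * float(_k1_inf(V, params.EK1)) * (V - params.EK1)
    ikp = params.GKp / (1.0 + np.exp((7.488 - V) / 5.98)) * (V - params.EK1)
    ib = params.Gb * (V - params.Eb)
    itof = params.Gtof * state.xtof * state.ytof * (V - params.EK_tof)
    return CurrentBreakdown(ina, isi, ik, ik1, ikp, ib, itof)


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def step_cell(state: CellState, istim: float, dt: float, params: ModelParams) -> CellState:
    """Advance one cell by one time step.

    Forward Euler for V and Cai; exponential (Rush-Larsen) update for all
    gates, which keeps them in [0, 1] unconditionally.  ``istim`` is the
    stimulus current density in uA/cm^2, positive = depolarizing.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cur = total_current(state, params)
    v_new = state.V + dt * (-cur.Iion + istim) / params.Cm

    gates = {}
    for g in GATE_NAMES:
        kin = gate_kinetics(g, state.V, params)
        y = getattr(state, g)
        gates[g] = kin.y_inf + (y - kin.y_inf) * np.exp(-dt / kin.tau_y)

    cai_new = state.Cai + dt * (
        -params.cai_influx_coeff * cur.ISi
        + params.cai_uptake_rate * (params.cai_rest - state.Cai)
    )
    out = CellState(V=v_new, Cai=cai_new, **gates)
    if not np.isfinite(v_new) or not np.isfinite(cai_new):
        raise FloatingPointError("numerical blow-up: non-finite state after step")
    return out


def resting_state(
    params: ModelParams,
    tol: float = 1.0e-9,
    dt: float = 0.05,
    t_max: float = 60_000.0,
) -> CellState:
    """Relax the cell without stimulus until ``|dV/dt| < tol`` (mV/ms).

    Raises ``RuntimeError`` if the quiescent state is not reached within
    ``t_max`` ms of simulated time.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    from .kernels import CellKernel  # deferred: numba compilation on demand

    kern = CellKernel(params, dt)
    y = DEFAULT_INITIAL.as_array()
    chunk = 500.0  # ms between convergence checks
    t = 0.0
    while t < t_max:
        y_prev = y.copy()
        y = kern.run(y, chunk, stim_starts=(), stim_duration=1.0, stim_amplitude=0.0)
        t += chunk
        dvdt = abs(y[0] - y_prev[0]) / chunk
        if dvdt < tol:
            state = CellState.from_array(y)
            # pin the gates to their exact steady states at the final voltage
            for g in GATE_NAMES:
                setattr(state, g, float(gate_kinetics(g, state.V, params).y_inf))
            return state
    raise RuntimeError(f"no rest state within {t_max} ms (|dV/dt| still >= {tol})")
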