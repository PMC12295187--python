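"""Single-cell ionic model: gate kinetics, current breakdown, stepping."""

import math

import numpy as np
import pytest

from lr1spiral import (CellState, ModelParams, gate_kinetics, resting_state,
                       step_cell, total_current)
from lr1spiral.ionic import DEFAULT_INITIAL, GATE_NAMES
from lr1spiral.kernels import CellKernel, build_tables

V_GRID = [-80.0, -40.0, 0.0, 40.0]


# ---------------------------------------------------------------------------
# independent scalar transcription of the published rate equations, written
# separately from the implementation on purpose (dual-implementation oracle)
# ---------------------------------------------------------------------------

def oracle_rates(gate, v):
    e = math.exp
    if gate == "m":
        a = 0.32 * (v + 47.13) / (1.0 - e(-0.1 * (v + 47.13)))
        b = 0.08 * e(-v / 11.0)
    elif gate == "h":
        if v < -40.0:
            a = 0.135 * e((80.0 + v) / -6.8)
            b = 3.56 * e(0.079 * v) + 3.1e5 * e(0.35 * v)
        else:
            a = 0.0
            b = 1.0 / (0.13 * (1.0 + e((v + 10.66) / -11.1)))
    elif gate == "j":
        if v < -40.0:
            a = ((-1.2714e5 * e(0.2444 * v) - 3.474e-5 * e(-0.04391 * v))
                 * (v + 37.78) / (1.0 + e(0.311 * (v + 79.23))))
            b = 0.1212 * e(-0.01052 * v) / (1.0 + e(-0.1378 * (v + 40.14)))
        else:
            a = 0.0
            b = 0.3 * e(-2.535e-7 * v) / (1.0 + e(-0.1 * (v + 32.0)))
    elif gate == "d":
        a = 0.095 * e(-0.01 * (v - 5.0)) / (1.0 + e(-0.072 * (v - 5.0)))
        b = 0.07 * e(-0.017 * (v + 44.0)) / (1.0 + e(0.05 * (v + 44.0)))
    elif gate == "f":
        a = 0.012 * e(-0.008 * (v + 28.0)) / (1.0 + e(0.15 * (v + 28.0)))
        b = 0.0065 * e(-0.02 * (v + 30.0)) / (1.0 + e(-0.2 * (v + 30.0)))
    elif gate == "x":
        a = 0.0005 * e(0.083 * (v + 50.0)) / (1.0 + e(0.057 * (v + 50.0)))
        b = 0.0013 * e(-0.06 * (v + 20.0)) / (1.0 + e(-0.04 * (v + 20.0)))
    else:
        raise KeyError(gate)
    return a, b


def oracle_tof_kinetics(gate, v):
    e = math.exp
    if gate == "xtof":
        return 1.0 / (1.0 + e(-(v + 3.0) / 15.0)), 3.5 * e(-((v / 30.0) ** 2)) + 1.5
    if gate == "ytof":
        yi = 1.0 / (1.0 + e((v + 33.5) / 10.0))
        return yi, 20.0 / (1.0 + e((v + 33.5) / 10.0)) + 20.0
    raise KeyError(gate)


def oracle_currents(s: CellState, p: ModelParams):
    e, ln = math.exp, math.log
    v = s.V
    ina = p.GNa * s.m ** 3 * s.h * s.j * (v - p.ENa)
    esi = 7.7 - 13.0287 * ln(s.Cai)
    isi = p.Gsi * s.d * s.f * (v - esi)
    if v > -100.0:
        xi = 2.837 * (e(0.04 * (v + 77.0)) - 1.0) / ((v + 77.0) * e(0.04 * (v + 35.0)))
    else:
        xi = 1.0
    ik = p.GK * s.x * xi * (v - p.EK)
    dv = v - p.EK1
    ak1 = 1.02 / (1.0 + e(0.2385 * (dv - 59.215)))
    bk1 = ((0.49124 * e(0.08032 * (dv + 5.476)) + e(0.06175 * (dv - 594.31)))
           / (1.0 + e(-0.5143 * (dv + 4.753))))
    ik1 = p.GK1 * ak1 / (ak1 + bk1) * dv
    ikp = p.GKp * (v - p.EK1) / (1.0 + e((7.488 - v) / 5.98))
    ib = p.Gb * (v + 59.87)
    itof = p.Gtof * s.xtof * s.ytof * (v - p.EK_tof)
    return ina, isi, ik, ik1, ikp, ib, itof


FIXED_STATE = CellState(V=-20.0, m=0.4, h=0.3, j=0.5, d=0.2, f=0.8,
                        x=0.15, xtof=0.3, ytof=0.6, Cai=5.0e-4)


class TestGateKinetics:
    @pytest.mark.parametrize("gate", GATE_NAMES)
    @pytest.mark.parametrize("v", V_GRID)
    def test_matches_independent_transcription(self, gate, v):
        kin = gate_kinetics(gate, v, ModelParams())
        if gate in ("xtof", "ytof"):
            yi, tau = oracle_tof_kinetics(gate, v)
        else:
            a, b = oracle_rates(gate, v)
            yi, tau = a / (a + b), 1.0 / (a + b)
        assert kin.y_inf == pytest.approx(yi, abs=1e-12)
        assert kin.tau_y == pytest.approx(tau, rel=1e-12)

    @pytest.mark.parametrize("gate", GATE_NAMES)
    def test_identity_scaling_leaves_all_gates_unchanged(self, gate):
        base = ModelParams(kd=1.0, kf=1.0)
        v = np.linspace(-100.0, 50.0, 301)
        kin = gate_kinetics(gate, v, base)
        ref = gate_kinetics(gate, v, ModelParams())
        np.testing.assert_array_equal(kin.y_inf, ref.y_inf)
        np.testing.assert_array_equal(kin.tau_y, ref.tau_y)

    @pytest.mark.parametrize("gate,scaled", [("d", True), ("f", True),
                                             ("m", False), ("x", False),
                                             ("ytof", False)])
    def test_tau_scaling_hits_only_the_ca_gates(self, gate, scaled):
        v = np.linspace(-90.0, 40.0, 53)
        fast = ModelParams(kd=0.3, kf=0.3)
        kin = gate_kinetics(gate, v, fast)
        ref = gate_kinetics(gate, v, ModelParams())
        np.testing.assert_allclose(kin.y_inf, ref.y_inf, rtol=0, atol=0)
        factor = 0.3 if scaled else 1.0
        np.testing.assert_allclose(kin.tau_y, factor * np.asarray(ref.tau_y),
                                   rtol=1e-14)

    def test_bounds_and_positivity(self):
        v = np.linspace(-110.0, 70.0, 1801)
        for gate in GATE_NAMES:
            kin = gate_kinetics(gate, v, ModelParams())
            assert np.all((np.asarray(kin.y_inf) >= 0)
                          & (np.asarray(kin.y_inf) <= 1))
            assert np.all(np.asarray(kin.tau_y) > 0)

    def test_rejects_bad_input(self):
        with pytest.raises(KeyError):
            gate_kinetics("q", -80.0, ModelParams())
        with pytest.raises(ValueError):
            gate_kinetics("m", float("nan"), ModelParams())

    @pytest.mark.parametrize("gate", GATE_NAMES)
    @pytest.mark.parametrize("v", V_GRID)
    def test_clamped_relaxation_matches_closed_form(self, gate, v):
        """Under voltage clamp each gate relaxes as
        y(t) = y_inf + (y0 - y_inf) exp(-t/tau): the package's exponential
        update must reproduce it, and an independent adaptive ODE solve of
        dy/dt = (y_inf - y)/tau must agree to 1e-6."""
        from scipy.integrate import solve_ivp

        p = ModelParams()
        kin = gate_kinetics(gate, v, p)
        y0, dt, t_end = 0.2, 0.01, 20.0
        exact = kin.y_inf + (y0 - kin.y_inf) * math.exp(-t_end / kin.tau_y)
        # package scheme (Rush-Larsen), stepped at dt
        y = y0
        for _ in range(int(round(t_end / dt))):
            y = kin.y_inf + (y - kin.y_inf) * math.exp(-dt / kin.tau_y)
        assert y == pytest.approx(exact, abs=1e-9)
        # independent numeric oracle
        sol = solve_ivp(lambda t, yy: (kin.y_inf - yy) / kin.tau_y,
                        (0.0, t_end), [y0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(exact, abs=1e-6)


class TestTotalCurrent:
    def test_matches_independent_transcription(self):
        p = ModelParams(Gtof=0.2)
        cur = total_current(FIXED_STATE, p)
        ina, isi, ik, ik1, ikp, ib, itof = oracle_currents(FIXED_STATE, p)
        assert cur.INa == pytest.approx(ina, abs=1e-10)
        assert cur.ISi == pytest.approx(isi, abs=1e-10)
        assert cur.IK == pytest.approx(ik, abs=1e-10)
        assert cur.IK1 == pytest.approx(ik1, abs=1e-10)
        assert cur.IKp == pytest.approx(ikp, abs=1e-10)
        assert cur.Ib == pytest.approx(ib, abs=1e-10)
        assert cur.Itof == pytest.approx(itof, abs=1e-10)
        assert cur.Iion == pytest.approx(ina + isi + ik + ik1 + ikp + ib + itof,
                                         abs=1e-10)

    def test_zero_conductance_removes_ito_exactly(self):
        p0 = ModelParams(Gtof=0.0)
        cur = total_current(FIXED_STATE, p0)
        assert cur.Itof == 0.0
        ref = total_current(FIXED_STATE, ModelParams())
        assert cur.Iion == ref.Iion

    def test_ito_vanishes_at_its_reversal(self):
        p = ModelParams(Gtof=0.5)
        s = CellState(V=p.EK_tof, m=0.1, h=0.9, j=0.9, d=0.1, f=0.9,
                      x=0.1, xtof=0.9, ytof=0.9, Cai=2e-4)
        assert total_current(s, p).Itof == 0.0

    def test_nonpositive_calcium_rejected(self):
        s = FIXED_STATE.copy()
        s.Cai = 0.0
        with pytest.raises(ValueError):
            total_current(s, ModelParams())


class TestStepCell:
    def test_rest_state_is_a_fixed_point(self, control_params, rest_control):
        s = rest_control
        s2 = step_cell(s, 0.0, 0.01, control_params)
        assert abs(s2.V - s.V) < 1e-6
        for g in GATE_NAMES:
            assert abs(getattr(s2, g) - getattr(s, g)) < 1e-9

    def test_stimulus_elicits_action_potential(self, control_params, rest_control):
        kern = CellKernel(control_params, dt=0.01)
        t, v, _ = kern.run_trace(rest_control.as_array(), 400.0,
                                 stim_starts=[0.0], stim_duration=1.0,
                                 stim_amplitude=57.0, record_dt=0.05)
        up = np.argmax(v > 0.0)
        assert v.max() > 0.0 and t[up] < 5.0       # fast upstroke
        assert v[-1] < -75.0                        # full repolarization

    def test_gates_stay_boxed(self, control_params, rest_control):
        s = rest_control
        for k in range(2000):
            s = step_cell(s, 57.0 if k < 100 else 0.0, 0.02, control_params)
            for g in GATE_NAMES:
                assert 0.0 <= getattr(s, g) <= 1.0

    def test_dt_halving_changes_apd_below_1ms(self, control_params, rest_control):
        from lr1spiral import extract_apds

        apds = {}
        for dt in (0.01, 0.005):
            kern = CellKernel(control_params, dt=dt)
            t, v, _ = kern.run_trace(rest_control.as_array(), 450.0,
                                     stim_starts=[0.0], stim_duration=1.0,
                                     stim_amplitude=57.0, record_dt=0.05)
            apds[dt] = extract_apds(t, v)[0].apd
        assert abs(apds[0.01] - apds[0.005]) < 1.0

    def test_table_kernel_matches_exact_path(self, control_params, rest_control):
        """The interpolated-table fast path and the exact scalar stepper must
        produce the same AP (sub-0.1 ms APD agreement)."""
        from lr1spiral import extract_apds

        dt = 0.01
        s = rest_control
        vs = []
        for k in range(int(450.0 / dt)):
            s = step_cell(s, 57.0 if k * dt < 1.0 else 0.0, dt, control_params)
            if k % 5 == 0:
                vs.append(s.V)
        t = np.arange(len(vs)) * 5 * dt
        apd_exact = extract_apds(t, np.asarray(vs))[0].apd
        kern = CellKernel(control_params, dt=dt)
        tt, vv, _ = kern.run_trace(rest_control.as_array(), 450.0,
                                   stim_starts=[0.0], stim_duration=1.0,
                                   stim_amplitude=57.0, record_dt=0.05)
        apd_tab = extract_apds(tt, vv)[0].apd
        assert abs(apd_exact - apd_tab) < 0.1


class TestRestingState:
    def test_in_physiological_range(self, rest_control):
        assert -90.0 <= rest_control.V <= -80.0

    def test_gates_at_steady_state(self, control_params, rest_control):
        for g in GATE_NAMES:
            kin = gate_kinetics(g, rest_control.V, control_params)
            assert getattr(rest_control, g) == pytest.approx(kin.y_inf, abs=1e-9)

    def test_invariant_under_kernel_stepping(self, control_params, rest_control):
        kern = CellKernel(control_params, dt=0.01)
        y = kern.run(rest_control.as_array(), 100.0)
        assert abs(y[0] - rest_control.V) < 1e-3


def test_state_roundtrip_and_validation():
    s = DEFAULT_INITIAL
    s2 = CellState.from_array(s.as_array())
    assert s2 == s
    s2.validate()
    bad = s.copy()
    bad.m = 1.5
    with pytest.raises(ValueError):
        bad.validate()


def test_params_config_roundtrip(tmp_path):
    p = ModelParams(Gsi=0.05, Gtof=0.24, kd=0.3, kf=0.3)
    f = tmp_path / "params.yaml"
    p.save(f)
    q = ModelParams.load(f)
    assert q == p
    with pytest.raises(ValueError):
        ModelParams(GNa=-1.0)
    with pytest.raises(KeyError):
        ModelParams.from_dict({"nope": 1})


def test_tables_reproduce_kinetics_to_interpolation_accuracy():
    p = ModelParams(kd=0.3, kf=0.3)
    tab = build_tables(p, dt=0.01)
    v = -62.512  # off-grid voltage
    from lr1spiral.kernels import TABLE_DV, TABLE_VMIN

    idx = (v - TABLE_VMIN) / TABLE_DV
    i0, w = int(idx), idx - int(idx)
    for k, g in enumerate(("m", "h", "j", "d", "f", "x", "xtof", "ytof")):
        kin = gate_kinetics(g, v, p)
        y_tab = tab[i0, 2 * k] + w * (tab[i0 + 1, 2 * k] - tab[i0, 2 * k])
        assert y_tab == pytest.approx(kin.y_inf, abs=1e-5)
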