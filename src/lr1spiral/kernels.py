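"""Table-driven numba kernels for fast single-cell, cable and 2D stepping.

All voltage-dependent quantities (gate steady states, Rush-Larsen decay
factors exp(-dt/tau), and the purely voltage-dependent K currents) are
pre-tabulated on a uniform voltage grid and linearly interpolated inside the
inner loop.  Tables are rebuilt for every (params, dt) pair, so the tau-scale
factors kd/kf and the fixed conductances are baked in; GNa, Gsi and Gtof are
applied inline and never enter the tables.

The exact (non-tabulated) reference path lives in :mod:`lr1spiral.ionic`;
the test suite checks the two against each other.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import ionic
from .params import ModelParams

TABLE_VMIN = -110.0
TABLE_VMAX = 70.0
TABLE_DV = 0.05

# table column layout: [y_inf, exp(-dt/tau)] per gate in ionic.GATE_NAMES order,
# then the x-independent K currents and the IK coefficient.
_COL_IK1KPB = 16   # IK1 + IKp + Ib evaluated at V
_COL_IKCOEF = 17   # GK * Xi(V) * (V - EK); multiply by gate x
N_COLS = 18


def build_tables(params: ModelParams, dt: float) -> np.ndarray:
    """Voltage lookup table for a given parameter set and time step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    V = np.arange(TABLE_VMIN, TABLE_VMAX + TABLE_DV / 2, TABLE_DV)
    tab = np.empty((V.size, N_COLS), dtype=np.float64)
    for k, g in enumerate(ionic.GATE_NAMES):
        kin = ionic.gate_kinetics(g, V, params)
        tab[:, 2 * k] = kin.y_inf
        tab[:, 2 * k + 1] = np.exp(-dt / kin.tau_y)
    ik1 = params.GK1 * ionic._k1_inf(V, params.EK1) * (V - params.EK1)
    ikp = params.GKp / (1.0 + np.exp((7.488 - V) / 5.98)) * (V - params.EK1)
    ib = params.Gb * (V - params.Eb)
    tab[:, _COL_IK1KPB] = ik1 + ikp + ib
    tab[:, _COL_IKCOEF] = params.GK * ionic._xi_factor(V) * (V - params.EK)
    return np.ascontiguousarray(tab)


def _scalar_consts(params: ModelParams) -> tuple:
    p = params
    return (p.GNa, p.Gsi, p.Gtof, p.ENa, p.EK_tof, p.ESi_a, p.ESi_b,
            p.cai_rest, p.cai_uptake_rate, p.cai_influx_coeff, p.Cm)


@njit(cache=True, fastmath=True)
def _cell_run(y, tab, dt, n_steps, stim_starts, stim_dur_steps, stim_amp,
              gna, gsi, gtof, ena, ektof, esia, esib,
              cai_rest, cai_up, cai_in, cm, record_stride, v_rec):
    inv_dv = 1.0 / TABLE_DV
    nrow = tab.shape[0]
    nstim = stim_starts.shape[0]
    si = 0
    for step in range(n_steps):
        while si < nstim and step >= stim_starts[si] + stim_dur_steps:
            si += 1
        istim = stim_amp if (si < nstim and step >= stim_starts[si]) else 0.0

        V = y[0]
        if record_stride > 0 and step % record_stride == 0:
            v_rec[step // record_stride] = V
        idx = (V - TABLE_VMIN) * inv_dv
        if idx < 0.0:
            idx = 0.0
        if idx > nrow - 1.000001:
            idx = nrow - 1.000001
        i0 = int(idx)
        w = idx - i0

        esi = esia - esib * np.log(y[9])
        ina = gna * y[1] * y[1] * y[1] * y[2] * y[3] * (V - ena)
        isi = gsi * y[4] * y[5] * (V - esi)
        ikbg = tab[i0, 16] + w * (tab[i0 + 1, 16] - tab[i0, 16])
        ikco = tab[i0, 17] + w * (tab[i0 + 1, 17] - tab[i0, 17])
        itof = gtof * y[7] * y[8] * (V - ektof)
        iion = ina + isi + ikco * y[6] + ikbg + itof

        for k in range(8):
            yi = tab[i0, 2 * k] + w * (tab[i0 + 1, 2 * k] - tab[i0, 2 * k])
            ee = tab[i0, 2 * k + 1] + w * (tab[i0 + 1, 2 * k + 1] - tab[i0, 2 * k + 1])
            y[1 + k] = yi + (y[1 + k] - yi) * ee
        y[9] = y[9] + dt * (-cai_in * isi + cai_up * (cai_rest - y[9]))
        y[0] = V + dt * (-iion + istim) / cm
    return y


@njit(cache=True, fastmath=True)
def _tissue_steps(S, Vb, tab, dt, n_steps, alpha,
                  stim, use_stim, clamp_mask, use_clamp, clamp_v, ionic_on,
                  gna, gsi, gtof, ena, ektof, esia, esib,
                  cai_rest, cai_up, cai_in, cm,
                  rec_i, rec_j, rec):
    """Advance a 2D sheet (or 1D cable when ny == 1) by n_steps.

    Explicit forward Euler: 5-point Laplacian with edge-replicated ghost
    nodes (zero-flux), reaction term from the tables, optional additive
    stimulus-current field and optional voltage clamp applied after the
    update.  Records V at the (rec_i, rec_j) sites at every step.
    """
    ny, nx = S.shape[1], S.shape[2]
    V = S[0]
    inv_dv = 1.0 / TABLE_DV
    nrow = tab.shape[0]
    nrec = rec_i.shape[0]
    for step in range(n_steps):
        for r in range(nrec):
            rec[step, r] = V[rec_i[r], rec_j[r]]
        for i in range(ny):
            for j in range(nx):
                v = V[i, j]
                # zero-flux: ghost node replicates the edge value
                vl = V[i, j - 1] if j > 0 else v
                vr = V[i, j + 1] if j < nx - 1 else v
                vu = V[i - 1, j] if i > 0 else v
                vd = V[i + 1, j] if i < ny - 1 else v
                lap = vl + vr + vu + vd - 4.0 * v

                iion = 0.0
                if ionic_on:
                    idx = (v - TABLE_VMIN) * inv_dv
                    if idx < 0.0:
                        idx = 0.0
                    if idx > nrow - 1.000001:
                        idx = nrow - 1.000001
                    i0 = int(idx)
                    w = idx - i0
                    cai = S[9, i, j]
                    esi = esia - esib * np.log(cai)
                    ina = gna * S[1, i, j] * S[1, i, j] * S[1, i, j] * S[2, i, j] * S[3, i, j] * (v - ena)
                    isi = gsi * S[4, i, j] * S[5, i, j] * (v - esi)
                    ikbg = tab[i0, 16] + w * (tab[i0 + 1, 16] - tab[i0, 16])
                    ikco = tab[i0, 17] + w * (tab[i0 + 1, 17] - tab[i0, 17])
                    itof = gtof * S[7, i, j] * S[8, i, j] * (v - ektof)
                    iion = ina + isi + ikco * S[6, i, j] + ikbg + itof
                    for k in range(8):
                        yi = tab[i0, 2 * k] + w * (tab[i0 + 1, 2 * k] - tab[i0, 2 * k])
                        ee = tab[i0, 2 * k + 1] + w * (tab[i0 + 1, 2 * k + 1] - tab[i0, 2 * k + 1])
                        S[1 + k, i, j] = yi + (S[1 + k, i, j] - yi) * ee
                    S[9, i, j] = cai + dt * (-cai_in * isi + cai_up * (cai_rest - cai))

                istim = stim[i, j] if use_stim else 0.0
                vnew = v + dt * (-iion + istim) / cm + alpha * lap
                if use_clamp and clamp_mask[i, j]:
                    vnew = clamp_v
                Vb[i, j] = vnew
        for i in range(ny):
            for j in range(nx):
                V[i, j] = Vb[i, j]
    return S


class CellKernel:
    """Fast single-cell integrator bound to one (params, dt) pair."""

    def __init__(self, params: ModelParams, dt: float = 0.01):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.params = params
        self.dt = float(dt)
        self.tab = build_tables(params, self.dt)
        self._consts = _scalar_consts(params)

    def run(self, y: np.ndarray, duration: float, stim_starts=(),
            stim_duration: float = 1.0, stim_amplitude: float = 0.0) -> np.ndarray:
        """Advance state vector ``y`` (copied) by ``duration`` ms.

        ``stim_starts`` are onset times (ms, relative to the start of this
        call) of rectangular depolarizing pulses.
        """
        y = np.array(y, dtype=np.float64)
        n_steps = int(round(duration / self.dt))
        starts = np.asarray(
            [int(round(s / self.dt)) for s in sorted(stim_starts)], dtype=np.int64)
        dur_steps = max(1, int(round(stim_duration / self.dt)))
        dummy = np.empty(0, dtype=np.float64)
        _cell_run(y, self.tab, self.dt, n_steps, starts, dur_steps,
                  float(stim_amplitude), *self._consts, 0, dummy)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError("numerical blow-up in cell run")
        return y

    def run_trace(self, y: np.ndarray, duration: float, stim_starts=(),
                  stim_duration: float = 1.0, stim_amplitude: float = 0.0,
                  record_dt: float = 0.05):
        """Like :meth:`run` but also returns the sampled (t, V) trace."""
        y = np.array(y, dtype=np.float64)
        n_steps = int(round(duration / self.dt))
        stride = max(1, int(round(record_dt / self.dt)))
        n_rec = (n_steps + stride - 1) // stride
        v_rec = np.empty(n_rec, dtype=np.float64)
        starts = np.asarray(
            [int(round(s / self.dt)) for s in sorted(stim_starts)], dtype=np.int64)
        dur_steps = max(1, int(round(stim_duration / self.dt)))
        _cell_run(y, self.tab, self.dt, n_steps, starts, dur_steps,
                  float(stim_amplitude), *self._consts, stride, v_rec)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError("numerical blow-up in cell run")
        t = np.arange(n_rec) * (stride * self.dt)
        return t, v_rec, y
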