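"""Monodomain tissue solver: 1D cables and 2D sheets.

The voltage obeys dV/dt = -Iion/Cm + D * Laplacian(V) on a uniform square
lattice with zero-flux boundaries, integrated by explicit forward Euler with
the 5-point Laplacian (edge-replicated ghost nodes).  Defaults follow the
study conditions: dx = dy = 0.0125 cm, D = 0.001 cm^2/ms, dt = 0.01 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ionic import CellState, N_STATE, resting_state
from .kernels import CellKernel, _tissue_steps, build_tables, _scalar_consts
from .params import ModelParams
from .protocols import (DEFAULT_PULSE_AMPLITUDE, DEFAULT_PULSE_DURATION,
                        PacingProtocol, prepace_cell)

DEFAULT_DX = 0.0125   # cm
DEFAULT_D = 0.001     # cm^2/ms
DEFAULT_DT = 0.01     # ms
CV_UPSTROKE_V = -40.0  # mV, upstroke threshold for conduction-velocity timing


@dataclass
class TissueField:
    """Lattice of cell states; ``state`` has shape (n_vars, ny, nx)."""

    params: ModelParams
    state: np.ndarray
    dx: float = DEFAULT_DX
    D: float = DEFAULT_D
    t: float = 0.0

    def __post_init__(self):
        if self.state.ndim != 3 or self.state.shape[0] != N_STATE:
            raise ValueError(f"state must have shape ({N_STATE}, ny, nx)")
        if self.D < 0 or self.dx <= 0:
            raise ValueError("need D >= 0 and dx > 0")
        self._tab_cache: dict = {}

    @property
    def shape(self) -> tuple[int, int]:
        return self.state.shape[1], self.state.shape[2]

    @property
    def V(self) -> np.ndarray:
        return self.state[0]

    def stability_limit(self) -> float:
        """Largest stable explicit time step, dx^2/(4D) (inf when D = 0)."""
        return np.inf if self.D == 0 else self.dx ** 2 / (4.0 * self.D)

    def tables(self, dt: float) -> np.ndarray:
        key = (self.params.config_hash(), dt)
        if key not in self._tab_cache:
            self._tab_cache.clear()
            self._tab_cache[key] = build_tables(self.params, dt)
        return self._tab_cache[key]

    def copy(self) -> "TissueField":
        return TissueField(self.params, self.state.copy(), self.dx, self.D, self.t)


def uniform_field(params: ModelParams, nx: int, ny: int = 1,
                  init: CellState | None = None,
                  dx: float = DEFAULT_DX, D: float = DEFAULT_D) -> TissueField:
    """Spatially uniform tissue, every cell initialized to ``init``
    (pre-paced state by convention; rest state when ``init`` is None)."""
    if nx < 3 or (ny != 1 and ny < 3):
        raise ValueError("grid must be >= 3 sites in each simulated dimension")
    if init is None:
        init = resting_state(params)
    y = init.as_array()
    state = np.empty((N_STATE, ny, nx), dtype=np.float64)
    state[:] = y[:, None, None]
    return TissueField(params, state, dx=dx, D=D)


def step_tissue(field: TissueField, dt: float = DEFAULT_DT, *,
                n_steps: int | None = None, duration: float | None = None,
                stim: np.ndarray | None = None,
                clamp_mask: np.ndarray | None = None, clamp_v: float = -30.0,
                ionic_on: bool = True,
                record_sites=None) -> np.ndarray | None:
    """Advance the field in place by ``n_steps`` (or ``duration`` ms).

    ``stim`` is an additive current-density field (uA/cm^2, positive =
    depolarizing) applied on every step of this call; ``clamp_mask`` forces
    masked sites to exactly ``clamp_v`` after each update.  With
    ``ionic_on=False`` the membrane reaction term is switched off
    (pure diffusion).  ``record_sites`` is a list of (row, col) pairs whose
    voltage is recorded every step; the (n_steps, n_sites) array is returned.
    """
    if (n_steps is None) == (duration is None):
        raise ValueError("give exactly one of n_steps / duration")
    if duration is not None:
        n_steps = int(round(duration / dt))
    if n_steps < 0:
        raise ValueError("negative step count")
    if n_steps == 0:
        return None
    if dt > field.stability_limit():
        raise ValueError(
            f"dt = {dt} ms violates the explicit-diffusion stability bound "
            f"dx^2/(4D) = {field.stability_limit():.4g} ms")
    ny, nx = field.shape
    alpha = field.D * dt / field.dx ** 2
    zeros2 = np.zeros((1, 1))
    stim_arr = np.ascontiguousarray(stim, dtype=np.float64) if stim is not None else zeros2
    use_stim = stim is not None
    clamp_arr = (np.ascontiguousarray(clamp_mask, dtype=np.uint8)
                 if clamp_mask is not None else np.zeros((1, 1), dtype=np.uint8))
    use_clamp = clamp_mask is not None
    if use_stim and stim_arr.shape != (ny, nx):
        raise ValueError("stim shape mismatch")
    if use_clamp and clamp_arr.shape != (ny, nx):
        raise ValueError("clamp_mask shape mismatch")

    if record_sites is not None and len(record_sites):
        rec_i = np.asarray([r for r, _ in record_sites], dtype=np.int64)
        rec_j = np.asarray([c for _, c in record_sites], dtype=np.int64)
        rec = np.empty((n_steps, rec_i.size), dtype=np.float64)
    else:
        rec_i = np.empty(0, dtype=np.int64)
        rec_j = np.empty(0, dtype=np.int64)
        rec = np.empty((n_steps, 0), dtype=np.float64)

    buf = np.empty((ny, nx), dtype=np.float64)
    _tissue_steps(field.state, buf, field.tables(dt), dt, n_steps, alpha,
                  stim_arr, use_stim, clamp_arr, use_clamp, float(clamp_v),
                  ionic_on, *_scalar_consts(field.params),
                  rec_i, rec_j, rec)
    field.t += n_steps * dt
    if not np.all(np.isfinite(field.V)):
        raise FloatingPointError(f"numerical blow-up in tissue at t = {field.t} ms")
    return rec if rec.shape[1] else None


@dataclass(frozen=True)
class CVResult:
    cv: float          # m/s
    t_first: float     # ms, upstroke time at the first sensor
    t_second: float    # ms, upstroke time at the second sensor
    sensors: tuple     # site indices


def _upstroke_time(t: np.ndarray, v: np.ndarray, threshold: float) -> float | None:
    above = v >= threshold
    if not above.any() or above[0]:
        return None
    k = int(np.argmax(above))
    f = (threshold - v[k - 1]) / (v[k] - v[k - 1])
    return float(t[k - 1] + f * (t[k] - t[k - 1]))


def measure_cv(params: ModelParams | None = None, n_sites: int = 400,
               dx: float = DEFAULT_DX, D: float = DEFAULT_D,
               dt: float = DEFAULT_DT,
               pulse_amplitude: float = DEFAULT_PULSE_AMPLITUDE,
               pulse_duration: float = DEFAULT_PULSE_DURATION,
               init: CellState | None = None, prepace_beats: int = 50,
               t_max: float = 250.0) -> CVResult:
    """Plane-wave conduction velocity on a 1D cable, in m/s.

    A 5-site strip at the left end is stimulated once from the pre-paced
    state; the upstroke (interpolated -40 mV crossing) is timed at two
    sensors placed in the middle half of the cable.  Raises ``RuntimeError``
    on propagation failure.
    """
    params = params or ModelParams()
    if init is None:
        init = prepace_cell(params, PacingProtocol(500.0, prepace_beats))
    field = uniform_field(params, n_sites, 1, init=init, dx=dx, D=D)
    s1, s2 = n_sites // 3, (2 * n_sites) // 3
    stim = np.zeros((1, n_sites))
    stim[0, :5] = pulse_amplitude
    rec_a = step_tissue(field, dt, duration=pulse_duration, stim=stim,
                        record_sites=[(0, s1), (0, s2)])
    rec_b = step_tissue(field, dt, duration=t_max,
                        record_sites=[(0, s1), (0, s2)])
    rec = np.vstack([rec_a, rec_b])
    t = np.arange(rec.shape[0]) * dt
    t1 = _upstroke_time(t, rec[:, 0], CV_UPSTROKE_V)
    t2 = _upstroke_time(t, rec[:, 1], CV_UPSTROKE_V)
    if t1 is None or t2 is None or t2 <= t1:
        raise RuntimeError("propagation failure: wavefront did not traverse "
                           "both sensor sites")
    cv_cm_per_ms = (s2 - s1) * dx / (t2 - t1)
    return CVResult(cv=cv_cm_per_ms * 10.0, t_first=t1, t_second=t2,
                    sensors=(s1, s2))


@dataclass
class SnapshotSeries:
    """Voltage-field snapshots at a fixed stride, with run metadata."""

    times: list = field(default_factory=list)
    frames: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def append(self, t: float, v: np.ndarray) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("snapshot times must be strictly increasing")
        if self.frames and v.shape != self.frames[-1].shape:
            raise ValueError("inconsistent frame shape")
        self.times.append(float(t))
        self.frames.append(np.array(v, dtype=np.float64))

    def __len__(self) -> int:
        return len(self.times)

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=np.asarray(self.times))
            f.create_dataset("V", data=np.stack(self.frames),
                             chunks=(1, *self.frames[0].shape),
                             compression="gzip", compression_opts=4)
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "SnapshotSeries":
        import h5py

        with h5py.File(path, "r") as f:
            s = cls(times=list(np.asarray(f["t"])),
                    frames=list(np.asarray(f["V"])),
                    meta=dict(f.attrs))
        return s
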