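"""Pseudo-ECGs from 2D voltage-field time series.

The extracellular potential at an electrode r' in an infinite homogeneous
medium is proportional to the integral of grad(V) . grad(1/|r - r'|) over
the tissue sheet; amplitudes are reported in arbitrary units (K = 1) and
only trace shape and regularity are meaningful.  Four standard probe
placements mirror the study: unipolar probes just beyond the right edge and
the top edge (in plane), a unipolar probe above the sheet center, and a
closely spaced bipolar pair above the center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Probe:
    """Virtual electrode; ``position`` is (x, y, z) in cm with the tissue in
    the z = 0 plane.  Bipolar probes subtract the ``partner`` sample."""

    position: tuple
    kind: str = "unipolar"
    partner: tuple | None = None
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("unipolar", "bipolar"):
            raise ValueError("kind must be unipolar or bipolar")
        if self.kind == "bipolar" and self.partner is None:
            raise ValueError("bipolar probe needs a partner position")


def default_probes(nx: int, ny: int, dx: float,
                   edge_offset: float = 0.5, height: float = 1.0,
                   bipolar_sep: float = 0.1) -> list[Probe]:
    """The four study placements for an (ny, nx) sheet with spacing dx."""
    lx, ly = nx * dx, ny * dx
    cx, cy = lx / 2.0, ly / 2.0
    return [
        Probe((lx + edge_offset, cy, 0.0), name="ECG1_right_edge"),
        Probe((cx, -edge_offset, 0.0), name="ECG2_top_edge"),
        Probe((cx, cy, height), name="ECG3_above"),
        Probe((cx, cy, height), kind="bipolar",
              partner=(cx + bipolar_sep, cy, height), name="ECG4_bipolar_above"),
    ]


def _lead_kernels(shape, dx: float, position) -> tuple[np.ndarray, np.ndarray]:
    """x- and y-components of grad_site(1/|r_site - r'|) on the lattice."""
    ny, nx = shape
    px, py, pz = position
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dx
    X, Y = np.meshgrid(x, y)
    rx, ry, rz = X - px, Y - py, -pz
    d = np.sqrt(rx ** 2 + ry ** 2 + rz ** 2)
    if d.min() < dx:
        raise ValueError(
            f"probe at {position} is within one lattice spacing of the sheet")
    d3 = d ** 3
    return -rx / d3, -ry / d3


def ecg_sample(v: np.ndarray, probe: Probe, dx: float,
               _cache: dict | None = None) -> float:
    """Extracellular-potential sample for one voltage frame.

    phi = -K * sum grad(V) . grad(1/dist) dA with K = 1 (arbitrary units);
    bipolar probes return the difference of the two unipolar samples.
    """
    v = np.asarray(v, dtype=np.float64)

    def unipolar(position) -> float:
        key = (v.shape, dx, tuple(position))
        if _cache is not None and key in _cache:
            kx, ky = _cache[key]
        else:
            kx, ky = _lead_kernels(v.shape, dx, position)
            if _cache is not None:
                _cache[key] = (kx, ky)
        gy, gx = np.gradient(v, dx)
        return float(-(gx * kx + gy * ky).sum() * dx * dx)

    phi = unipolar(probe.position)
    if probe.kind == "bipolar":
        phi -= unipolar(probe.partner)
    return phi


@dataclass
class ECGTrace:
    """(t, phi) series for one probe, arbitrary units."""

    probe: Probe
    t: np.ndarray
    phi: np.ndarray
    irregularity: float | None = None   # sample entropy of the trace


def sample_entropy(x, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy SampEn(m, r) with r = r_frac * std(x).

    Higher values mean a less regular, less self-similar signal.  Returns
    inf when no template pairs match at length m + 1.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < m + 2:
        raise ValueError("trace too short for sample entropy")
    r = r_frac * x.std()
    if r == 0:
        return 0.0

    def count(mm: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        c = 0
        for i in range(emb.shape[0] - 1):
            d = np.max(np.abs(emb[i + 1:] - emb[i]), axis=1)
            c += int(np.sum(d <= r))
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("inf")
    return float(-np.log(a / b))


def ecg_trace(series, probes, entropy_m: int = 2) -> list[ECGTrace]:
    """Per-probe pseudo-ECG traces from a snapshot series.

    ``series`` is any object with ``times`` (ms) and ``frames`` (V arrays)
    plus a ``meta`` dict carrying ``dx``.  Raises on an empty series.  The
    sample-entropy irregularity score is attached when the trace is long
    enough (single-frame series yield a degenerate single-sample trace).
    """
    if len(series.times) == 0:
        raise ValueError("empty snapshot series")
    dx = float(series.meta.get("dx", 0.0125))
    cache: dict = {}
    out = []
    t = np.asarray(series.times)
    for probe in probes:
        phi = np.array([ecg_sample(f, probe, dx, _cache=cache)
                        for f in series.frames])
        tr = ECGTrace(probe, t, phi)
        if phi.size >= entropy_m + 2:
            tr.irregularity = sample_entropy(phi, m=entropy_m)
        out.append(tr)
    return out
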