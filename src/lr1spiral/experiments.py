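"""Orchestration of whole experiments: spiral-wave runs, parameter sweeps
for phase diagrams, threshold searches, restitution and morphology scans.

Every experiment is a deterministic function of its parameters; sweep
points are independent and their results order-invariant.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import analysis
from .analysis import DynamicsClass, TipTrack
from .ionic import CellState
from .params import ModelParams
from .protocols import (CrossFieldProtocol, PacingProtocol, apply_cross_field,
                        prepace_cell, single_ap_from_rest)
from .tissue import SnapshotSeries, TissueField, step_tissue, uniform_field

DEFAULT_SWEEP_GRID = 384
DEFAULT_HORIZON = 4000.0      # ms of free evolution after induction
DEFAULT_PREPACE = PacingProtocol(pcl=2000.0, n_beats=20)


@dataclass
class WaveReport:
    """Everything measured from one tissue run."""

    label: str
    evidence: dict
    events: list
    tip_times: list
    tip_counts: list
    mean_apd: float | None = None
    params: dict | None = None
    grid: tuple | None = None

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), default=float, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s


def spiral_run(params: ModelParams, n: int = DEFAULT_SWEEP_GRID,
               horizon: float = DEFAULT_HORIZON,
               prepace: PacingProtocol = DEFAULT_PREPACE,
               induction: CrossFieldProtocol | None = None,
               dt: float = 0.01, dx: float = 0.0125, D: float = 0.001,
               tip_stride: float = 10.0,
               snapshot_stride: float | None = None,
               apd_site: tuple | None = None,
               init: CellState | None = None):
    """Induce a spiral by cross-field stimulation and classify its dynamics.

    Returns ``(report, series)`` where ``series`` is a SnapshotSeries (empty
    unless ``snapshot_stride`` is set).  The tissue is initialized uniformly
    from the pre-paced single-cell state, a plane wave is launched from the
    left edge, the bottom half is clamped when the center cell repolarizes
    through -55 mV, and the free evolution is tracked for ``horizon`` ms
    with phase-singularity detection every ``tip_stride`` ms.
    """
    induction = induction or CrossFieldProtocol()
    if init is None:
        init = prepace_cell(params, prepace, dt=dt)
    field = uniform_field(params, n, n, init=init, dx=dx, D=D)
    events = apply_cross_field(field, induction, dt=dt)
    t0 = field.t

    series = SnapshotSeries(meta={"dx": dx, "config": params.config_hash()})
    track = TipTrack()
    lag = analysis.PHASE_LAG
    apd_rec = []
    ci, cj = (apd_site or (n // 2, n // 4))

    t_rel = 0.0
    while t_rel < horizon - 1e-9:
        seg = min(tip_stride, horizon - t_rel)
        # stop a phase-lag short of the frame time, remember V(t - lag)
        r1 = step_tissue(field, dt, duration=seg - lag, record_sites=[(ci, cj)])
        v_lagged = field.V.copy()
        r2 = step_tissue(field, dt, duration=lag, record_sites=[(ci, cj)])
        if r1 is not None:
            apd_rec.append(r1[:, 0])
        apd_rec.append(r2[:, 0])
        t_rel += seg
        track.append(t_rel, analysis.detect_phase_singularities(field.V, v_lagged))
        if snapshot_stride is not None and (
                len(series) == 0 or field.t - series.times[-1] >= snapshot_stride - 1e-9):
            series.append(field.t, field.V)

    cls = analysis.classify_dynamics(track, horizon=horizon, dx=dx)

    # mean APD at the monitor site over the whole tracked window (the
    # per-call recordings are contiguous, one sample per dt step)
    vtrace = np.concatenate(apd_rec)
    ttrace = np.arange(vtrace.size) * dt
    eps = analysis.extract_apds(ttrace, vtrace)
    mean_apd = float(np.mean([e.apd for e in eps])) if eps else None

    report = WaveReport(
        label=cls.label, evidence=cls.evidence, events=events,
        tip_times=list(track.times), tip_counts=[int(c) for c in track.counts],
        mean_apd=mean_apd, params=params.to_dict(), grid=(n, n),
    )
    return report, series, track


@dataclass(frozen=True)
class SweepSpec:
    """Cartesian parameter sweep for a phase diagram.

    ``axes`` maps ModelParams field names to value lists; the special name
    ``tau_scale`` sets kd and kf together.
    """

    axes: dict
    fixed: dict = field(default_factory=dict)
    n: int = DEFAULT_SWEEP_GRID
    horizon: float = DEFAULT_HORIZON
    prepace: PacingProtocol = DEFAULT_PREPACE
    dt: float = 0.01

    def __post_init__(self):
        valid = set(ModelParams().to_dict()) | {"tau_scale"}
        for k, vals in self.axes.items():
            if k not in valid:
                raise KeyError(f"unknown sweep axis {k!r}")
            if not len(vals):
                raise ValueError(f"empty value list for axis {k!r}")
        for k in self.fixed:
            if k not in valid:
                raise KeyError(f"unknown fixed parameter {k!r}")

    def points(self):
        names = list(self.axes)
        for combo in itertools.product(*(self.axes[k] for k in names)):
            yield dict(zip(names, combo))


def _make_params(point: dict, fixed: dict) -> ModelParams:
    d = dict(fixed)
    d.update(point)
    if "tau_scale" in d:
        s = d.pop("tau_scale")
        d["kd"] = d["kf"] = s
    return ModelParams().replace(**d)


@dataclass
class PhaseDiagramResult:
    """Per-point dynamics labels with full provenance."""

    spec: dict
    entries: list = field(default_factory=list)   # {point, label, evidence}

    def labels(self) -> list:
        return [e["label"] for e in self.entries]

    def to_json(self, path=None) -> str:
        s = json.dumps({"spec": self.spec, "entries": self.entries},
                       default=float, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s


def run_sweep(spec: SweepSpec, runner=None,
              progress_path=None) -> PhaseDiagramResult:
    """Classify spiral dynamics at every sweep point.

    ``runner(params, spec) -> DynamicsClass`` may be injected (tests, custom
    scales); the default runs :func:`spiral_run` at the spec's grid and
    horizon.  A blow-up at one point labels it "failed" and the sweep
    continues.  With ``progress_path`` every finished point is appended to a
    JSON-lines file, so an interrupted sweep can be resumed losslessly.
    """
    if runner is None:
        def runner(params, sp):
            rep, _, _ = spiral_run(params, n=sp.n, horizon=sp.horizon,
                                   prepace=sp.prepace, dt=sp.dt)
            return DynamicsClass(rep.label, rep.evidence)

    done: dict = {}
    if progress_path is not None and Path(progress_path).exists():
        for line in Path(progress_path).read_text().splitlines():
            e = json.loads(line)
            done[json.dumps(e["point"], sort_keys=True)] = e

    spec_d = {"axes": {k: list(v) for k, v in spec.axes.items()},
              "fixed": dict(spec.fixed), "n": spec.n, "horizon": spec.horizon}
    result = PhaseDiagramResult(spec=spec_d)
    for point in spec.points():
        key = json.dumps(point, sort_keys=True)
        if key in done:
            result.entries.append(done[key])
            continue
        params = _make_params(point, spec.fixed)
        try:
            cls = runner(params, spec)
            entry = {"point": point, "label": cls.label, "evidence": cls.evidence}
        except FloatingPointError as e:
            entry = {"point": point, "label": "failed", "evidence": {"error": str(e)}}
        result.entries.append(entry)
        if progress_path is not None:
            with open(progress_path, "a") as f:
                f.write(json.dumps(entry, default=float) + "\n")
    return result


@dataclass(frozen=True)
class ThresholdResult:
    critical: float
    bracket: tuple     # (last value where predicate True, first where False)
    evaluations: int


def find_threshold(predicate, bracket, resolution: float,
                   max_iter: int = 60) -> ThresholdResult:
    """Bisection for the switch point of a monotone boolean predicate.

    ``predicate(x)`` must differ between the bracket ends; the reported
    critical value is the bracket midpoint at the requested resolution, and
    the final bracketing pair is returned alongside.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    p_lo, p_hi = predicate(lo), predicate(hi)
    if p_lo == p_hi:
        raise ValueError(
            f"predicate is constant ({p_lo}) across the bracket {bracket}")
    n_eval = 2
    while hi - lo > resolution and n_eval < max_iter:
        mid = 0.5 * (lo + hi)
        if predicate(mid) == p_lo:
            lo = mid
        else:
            hi = mid
        n_eval += 1
    return ThresholdResult(0.5 * (lo + hi), (lo, hi), n_eval)


# ---------------------------------------------------------------------------
# single-cell morphology predicates and scans
# ---------------------------------------------------------------------------

def morphology_at(params: ModelParams, reference_apd: float | None = None,
                  dt: float = 0.01) -> analysis.APMetrics:
    """Morphology of the representative AP (one beat from rest, PCL-500
    window) at the given parameters."""
    t, v = single_ap_from_rest(params, duration=500.0, dt=dt)
    return analysis.classify_morphology(t, v, reference_apd=reference_apd)


def dome_present(params: ModelParams, dt: float = 0.01,
                 reference_apd: float | None = None) -> bool:
    """Dome-loss predicate: True while the AP keeps its second plateau.

    An AP without any phase-1 notch is ambiguous on its own: a weak Ito
    leaves the plateau intact (long AP), while far past dome loss the cell
    repolarizes monotonically from the spike (short AP).  The Ito-free APD
    of the same parameter set disambiguates: plateau intact iff the APD
    exceeds half that reference.
    """
    m = morphology_at(params, dt=dt)
    if m.notch_v is None:
        if reference_apd is None:
            reference_apd = morphology_at(params.replace(Gtof=0.0), dt=dt).apd
        return m.apd > 0.5 * reference_apd
    return m.dome_present


def critical_gtof(params: ModelParams | None = None,
                  bracket=(0.20, 0.35), resolution: float = 0.002,
                  dt: float = 0.01) -> ThresholdResult:
    """Critical transient-outward conductance at which the AP dome is lost
    (all-or-none early repolarization), by bisection over Gtof."""
    base = params or ModelParams()
    ref_apd = morphology_at(base.replace(Gtof=0.0), dt=dt).apd
    return find_threshold(
        lambda g: dome_present(base.replace(Gtof=g), dt=dt,
                               reference_apd=ref_apd),
        bracket, resolution)
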