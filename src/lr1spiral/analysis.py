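"""Measurements on voltage traces and 2D voltage fields.

Covers APD extraction (threshold -75 mV), restitution-curve slope, APD
alternans, spike-and-dome morphology classification, phase-singularity
(spiral-tip) detection by time-delay embedding, and the
stable / quasi-periodic / breakup classifier for full runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

APD_THRESHOLD = -75.0   # mV; APD = time spent above this voltage

#: phase-embedding constants for tip detection
PHASE_V_STAR = -30.0    # mV
PHASE_LAG = 2.0         # ms

#: classifier constants (the stable/breakup calls in the source study were
#: visual; these make the rule explicit and reproducible)
BREAKUP_MIN_TIPS = 4
BREAKUP_SUSTAIN = 500.0     # ms
TRANSIENT_CUT = 500.0       # ms discarded after induction
MEANDER_BOUND = 0.5         # cm RMS core wander separating stable from quasi-periodic


@dataclass
class APMetrics:
    """Morphology of one suprathreshold episode.

    ``apd`` is the time V stays above the -75 mV threshold; ``notch_v`` is
    the first local minimum after the upstroke peak (phase-1 notch) when one
    exists inside the first half of the AP; ``dome_present`` flags a later
    local maximum at least 5 mV above the notch; ``early_repolarization``
    flags a dome-less AP much shorter than its reference.
    """

    apd: float
    t_start: float
    t_end: float
    peak_v: float
    clipped: bool = False
    notch_v: float | None = None
    notch_t: float | None = None
    dome_present: bool = False
    dome_v: float | None = None
    early_repolarization: bool = False


def extract_apds(t, v, threshold: float = APD_THRESHOLD,
                 include_clipped: bool = False) -> list[APMetrics]:
    """Segment a uniformly sampled (t, V) trace into APs.

    Crossing times are linearly interpolated.  Episodes cut off by either
    trace end are flagged ``clipped`` and excluded unless
    ``include_clipped`` is True.  Raises ``ValueError`` on an empty trace.
    """
    t = np.asarray(t, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if t.size == 0 or v.size != t.size:
        raise ValueError("empty trace or mismatched t/V lengths")
    above = v > threshold
    episodes: list[APMetrics] = []
    i = 0
    n = t.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        clipped = (i == 0) or (j == n)
        if i > 0:
            f = (threshold - v[i - 1]) / (v[i] - v[i - 1])
            t_start = t[i - 1] + f * (t[i] - t[i - 1])
        else:
            t_start = t[0]
        if j < n:
            f = (threshold - v[j - 1]) / (v[j] - v[j - 1])
            t_end = t[j - 1] + f * (t[j] - t[j - 1])
        else:
            t_end = t[-1]
        m = APMetrics(apd=t_end - t_start, t_start=t_start, t_end=t_end,
                      peak_v=float(v[i:j].max()), clipped=clipped)
        if not clipped:
            _fill_morphology(t[i:j], v[i:j], m)
        if include_clipped or not clipped:
            episodes.append(m)
        i = j
    return episodes


def _fill_morphology(t, v, m: APMetrics,
                     reference_apd: float | None = None,
                     dome_prominence: float = 5.0) -> None:
    ipk = int(np.argmax(v))
    # first local min after the upstroke peak, inside the first half of the AP
    half_t = m.t_start + 0.5 * m.apd
    notch_i = None
    for k in range(ipk + 1, v.size - 1):
        if t[k] > half_t:
            break
        if v[k] <= v[k - 1] and v[k] < v[k + 1]:
            notch_i = k
            break
    if notch_i is not None:
        m.notch_v = float(v[notch_i])
        m.notch_t = float(t[notch_i])
        seg = v[notch_i:]
        if float(seg.max()) >= m.notch_v + dome_prominence:
            m.dome_present = True
            m.dome_v = float(seg.max())
    if reference_apd is not None:
        m.early_repolarization = (not m.dome_present) and (m.apd < 0.5 * reference_apd)


def classify_morphology(t, v, reference_apd: float | None = None) -> APMetrics:
    """Morphology of a trace holding exactly one AP.

    ``reference_apd`` (typically the Gtof = 0 APD under the same protocol)
    enables the early-repolarization call: dome absent and APD below half
    the reference.  Raises ``ValueError`` when no AP is present.
    """
    eps = extract_apds(t, v, include_clipped=True)
    if not eps:
        raise ValueError("no suprathreshold episode in trace")
    m = eps[0]
    if m.peak_v < -40.0:
        raise ValueError(f"no upstroke: peak {m.peak_v:.1f} mV < -40 mV")
    i0 = np.searchsorted(t, m.t_start)
    i1 = np.searchsorted(t, m.t_end)
    _fill_morphology(np.asarray(t)[i0:i1], np.asarray(v)[i0:i1], m,
                     reference_apd=reference_apd)
    return m


@dataclass(frozen=True)
class AlternansReport:
    magnitude: float       # ms, mean |APD(n+1) - APD(n)| over the last beats
    alternating: bool      # sustained > 5 ms with strict sign alternation


def alternans_magnitude(apds, last_k: int = 8,
                        threshold: float = 5.0) -> AlternansReport:
    """Beat-to-beat APD alternation over the last ``last_k`` beats.

    Requires at least 4 APDs from steady pacing.
    """
    a = np.asarray(list(apds), dtype=np.float64)
    if a.size < 4:
        raise ValueError("need at least 4 APDs")
    d = np.diff(a[-min(last_k, a.size):])
    mag = float(np.mean(np.abs(d)))
    signs = np.sign(d)
    alternating = (
        mag > threshold
        and np.all(np.abs(d) > threshold / 2)
        and np.all(signs[1:] * signs[:-1] < 0)
    )
    return AlternansReport(mag, bool(alternating))


def restitution_slope(points):
    """Finite-difference slope d(APD)/d(DI) on captured, DI-sorted points.

    Returns (di_mid, slope) arrays; also accepts RestitutionPoint lists.
    """
    pts = [(p.di, p.apd) for p in points if getattr(p, "captured", True)]
    pts.sort()
    di = np.array([p[0] for p in pts])
    apd = np.array([p[1] for p in pts])
    if di.size < 2:
        raise ValueError("need >= 2 captured points")
    slope = np.diff(apd) / np.diff(di)
    return 0.5 * (di[1:] + di[:-1]), slope


# ---------------------------------------------------------------------------
# phase singularities
# ---------------------------------------------------------------------------

def phase_field(v_now, v_lag, v_star: float = PHASE_V_STAR) -> np.ndarray:
    """Time-delay-embedded phase: atan2(V(t - lag) - V*, V(t) - V*)."""
    v_now = np.asarray(v_now, dtype=np.float64)
    v_lag = np.asarray(v_lag, dtype=np.float64)
    if v_now.shape != v_lag.shape:
        raise ValueError("field shapes differ")
    return np.arctan2(v_lag - v_star, v_now - v_star)


def detect_phase_singularities(v_now, v_lag,
                               v_star: float = PHASE_V_STAR) -> np.ndarray:
    """Spiral tips as phase singularities of the delay-embedded phase.

    Sums the wrapped phase differences around every elementary plaquette;
    a winding of +-2*pi marks a tip.  Returns an (n, 3) array of
    (x, y, chirality) in grid units (plaquette centers).
    """
    phi = phase_field(v_now, v_lag, v_star)

    def wrap(d):
        return (d + np.pi) % (2 * np.pi) - np.pi

    # edges of each plaquette (i, j) -> (i, j+1) -> (i+1, j+1) -> (i+1, j) ->
    d1 = wrap(phi[:-1, 1:] - phi[:-1, :-1])
    d2 = wrap(phi[1:, 1:] - phi[:-1, 1:])
    d3 = wrap(phi[1:, :-1] - phi[1:, 1:])
    d4 = wrap(phi[:-1, :-1] - phi[1:, :-1])
    winding = d1 + d2 + d3 + d4
    ii, jj = np.where(np.abs(winding) > np.pi)
    if ii.size == 0:
        return np.empty((0, 3))
    return np.column_stack([jj + 0.5, ii + 0.5, np.sign(winding[ii, jj])])


@dataclass
class TipTrack:
    """Per-frame phase-singularity positions with chirality."""

    times: list = field(default_factory=list)      # ms
    tips: list = field(default_factory=list)       # (n_i, 3) arrays

    def append(self, t: float, tips: np.ndarray) -> None:
        self.times.append(float(t))
        self.tips.append(np.asarray(tips, dtype=np.float64))

    @property
    def counts(self) -> np.ndarray:
        return np.array([tp.shape[0] for tp in self.tips])

    def total_chirality(self) -> np.ndarray:
        return np.array([tp[:, 2].sum() if tp.size else 0.0 for tp in self.tips])


@dataclass
class DynamicsClass:
    """Classification of one tissue run: no_wave / stable / quasiperiodic /
    breakup, with the evidence that produced the label."""

    label: str
    evidence: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=float)


def classify_dynamics(track: TipTrack, horizon: float,
                      transient: float = TRANSIENT_CUT,
                      breakup_min_tips: int = BREAKUP_MIN_TIPS,
                      breakup_sustain: float = BREAKUP_SUSTAIN,
                      meander_bound_cells: float | None = None,
                      dx: float = 0.0125) -> DynamicsClass:
    """Label a run from its tip track (a pure function of track + constants).

    Rule, in order: no wave if no tips remain at the end; breakup if the tip
    count stays >= ``breakup_min_tips`` over any contiguous
    ``breakup_sustain`` ms window (after the transient); stable if the count
    stays at one and the core wanders less than the meander bound;
    quasi-periodic otherwise.
    """
    times = np.asarray(track.times)
    if times.size == 0 or times[-1] < horizon:
        raise ValueError("track shorter than the requested horizon")
    sel = (times >= transient) & (times <= horizon)
    if not np.any(sel):
        raise ValueError("no frames between transient cut and horizon")
    t = times[sel]
    counts = track.counts[sel]
    tips = [tp for tp, s in zip(track.tips, sel) if s]

    evidence: dict = {
        "final_count": int(counts[-1]),
        "max_count": int(counts.max()),
        "mean_count": float(counts.mean()),
    }
    if counts[-1] == 0:
        return DynamicsClass("no_wave", evidence)

    # longest contiguous window with count >= breakup_min_tips
    best = 0.0
    run_start = None
    for k in range(counts.size):
        if counts[k] >= breakup_min_tips:
            if run_start is None:
                run_start = t[k]
            best = max(best, t[k] - run_start)
        else:
            run_start = None
    evidence["longest_multitip_window_ms"] = float(best)
    if best >= breakup_sustain:
        return DynamicsClass("breakup", evidence)

    if meander_bound_cells is None:
        meander_bound_cells = MEANDER_BOUND / dx
    single = counts == 1
    evidence["fraction_single_tip"] = float(np.mean(single))
    if np.all(single):
        xy = np.array([tp[0, :2] for tp in tips])
        wander = float(np.sqrt(np.mean(np.sum((xy - xy.mean(0)) ** 2, axis=1))))
        evidence["core_rms_wander_cells"] = wander
        if wander < meander_bound_cells:
            return DynamicsClass("stable", evidence)
    return DynamicsClass("quasiperiodic", evidence)
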