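"""Model parameters and configuration I/O.

All conductances are in mS/cm^2 and potentials in mV.  With the default
membrane capacitance Cm = 1 uF/cm^2, mS/cm^2 and mS/uF are numerically
identical, so values quoted in either unit system can be used directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

# Nernst slope RT/F at 37 C, mV (the rounded value conventional for this model)
RT_OVER_F = 26.73

# Fixed ionic concentrations (mM)
K_O = 5.4
K_I = 145.0
NA_O = 140.0
NA_I = 18.0

#: Nernst potential of potassium, mV: (RT/F) ln([K]o/[K]i)
EK_NERNST = RT_OVER_F * math.log(K_O / K_I)  # ~ -87.95 mV


@dataclass
class ModelParams:
    """Conductances, reversal potentials and gate-speed factors.

    ``kd`` and ``kf`` multiply the time constants of the slow-inward (Ca)
    activation/inactivation gates d and f; 1.0 is the control kinetics and
    e.g. 0.3 means the gates relax 1/0.3 times faster ("accelerated"
    kinetics).  ``Gtof`` is the maximum conductance of the fast transient
    outward current; 0 removes the current entirely.
    """

    Cm: float = 1.0          # uF/cm^2
    GNa: float = 16.0        # mS/cm^2 (reduced from the 23 of the source model)
    Gsi: float = 0.09        # mS/cm^2, slow-inward (L-type Ca-like)
    GK: float = 0.282        # mS/cm^2, time-dependent K
    GK1: float = 0.6047      # mS/cm^2, inward rectifier
    GKp: float = 0.0183      # mS/cm^2, plateau K
    Gb: float = 0.03921      # mS/cm^2, background
    Gtof: float = 0.0        # mS/cm^2, fast transient outward (0 = absent)
    kd: float = 1.0          # tau_d scale factor, dimensionless
    kf: float = 1.0          # tau_f scale factor, dimensionless
    ENa: float = 54.4        # mV
    EK: float = -77.0        # mV, time-dependent K reversal (incl. Na permeability)
    EK1: float = EK_NERNST   # mV, inward rectifier / plateau K reversal
    EK_tof: float = -77.0    # mV, transient-outward reversal (the model's EK)
    Eb: float = -59.87       # mV, background reversal
    ESi_a: float = 7.7       # mV, ESi = a - b*ln(Cai)
    ESi_b: float = 13.0287
    cai_rest: float = 1.0e-4   # mM, Cai relaxation target
    cai_uptake_rate: float = 0.07   # 1/ms
    cai_influx_coeff: float = 1.0e-4  # mM cm^2 / (uA ms)

    def __post_init__(self) -> None:
        for name in ("Cm", "GNa", "Gsi", "GK", "GK1", "GKp", "Gb", "Gtof"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.kd <= 0 or self.kf <= 0:
            raise ValueError("kd and kf must be positive")

    @property
    def accelerated(self) -> bool:
        """True when either Ca-gate time constant is scaled below control."""
        return self.kd < 1.0 or self.kf < 1.0

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable short hash of the parameter set, for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
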