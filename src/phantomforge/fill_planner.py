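"""Radiotracer fill planning with radioactive-decay correction.

Given compartment volumes and target concentration ratios relative to WM
(GM/WM 2.80 and striatum/WM 2.63 by default, the ¹⁸F-FDG-like contrast the
phantom is designed to reproduce), computes the activity concentration each
compartment must hold at scan time and the dose to inject at fill time,
decay-corrected over the injection-to-scan interval.

Units: volumes mL, doses MBq, concentrations kBq/mL, times minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import BACKGROUND, GM, STRIATUM, WM

__all__ = [
    "F18_HALF_LIFE_MIN",
    "DEFAULT_RATIOS",
    "DecayModel",
    "FillPlan",
    "compartment_volumes",
    "plan_fill",
    "decay_to_scan",
]

#: ¹⁸F physical half-life (minutes)
F18_HALF_LIFE_MIN = 109.77

#: default target concentration ratios vs WM
DEFAULT_RATIOS = {GM: 2.80, STRIATUM: 2.63}


@dataclass
class DecayModel:
    """Exponential decay over per-compartment injection-to-scan intervals.

    ``injection_to_scan_min`` may be a scalar (shared interval) or a mapping
    compartment → minutes; the physical fill procedure injects compartments
    one at a time, so intervals are independent parameters.
    """

    half_life_min: float = F18_HALF_LIFE_MIN
    injection_to_scan_min: float | dict[int, float] = 0.0

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")
        if isinstance(self.injection_to_scan_min, dict):
            intervals = list(self.injection_to_scan_min.values())
        else:
            intervals = [self.injection_to_scan_min]
        if any(dt < 0 for dt in intervals):
            raise ValueError("injection-to-scan interval must be >= 0")

    def _interval(self, compartment: int) -> float:
        if isinstance(self.injection_to_scan_min, dict):
            return float(self.injection_to_scan_min[compartment])
        return float(self.injection_to_scan_min)

    def decay_factor(self, compartment: int) -> float:
        """2^(−Δt / T½) for the compartment's interval."""
        return float(2.0 ** (-self._interval(compartment) / self.half_life_min))


@dataclass
class FillPlan:
    """Per-compartment volume, injected dose and scan-time concentration."""

    volumes_mL: dict[int, float]
    concentrations_kBq_per_mL: dict[int, float]
    doses_MBq: dict[int, float]
    ratios_vs_wm: dict[int, float]
    decay: DecayModel = field(default_factory=DecayModel)

    def concentration(self, compartment: int) -> float:
        if compartment == BACKGROUND:
            return 0.0
        return self.concentrations_kBq_per_mL[compartment]

    def as_records(self) -> list[dict]:
        return [
            {
                "compartment": c,
                "volume_mL": self.volumes_mL[c],
                "dose_MBq": self.doses_MBq[c],
                "concentration_kBq_per_mL": self.concentrations_kBq_per_mL[c],
            }
            for c in sorted(self.concentrations_kBq_per_mL)
        ]


def compartment_volumes(model) -> dict[int, float]:
    """Voxel-count volume of every non-background compartment, in mL."""
    vol = model.labels
    vv_mL = vol.voxel_volume_mm3 / 1000.0
    counts = vol.counts()
    out = {
        int(lbl): n * vv_mL for lbl, n in counts.items() if lbl != BACKGROUND
    }
    if not out:
        raise ValueError("model holds no non-background compartment")
    for lbl in (GM, WM, STRIATUM):
        if lbl in counts and counts[lbl] == 0:
            raise ValueError(f"compartment {lbl} is empty")
    return out


def decay_to_scan(dose_MBq: float, volume_mL: float, decay: DecayModel, compartment: int = GM) -> float:
    """Concentration at scan time (kBq/mL) from the injected dose.

    concentration = (dose / volume) × 2^(−Δt/T½), MBq/mL → kBq/mL.
    """
    if dose_MBq <= 0 or volume_mL <= 0:
        raise ValueError("dose and volume must be positive")
    return 1000.0 * dose_MBq / volume_mL * decay.decay_factor(compartment)


def plan_fill(
    volumes_mL: dict[int, float],
    wm_concentration_at_scan: float,
    ratios: dict[int, float] | None = None,
    decay: DecayModel | None = None,
) -> FillPlan:
    """Doses realizing the target scan-time concentration ratios exactly.

    WM is the reference compartment; every other compartment's scan-time
    concentration is ratio × WM.  Injected dose inverts the decay:
    dose = concentration × volume × 2^(+Δt/T½).
    """
    ratios = dict(DEFAULT_RATIOS) if ratios is None else dict(ratios)
    decay = DecayModel() if decay is None else decay
    if wm_concentration_at_scan <= 0:
        raise ValueError("WM concentration must be positive")
    if WM not in volumes_mL:
        raise ValueError("volumes must include the WM reference compartment")
    for c, v in volumes_mL.items():
        if v <= 0:
            raise ValueError(f"volume of compartment {c} must be positive")
    for c, r in ratios.items():
        if r <= 0:
            raise ValueError(f"ratio for compartment {c} must be positive")

    conc = {WM: float(wm_concentration_at_scan)}
    for c in volumes_mL:
        if c == WM:
            continue
        if c not in ratios:
            raise ValueError(f"no target ratio given for compartment {c}")
        conc[c] = ratios[c] * wm_concentration_at_scan
    doses = {
        c: conc[c] * volumes_mL[c] / 1000.0 / decay.decay_factor(c)  # kBq·mL⁻¹·mL → MBq
        for c in conc
    }
    return FillPlan(
        volumes_mL={int(c): float(v) for c, v in volumes_mL.items()},
        concentrations_kBq_per_mL=conc,
        doses_MBq=doses,
        ratios_vs_wm={**ratios, WM: 1.0},
        decay=decay,
    )
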