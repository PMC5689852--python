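"""Multichannel vaginal cylinder (MCVC) geometry, loadings and dwell-time
optimization.

The applicator is a 35 mm diameter cylinder with one central channel and
eight peripheral channels; two 5 mm deep fixation grooves run along the
outside starting 60 mm from the tip, at azimuths 0° and 180°.  The tip is
at z = 0 with +z toward the base.  A prescription of 500 cGy is specified
to a grid of surface points (z every 5 mm from 60 to 130 mm, azimuth every
22.5°, 240 points), and dwell times are assigned by geometric optimization
followed by a single global normalization of the mean surface dose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tg43 import DwellPosition, SourceModel, dose_from_plan

Z_AXIS = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class ApplicatorModel:
    """MCVC dimensions, mm.  Library values unless noted as measured."""

    outer_radius: float = 17.5
    measured_outer_radius: float = 17.535      # µCT: (35.07 ± 0.04) mm diameter
    central_channel_radius: float = 1.25       # library 2.5 mm diameter
    measured_central_channel_radius: float = 1.345  # µCT: (2.69 ± 0.04) mm
    peripheral_channel_count: int = 8
    peripheral_channel_offset_radius: float | None = 13.0  # not published; config
    peripheral_channel_phase_deg: float = 22.5  # channels between the grooves
    groove_depth: float = 5.0
    groove_start_z: float = 60.0
    groove_azimuths_deg: tuple = (0.0, 180.0)

    def __post_init__(self):
        if self.peripheral_channel_offset_radius is not None:
            if not (0 < self.central_channel_radius
                    < self.peripheral_channel_offset_radius < self.outer_radius):
                raise ValueError("channel radii must nest inside the applicator")
        if self.groove_depth >= self.outer_radius:
            raise ValueError("groove depth exceeds applicator radius")


@dataclass
class Plan:
    """Dwell loading plus the surface prescription it is normalized to."""

    dwells: list
    prescription_points: np.ndarray      # (N, 3) mm, on the cylinder surface
    prescription_dose: float = 500.0     # cGy
    loading_mode: str = "central"
    normalization: dict = field(default_factory=dict)

    @property
    def dwell_times(self) -> np.ndarray:
        return np.array([d.dwell_time for d in self.dwells])

    @property
    def dwell_centers(self) -> np.ndarray:
        return np.array([d.center for d in self.dwells])

    def validate(self, applicator: ApplicatorModel) -> None:
        rho = np.hypot(self.prescription_points[:, 0], self.prescription_points[:, 1])
        if np.max(np.abs(rho - applicator.outer_radius)) > 1e-9:
            raise ValueError("prescription points must lie on the cylinder surface")
        drho = np.hypot(self.dwell_centers[:, 0], self.dwell_centers[:, 1])
        if np.any(drho >= applicator.outer_radius):
            raise ValueError("dwell centers must lie inside the applicator")

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "loading_mode": self.loading_mode,
            "prescription_dose_cGy": self.prescription_dose,
            "normalization": self.normalization,
            "dwells": [{"x_mm": d.center[0], "y_mm": d.center[1],
                        "z_mm": d.center[2], "time_s": d.dwell_time,
                        "channel": d.channel_id} for d in self.dwells],
            "prescription_points_mm": self.prescription_points.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Plan":
        with open(path) as fh:
            obj = json.load(fh)
        dwells = [DwellPosition(np.array([d["x_mm"], d["y_mm"], d["z_mm"]]),
                                d["time_s"], channel_id=d["channel"])
                  for d in obj["dwells"]]
        return cls(dwells, np.asarray(obj["prescription_points_mm"], float),
                   obj["prescription_dose_cGy"], obj["loading_mode"],
                   obj.get("normalization", {}))

    def dwell_table(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": [d.channel_id for d in self.dwells],
                             "x_mm": self.dwell_centers[:, 0],
                             "y_mm": self.dwell_centers[:, 1],
                             "z_mm": self.dwell_centers[:, 2],
                             "time_s": self.dwell_times})


# ---------------------------------------------------------------------------
# point/dwell builders

def build_prescription_points(applicator: ApplicatorModel) -> np.ndarray:
    """Surface prescription grid: z 60..130 by 5 mm × azimuth 0..337.5 by 22.5°.

    Ordering is z-major, azimuth ascending; 15 × 16 = 240 points.
    """
    z = np.arange(60.0, 130.0 + 1e-9, 5.0)
    az = np.deg2rad(np.arange(0.0, 360.0, 22.5))
    R = applicator.outer_radius
    pts = [(R * np.cos(a), R * np.sin(a), zi) for zi in z for a in az]
    return np.array(pts)


def prescription_azimuths_deg() -> np.ndarray:
    return np.arange(0.0, 360.0, 22.5)


def build_central_loading(applicator: ApplicatorModel) -> list:
    """20 on-axis dwells at z = 50, 55, ..., 145 mm, unit placeholder times."""
    return [DwellPosition(np.array([0.0, 0.0, z]), 1.0, Z_AXIS, "central")
            for z in np.arange(50.0, 145.0 + 1e-9, 5.0)]


def build_peripheral_loading(applicator: ApplicatorModel) -> list:
    """8 × 17 dwells at z = 54..134 mm on the peripheral channel circle."""
    rho = applicator.peripheral_channel_offset_radius
    if rho is None:
        raise ValueError("peripheral_channel_offset_radius is not configured")
    dwells = []
    for k in range(applicator.peripheral_channel_count):
        a = np.deg2rad(applicator.peripheral_channel_phase_deg + k * 45.0)
        for z in np.arange(54.0, 134.0 + 1e-9, 5.0):
            dwells.append(DwellPosition(
                np.array([rho * np.cos(a), rho * np.sin(a), z]),
                1.0, Z_AXIS, f"peripheral-{k + 1}"))
    return dwells


# ---------------------------------------------------------------------------
# geometric optimization

def _relative_times(dwells, points, variant: str) -> np.ndarray:
    centers = np.array([d.center for d in dwells])
    if variant in ("distance", "volume"):
        # classical (Edmundson) geometric optimization: each dwell weighted by
        # the inverse summed inverse-square distance to the other dwells —
        # all of them ("distance") or those in other catheters ("volume")
        d = np.linalg.norm(centers[None, :, :] - centers[:, None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        inv2 = 1.0 / d**2
        if variant == "volume":
            ch = np.array([dw.channel_id for dw in dwells])
            if len(set(ch)) < 2:
                raise ValueError("volume mode needs more than one catheter")
            inv2 = np.where(ch[None, :] != ch[:, None], inv2, 0.0)
    elif variant == "points":
        d = np.linalg.norm(points[None, :, :] - centers[:, None, :], axis=-1)
        if np.any(d < 1e-9):
            raise ValueError("dwell coincides with a prescription point")
        inv2 = 1.0 / d**2
    else:
        raise ValueError(f"unknown optimization variant {variant!r}")
    w = 1.0 / inv2.sum(axis=1)
    return w / w.max()


def geometric_optimization(plan: Plan, source: SourceModel,
                           variant: str = "auto") -> Plan:
    """Assign dwell times geometrically, then normalize the prescription.

    Variants: ``"distance"`` — dwell-to-dwell over all dwells (the classical
    Edmundson rule, the TPS mode for a single catheter); ``"volume"`` —
    dwell-to-dwell restricted to other catheters (the TPS multi-catheter
    mode); ``"points"`` — inverse summed inverse-square contribution to the
    prescription points; ``"auto"`` — distance for a single catheter, volume
    otherwise.  After the relative weighting, a single global scale sets the
    mean TG-43 dose over the prescription points to
    ``plan.prescription_dose``.
    """
    if variant == "auto":
        n_cath = len({d.channel_id for d in plan.dwells})
        variant = "distance" if n_cath < 2 else "volume"
    w = _relative_times(plan.dwells, plan.prescription_points, variant)
    doses = dose_from_plan(source, plan.dwells, plan.prescription_points, times_s=w)
    scale = plan.prescription_dose / doses.mean()
    times = w * scale
    plan.dwells = [d.replace_time(t) for d, t in zip(plan.dwells, times)]
    plan.normalization = {"variant": variant, "scale_s": scale,
                          "mean_dose_cGy": plan.prescription_dose}
    return plan


def mean_prescription_dose(plan: Plan, source: SourceModel) -> float:
    """Arithmetic mean TG-43 dose over the prescription point set, cGy."""
    return float(dose_from_plan(source, plan.dwells, plan.prescription_points).mean())


def make_plan(source: SourceModel, applicator: ApplicatorModel,
              loading: str = "central", prescription_dose: float = 500.0,
              variant: str = "auto") -> Plan:
    """Build, optimize and normalize a central or peripheral plan."""
    if loading == "central":
        dwells = build_central_loading(applicator)
    elif loading == "peripheral":
        dwells = build_peripheral_loading(applicator)
    else:
        raise ValueError("loading must be 'central' or 'peripheral'")
    plan = Plan(dwells, build_prescription_points(applicator),
                prescription_dose, loading)
    plan.validate(applicator)
    return geometric_optimization(plan, source, variant)
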