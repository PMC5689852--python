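"""2D TG-43 line-source dose engine for HDR Ir-192 dwells.

Dose rate around a single dwell follows the AAPM TG-43 formalism,

    D(r, theta) = Sk * Lambda * [G_L(r, theta) / G_L(1 cm, 90 deg)] * g(r) * F(r, theta),

with ``G_L`` the line-source geometry function, ``g`` the radial dose
function and ``F`` the 2D anisotropy function, both tabulated.  Geometry is
handled internally in mm (applicator frame: tip at z = 0, axis along +z);
the TG-43 radial arguments are converted to cm at the engine boundary.
Dwell times are seconds, dose rates cGy/h; the 1/3600 conversion is applied
once in :func:`dose_from_plan`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MM_PER_CM = 10.0
SECONDS_PER_HOUR = 3600.0


class ExtrapolationError(ValueError):
    """Raised when a lookup falls outside the tables and policy is 'error'."""


@dataclass(frozen=True)
class SourceModel:
    """Ir-192 HDR source description.

    Parameters
    ----------
    air_kerma_strength : float
        Sk in U (µGy·m²·h⁻¹).
    dose_rate_constant : float
        Lambda in cGy·h⁻¹·U⁻¹.
    active_length_mm : float
        Physical active length of the source, mm.
    radial_r_cm, radial_g : arrays
        Radial dose function table, r strictly increasing, g(1 cm) = 1.
    aniso_r_cm, aniso_theta_deg, aniso_F : arrays
        2D anisotropy table on a (r, theta) grid with F(r, 90°) = 1.
    extrapolation : {"clamp", "error"}
        Policy for lookups outside the tabulated r (or theta) range.
    """

    air_kerma_strength: float
    dose_rate_constant: float
    active_length_mm: float
    radial_r_cm: np.ndarray
    radial_g: np.ndarray
    aniso_r_cm: np.ndarray
    aniso_theta_deg: np.ndarray
    aniso_F: np.ndarray
    extrapolation: str = "clamp"
    name: str = "unnamed"

    def __post_init__(self):
        r = np.asarray(self.radial_r_cm, float)
        g = np.asarray(self.radial_g, float)
        if r.ndim != 1 or np.any(np.diff(r) <= 0):
            raise ValueError("radial_dose_table r-grid must be strictly increasing")
        if abs(np.interp(1.0, r, g) - 1.0) > 1e-6:
            raise ValueError("radial dose function must satisfy g(1 cm) = 1")
        if self.active_length_mm <= 0:
            raise ValueError("active_length must be positive")
        F = np.asarray(self.aniso_F, float)
        th = np.asarray(self.aniso_theta_deg, float)
        if np.any(g <= 0) or np.any(F <= 0):
            raise ValueError("all table values must be positive")
        i90 = np.nonzero(np.isclose(th, 90.0))[0]
        if i90.size != 1 or np.max(np.abs(F[i90[0], :] - 1.0)) > 1e-6:
            raise ValueError("anisotropy table must contain theta = 90° with F = 1")
        object.__setattr__(self, "radial_r_cm", r)
        object.__setattr__(self, "radial_g", g)
        object.__setattr__(self, "aniso_r_cm", np.asarray(self.aniso_r_cm, float))
        object.__setattr__(self, "aniso_theta_deg", th)
        object.__setattr__(self, "aniso_F", F)

    # -- table lookups -----------------------------------------------------

    def _check_range(self, r_cm: np.ndarray, lo: float, hi: float, table: str) -> None:
        out = (r_cm < lo) | (r_cm > hi)
        if np.any(out):
            msg = (f"{int(out.sum())} lookup(s) outside {table} table range "
                   f"[{lo:g}, {hi:g}] cm")
            if self.extrapolation == "error":
                raise ExtrapolationError(msg)
            logger.warning("%s; clamping to nearest table value", msg)

    def radial_dose(self, r_cm) -> np.ndarray:
        """g(r), log-linear interpolation in r, clamped outside the grid."""
        r_cm = np.asarray(r_cm, float)
        self._check_range(r_cm, self.radial_r_cm[0], self.radial_r_cm[-1], "radial dose")
        lng = np.interp(r_cm, self.radial_r_cm, np.log(self.radial_g))
        return np.exp(lng)

    def anisotropy(self, r_cm, theta_deg) -> np.ndarray:
        """F(r, theta), bilinear on the (r, theta) grid, clamped outside."""
        r_cm = np.asarray(r_cm, float)
        theta_deg = np.asarray(theta_deg, float)
        self._check_range(r_cm, self.aniso_r_cm[0], self.aniso_r_cm[-1], "anisotropy")
        rc = np.clip(r_cm, self.aniso_r_cm[0], self.aniso_r_cm[-1])
        tc = np.clip(theta_deg, self.aniso_theta_deg[0], self.aniso_theta_deg[-1])
        i = np.clip(np.searchsorted(self.aniso_theta_deg, tc) - 1, 0,
                    len(self.aniso_theta_deg) - 2)
        j = np.clip(np.searchsorted(self.aniso_r_cm, rc) - 1, 0,
                    len(self.aniso_r_cm) - 2)
        t0, t1 = self.aniso_theta_deg[i], self.aniso_theta_deg[i + 1]
        r0, r1 = self.aniso_r_cm[j], self.aniso_r_cm[j + 1]
        ft = (tc - t0) / (t1 - t0)
        fr = (rc - r0) / (r1 - r0)
        F = self.aniso_F
        return ((1 - ft) * (1 - fr) * F[i, j] + ft * (1 - fr) * F[i + 1, j]
                + (1 - ft) * fr * F[i, j + 1] + ft * fr * F[i + 1, j + 1])


@dataclass(frozen=True)
class DwellPosition:
    """One stopping point of the stepping source, in the applicator frame (mm)."""

    center: np.ndarray
    dwell_time: float = 1.0
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    channel_id: str = "central"

    def __post_init__(self):
        c = np.asarray(self.center, float)
        a = np.asarray(self.axis_direction, float)
        if self.dwell_time < 0:
            raise ValueError("dwell_time must be >= 0")
        if abs(np.linalg.norm(a) - 1.0) > 1e-9:
            raise ValueError("axis_direction must be a unit vector")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "axis_direction", a)

    def replace_time(self, t: float) -> "DwellPosition":
        return DwellPosition(self.center, t, self.axis_direction, self.channel_id)


@dataclass(frozen=True)
class DosePoint:
    position: np.ndarray
    dose: float
    type_B_rel_uncertainty: float = 0.034

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


# ---------------------------------------------------------------------------
# geometry function

def geometry_factor_line(r_cm, theta_deg, L_cm):
    """Line-source geometry function G_L(r, theta) in cm^-2.

    beta/(L r sin(theta)) off axis, 1/(r^2 - L^2/4) on axis, where beta is
    the angle subtended by the active length at the point.  The point must
    not lie on the source segment.
    """
    r = np.asarray(r_cm, float)
    th = np.deg2rad(np.asarray(theta_deg, float))
    L = float(L_cm)
    if L <= 0:
        raise ValueError("active length must be positive")
    if np.any(r <= 0):
        raise ValueError("r must be positive")

    x = r * np.sin(th)           # perpendicular distance to the source axis
    y = r * np.cos(th)           # coordinate along the axis
    on_axis = np.isclose(x, 0.0)
    if np.any(on_axis & (r - L / 2.0 <= 1e-12)):
        raise ValueError("point lies on or inside the source segment")

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.arctan2(x, y - L / 2.0) - np.arctan2(x, y + L / 2.0)
        g_off = beta / (L * x)
        g_on = 1.0 / (r * r - L * L / 4.0)
    out = np.where(on_axis, g_on, g_off)
    return out.item() if out.ndim == 0 else out


def _r_theta(points_mm: np.ndarray, dwell: DwellPosition):
    """Radial distance (cm) and polar angle (deg) in the dwell's local frame."""
    v = np.atleast_2d(points_mm) - dwell.center
    r_mm = np.linalg.norm(v, axis=-1)
    if np.any(r_mm < dwell_capsule_radius_mm()):
        raise ValueError("dose point inside the source capsule")
    cos_t = np.clip(v @ dwell.axis_direction / r_mm, -1.0, 1.0)
    return r_mm / MM_PER_CM, np.rad2deg(np.arccos(cos_t))


def dwell_capsule_radius_mm() -> float:
    """Exclusion radius around a dwell; the v2 source capsule is ~0.9 mm wide."""
    return 0.45


def dose_rate_single(source: SourceModel, dwell: DwellPosition, points_mm) -> np.ndarray:
    """TG-43 dose rate (cGy/h) at one or more points from a single dwell."""
    pts = np.asarray(points_mm, float)
    scalar = pts.ndim == 1
    r_cm, theta = _r_theta(pts, dwell)
    L = source.active_length_mm / MM_PER_CM
    G = geometry_factor_line(r_cm, theta, L)
    G0 = geometry_factor_line(1.0, 90.0, L)
    rate = (source.air_kerma_strength * source.dose_rate_constant * (G / G0)
            * source.radial_dose(r_cm) * source.anisotropy(r_cm, theta))
    return rate[0] if scalar else rate


def dose_from_plan(source: SourceModel, dwells, points_mm, times_s=None) -> np.ndarray:
    """Total dose (cGy) at each point: sum of dwell rates times dwell times.

    ``times_s`` overrides the dwell objects' own times when given.
    """
    pts = np.atleast_2d(np.asarray(points_mm, float))
    total = np.zeros(len(pts))
    for i, dw in enumerate(dwells):
        t = dw.dwell_time if times_s is None else times_s[i]
        if not np.isfinite(t) or t < 0:
            raise ValueError("dwell times must be finite and >= 0")
        if t == 0.0:
            continue
        total += dose_rate_single(source, dw, pts) * (t / SECONDS_PER_HOUR)
    return total


def dose_points_from_plan(source, dwells, points_mm,
                          type_B_rel: float = 0.034) -> list[DosePoint]:
    doses = dose_from_plan(source, dwells, points_mm)
    return [DosePoint(np.asarray(p, float), d, type_B_rel)
            for p, d in zip(np.atleast_2d(points_mm), doses)]


# ---------------------------------------------------------------------------
# table I/O

def load_source_tables(radial_csv, anisotropy_csv):
    """Read a (radial, anisotropy) table pair from CSV.

    Radial file: columns ``r_cm,g``.  Anisotropy file: first column ``r_cm``,
    header row of theta in degrees, cells F(r, theta).
    """
    rad = pd.read_csv(radial_csv)
    ani = pd.read_csv(anisotropy_csv)
    theta = np.array([float(c) for c in ani.columns[1:]])
    return (rad["r_cm"].to_numpy(float), rad["g"].to_numpy(float),
            ani["r_cm"].to_numpy(float), theta,
            ani.iloc[:, 1:].to_numpy(float).T)


def example_source_model(air_kerma_strength: float = 40800.0,
                         extrapolation: str = "clamp") -> SourceModel:
    """Synthetic Ir-192 HDR-v2-like source built from the packaged tables.

    The table set is synthetic (smooth analytic g and F frozen to CSV), not a
    consensus dataset; Sk defaults to a nominal 10 Ci source and Lambda to
    1.109 cGy/(h·U).
    """
    data = resources.files("mcvcdose.data")
    r, g, ar, at, F = load_source_tables(
        Path(str(data / "radial_dose_synthetic.csv")),
        Path(str(data / "anisotropy_synthetic.csv")))
    return SourceModel(air_kerma_strength=air_kerma_strength,
                       dose_rate_constant=1.109, active_length_mm=3.6,
                       radial_r_cm=r, radial_g=g, aniso_r_cm=ar,
                       aniso_theta_deg=at, aniso_F=F,
                       extrapolation=extrapolation, name="synthetic-ir192-v2")
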