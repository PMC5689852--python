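"""Azimuthal surface-dose profiles and their variation statistics.

A film wrapped around the cylinder unrolls to a rectangle whose columns map
to azimuth; the longitudinally averaged dose across a band of rows gives
the azimuthal surface-dose profile.  Inverse-square (IS) corrections
relocate doses measured at the film active layer to the applicator
surface.  Variation metrics summarize the profile: the max-minus-min
spread, the height of the groove peaks above the baseline, and the
baseline spread excluding the peak windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .applicator import ApplicatorModel, Plan, prescription_azimuths_deg
from .film import DoseMap, expanded_uncertainty
from .tg43 import SourceModel, dose_from_plan


@dataclass
class AzimuthalProfile:
    azimuth_deg: np.ndarray
    dose: np.ndarray                      # cGy, longitudinally averaged
    n_rows_averaged: int = 1
    source_kind: str = "film"             # film | tg43 | external_grid

    def __post_init__(self):
        az = np.asarray(self.azimuth_deg, float)
        d = np.asarray(self.dose, float)
        if np.any(az < 0) or np.any(az >= 360) or np.any(np.diff(az) <= 0):
            raise ValueError("azimuth must be monotone within [0, 360)")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("dose must be finite and non-negative")
        self.azimuth_deg, self.dose = az, d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"azimuth_deg": self.azimuth_deg,
                             "dose_cGy": self.dose})


@dataclass
class VariationMetrics:
    """Spread statistics of an azimuthal profile with k=2 companions."""

    mean_dose: float
    max_variation: float
    baseline_variation: float | None = None
    largest_peak: float | None = None
    expanded: dict = field(default_factory=dict)

    @property
    def max_variation_pct(self):
        return 100.0 * self.max_variation / self.mean_dose

    @property
    def baseline_variation_pct(self):
        return (None if self.baseline_variation is None
                else 100.0 * self.baseline_variation / self.mean_dose)

    @property
    def largest_peak_pct(self):
        return (None if self.largest_peak is None
                else 100.0 * self.largest_peak / self.mean_dose)

    def to_dict(self) -> dict:
        d = {"mean_dose_cGy": self.mean_dose,
             "max_variation_cGy": self.max_variation,
             "max_variation_pct": self.max_variation_pct}
        if self.largest_peak is not None:
            d["largest_peak_cGy"] = self.largest_peak
            d["largest_peak_pct"] = self.largest_peak_pct
        if self.baseline_variation is not None:
            d["baseline_variation_cGy"] = self.baseline_variation
            d["baseline_variation_pct"] = self.baseline_variation_pct
        d.update({f"U_{k}": v for k, v in self.expanded.items()})
        return d


# ---------------------------------------------------------------------------
# inverse-square relocation

def is_correction_central(film_layer_radius_mm: float,
                          surface_radius_mm: float) -> float:
    """IS factor relocating a central-channel film dose to the surface:
    (r_film / r_surface)^2."""
    if film_layer_radius_mm <= 0 or surface_radius_mm <= 0:
        raise ValueError("radii must be positive")
    return (film_layer_radius_mm / surface_radius_mm) ** 2


def is_correction_peripheral(plan: Plan, applicator: ApplicatorModel,
                             film_layer_radius_mm: float = 17.635,
                             n_azimuths: int = 16,
                             evaluation_z_mm: float = 95.0) -> float:
    """Average IS correction for a peripheral loading.

    For each of ``n_azimuths`` equispaced surface points the correction is
    the dwell-time-weighted mean of the per-dwell factors
    (d_film / d_surface)^2 (3-D distances to the film-layer and surface
    locations of the point); the returned value is the average over the
    points.
    """
    if n_azimuths < 1:
        raise ValueError("n_azimuths must be >= 1")
    t = plan.dwell_times
    if np.all(t == 1.0) and "scale_s" not in plan.normalization:
        raise ValueError("plan has no optimized dwell times")
    centers = plan.dwell_centers
    az = np.deg2rad(np.arange(n_azimuths) * 360.0 / n_azimuths)
    rs, rf = applicator.outer_radius, film_layer_radius_mm
    p_surf = np.stack([rs * np.cos(az), rs * np.sin(az),
                       np.full_like(az, evaluation_z_mm)], axis=-1)
    p_film = np.stack([rf * np.cos(az), rf * np.sin(az),
                       np.full_like(az, evaluation_z_mm)], axis=-1)
    d_s = np.linalg.norm(p_surf[:, None, :] - centers[None, :, :], axis=-1)
    d_f = np.linalg.norm(p_film[:, None, :] - centers[None, :, :], axis=-1)
    per_point = (t[None, :] * (d_f / d_s) ** 2).sum(axis=1) / t.sum()
    return float(per_point.mean())


# ---------------------------------------------------------------------------
# profiles

def moving_average(y: np.ndarray, width: int, circular: bool = False):
    """Centered moving average; truncated window at the edges unless the
    profile wraps (``circular``)."""
    if width < 1 or width % 2 == 0:
        raise ValueError("moving-average width must be odd and >= 1")
    if width == 1:
        return np.asarray(y, float).copy()
    y = np.asarray(y, float)
    h = width // 2
    if circular:
        idx = np.arange(-h, h + 1)
        return np.mean(y[(np.arange(len(y))[:, None] + idx) % len(y)], axis=1)
    c = np.cumsum(np.concatenate([[0.0], y]))
    lo = np.maximum(np.arange(len(y)) - h, 0)
    hi = np.minimum(np.arange(len(y)) + h + 1, len(y))
    return (c[hi] - c[lo]) / (hi - lo)


def band_height_mm(band_height_px: int, dpi: float = 72.0) -> float:
    """Physical height of an averaging band of ``band_height_px`` rows."""
    return band_height_px * 25.4 / dpi


def longitudinal_profile(dose_map: DoseMap, band_height_px: int = 100,
                         moving_avg_px: int = 5,
                         wrap_diameter_mm: float = 35.27,
                         center_row: int | None = None,
                         circular: bool = False,
                         source_kind: str = "film") -> AzimuthalProfile:
    """Longitudinally average a wrapped-film dose map into an azimuthal
    profile.

    Column means are taken over ``band_height_px`` rows centered on
    ``center_row`` (map center by default), then smoothed with a centered
    moving average of ``moving_avg_px`` columns.  Column c maps to azimuth
    360 * (c * pitch) / (pi * wrap_diameter).
    """
    H, W = dose_map.dose.shape
    if band_height_px > H:
        raise ValueError("averaging band is taller than the dose map")
    c0 = H // 2 if center_row is None else center_row
    lo = c0 - band_height_px // 2
    if lo < 0 or lo + band_height_px > H:
        raise ValueError("averaging band does not fit inside the map")
    band = dose_map.dose[lo:lo + band_height_px, :]
    prof = moving_average(band.mean(axis=0), moving_avg_px, circular=circular)
    az = (360.0 * np.arange(W) * dose_map.pixel_pitch_mm
          / (np.pi * wrap_diameter_mm))
    if az[-1] >= 360.0:
        warnings.warn("film wider than one circumference; azimuths wrap",
                      stacklevel=2)
        az = az % 360.0
    return AzimuthalProfile(az, prof, n_rows_averaged=band_height_px,
                            source_kind=source_kind)


def variation_metrics(profile: AzimuthalProfile,
                      groove_azimuths_deg=(0.0, 180.0),
                      peak_halfwidth_deg: float = 15.0,
                      detect_peaks: bool = True,
                      type_a: float = 0.0,
                      type_b_rel: float = 0.0,
                      k: float = 2.0) -> VariationMetrics:
    """Variation statistics of a full-circumference azimuthal profile.

    ``max_variation`` is max - min over the whole profile; the peak windows
    (groove azimuth ± half-width) are excluded for ``baseline_variation``;
    ``largest_peak`` is the highest in-window dose above the mean outside
    the windows.  Expanded (k=2) companions combine the profile's type A
    scatter with the relative type B budget.
    """
    az, dose = profile.azimuth_deg, profile.dose
    if az[-1] - az[0] < 300.0:
        raise ValueError("profile must cover the full circumference")
    in_peak = np.zeros(len(az), bool)
    for g in np.atleast_1d(groove_azimuths_deg):
        diff = np.abs((az - g + 180.0) % 360.0 - 180.0)
        in_peak |= diff <= peak_halfwidth_deg
    if in_peak.all():
        raise ValueError("peak windows cover the whole circumference")

    mean_dose = float(dose.mean())
    max_var = float(dose.max() - dose.min())
    baseline = dose[~in_peak]
    base_var = float(baseline.max() - baseline.min())
    peak = (float(dose[in_peak].max() - baseline.mean())
            if detect_peaks and in_peak.any() else None)

    # type A: scatter of the averaged profile values (0 for an exact
    # engine curve unless supplied); type B: relative calibration/formalism
    # budget.  A difference of two profile values carries sqrt(2) of each.
    sem = type_a / np.sqrt(max(len(dose), 1))
    U_mean = expanded_uncertainty(dose, sem, type_b_rel, k)
    U_var = k * np.sqrt(2.0) * float(np.hypot(type_a, type_b_rel * mean_dose))
    exp = {"mean_dose_cGy": U_mean, "variation_cGy": U_var, "coverage_k": k}
    return VariationMetrics(mean_dose=mean_dose, max_variation=max_var,
                            baseline_variation=base_var, largest_peak=peak,
                            expanded=exp)


def percent_difference(reference, comparison) -> np.ndarray:
    """Elementwise 100 * (comparison - reference) / reference; non-positive
    reference entries are masked to NaN with a warning."""
    ref = np.asarray(reference, float)
    cmp_ = np.asarray(comparison, float)
    if ref.shape != cmp_.shape:
        raise ValueError("grids must share a point set")
    bad = ref <= 0
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} reference dose(s) <= 0 masked",
                      stacklevel=2)
    out = np.full(ref.shape, np.nan)
    out[~bad] = 100.0 * (cmp_[~bad] - ref[~bad]) / ref[~bad]
    return out


def surface_dose_curve(plan: Plan, source: SourceModel,
                       applicator: ApplicatorModel | None = None,
                       n_z: int = 9, span_mm: float = 40.0,
                       center_z_mm: float = 95.0) -> AzimuthalProfile:
    """TG-43 longitudinally averaged surface dose vs azimuth.

    For each of the 16 prescription azimuths, the mean dose over ``n_z``
    z-levels spanning ``span_mm`` centered at ``center_z_mm`` on the
    applicator surface.
    """
    applicator = applicator or ApplicatorModel()
    az = prescription_azimuths_deg()
    z = center_z_mm + np.linspace(-span_mm / 2.0, span_mm / 2.0, n_z)
    R = applicator.outer_radius
    A, Z = np.meshgrid(np.deg2rad(az), z, indexing="ij")
    pts = np.stack([R * np.cos(A), R * np.sin(A), Z], axis=-1).reshape(-1, 3)
    doses = dose_from_plan(source, plan.dwells, pts).reshape(len(az), n_z)
    return AzimuthalProfile(az, doses.mean(axis=1), n_rows_averaged=n_z,
                            source_kind="tg43")


def load_dose_grid_csv(path) -> pd.DataFrame:
    """Externally computed dose grid: columns x_mm, y_mm, z_mm, dose_cGy."""
    df = pd.read_csv(path)
    missing = {"x_mm", "y_mm", "z_mm", "dose_cGy"} - set(df.columns)
    if missing:
        raise ValueError(f"dose grid CSV missing columns {sorted(missing)}")
    return df
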