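"""Azimuthal dose asymmetry from off-axis source positioning.

The central channel (2.7 mm measured diameter) is much wider than the
0.9 mm Ir-192 source, so every dwell can rest against the channel wall.
In the worst case all dwells touch the same side while the film sits an
extra 0.2 mm off the surface on the opposite side.  The resulting
far-side/near-side dose ratio at the film active layer is estimated with
pure inverse-square weighting (no radial-dose or anisotropy factors): the
dwell-time-weighted mean of the per-dwell inverse-square ratios, evaluated
at a point midway down the irradiated film band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .applicator import Plan
from .tg43 import SourceModel, dose_from_plan, DwellPosition


@dataclass(frozen=True)
class OffsetGeometry:
    channel_inner_diameter_mm: float = 2.7   # measured from µCT
    source_diameter_mm: float = 0.9
    air_gap_mm: float = 0.2
    film_layer_radius_mm: float = 17.635
    evaluation_z_mm: float = 95.0            # midpoint of the irradiated band

    def __post_init__(self):
        if self.source_diameter_mm >= self.channel_inner_diameter_mm:
            raise ValueError("source must fit inside the channel")
        if self.air_gap_mm < 0:
            raise ValueError("air gap cannot be negative")


def max_source_offset(geom: OffsetGeometry) -> float:
    """Largest lateral source displacement: (channel - source diameter)/2, mm."""
    return (geom.channel_inner_diameter_mm - geom.source_diameter_mm) / 2.0


def far_near_dose_ratio(plan: Plan, geom: OffsetGeometry) -> float:
    """Worst-case far/near inverse-square dose ratio at the film layer.

    With every dwell displaced by the maximum offset toward the near side,
    the near lateral distance is ``film_layer_radius - offset`` and the far
    lateral distance ``film_layer_radius + air_gap + offset``.  Per dwell
    the ratio of inverse squared 3-D distances is averaged with dwell-time
    weights (the IS-correction convention), at a point at
    ``evaluation_z``.
    """
    t = plan.dwell_times
    if np.all(t == 1.0) and "scale_s" not in plan.normalization:
        raise ValueError("plan has no optimized dwell times")
    off = max_source_offset(geom)
    lat_near = geom.film_layer_radius_mm - off
    lat_far = geom.film_layer_radius_mm + geom.air_gap_mm + off
    dz = plan.dwell_centers[:, 2] - geom.evaluation_z_mm
    d2_near = lat_near**2 + dz**2
    d2_far = lat_far**2 + dz**2
    return float((t * (d2_near / d2_far)).sum() / t.sum())


def far_near_dose_ratio_summed(plan: Plan, geom: OffsetGeometry) -> float:
    """Physical far/near ratio: time-weighted inverse-square dose sums.

    [sum_i t_i d_far,i^-2] / [sum_i t_i d_near,i^-2] — the asymmetry a film
    actually measures.  Smaller than :func:`far_near_dose_ratio` (the
    average-IS-correction estimate) because the near-side sum is dominated
    by the closest dwells.
    """
    t = plan.dwell_times
    off = max_source_offset(geom)
    lat_near = geom.film_layer_radius_mm - off
    lat_far = geom.film_layer_radius_mm + geom.air_gap_mm + off
    dz = plan.dwell_centers[:, 2] - geom.evaluation_z_mm
    near = (t / (lat_near**2 + dz**2)).sum()
    far = (t / (lat_far**2 + dz**2)).sum()
    return float(far / near)


def far_near_dose_ratio_tg43(plan: Plan, source: SourceModel,
                             geom: OffsetGeometry) -> float:
    """Full TG-43 variant of the far/near ratio, for sensitivity analysis.

    Displaces the dwells laterally by the maximum offset and evaluates the
    TG-43 dose at the near- and far-side film-layer points at
    ``evaluation_z`` (not the acceptance path, which is pure
    inverse-square).
    """
    off = max_source_offset(geom)
    shifted = [DwellPosition(d.center + np.array([off, 0.0, 0.0]),
                             d.dwell_time, d.axis_direction, d.channel_id)
               for d in plan.dwells]
    near = np.array([geom.film_layer_radius_mm, 0.0, geom.evaluation_z_mm])
    far = np.array([-(geom.film_layer_radius_mm + geom.air_gap_mm), 0.0,
                    geom.evaluation_z_mm])
    d_near, d_far = dose_from_plan(source, shifted, [near, far])
    return float(d_far / d_near)


def baseline_variation_percent(ratio: float) -> float:
    """Peak-to-peak asymmetry as a percent of the mean:
    100 * 2 (1 - ratio) / (1 + ratio)."""
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio must be in (0, 1]")
    return 100.0 * 2.0 * (1.0 - ratio) / (1.0 + ratio)
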