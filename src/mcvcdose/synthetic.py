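"""Synthetic film-scan generator.

Emulates the measurement chain the analysis assumes — rational per-channel
response, a smooth multiplicative thickness-disturbance field, Gaussian
scanner noise, the wrapped-film geometry with an azimuth-dependent air
gap, and an optional lateral source offset — on top of exact TG-43 ground
truth.  No heterogeneity transport is simulated: groove scatter effects
are deliberately absent, so synthetic central-loading films have no groove
peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .applicator import ApplicatorModel, Plan
from .film import CHANNELS, CalibrationCurve, DoseMap, FilmImage, MAX_PV
from .tg43 import DwellPosition, SourceModel, dose_from_plan

DEFAULT_CAL_DOSES = (0.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0,
                     400.0, 500.0, 600.0, 800.0, 1000.0)


def default_true_curves() -> dict:
    """Plausible EBT3-like response curves (red most sensitive)."""
    return {
        "red": CalibrationCurve("red", a=270.0, b=0.10, c=300.0),
        "green": CalibrationCurve("green", a=285.0, b=0.18, c=300.0),
        "blue": CalibrationCurve("blue", a=288.0, b=0.48, c=300.0),
    }


@dataclass
class SimulationConfig:
    calibration_doses: tuple = DEFAULT_CAL_DOSES   # 13 levels over 0..1000 cGy
    true_curves: dict = field(default_factory=default_true_curves)
    pv_noise_rel: float = 0.003          # relative Gaussian scanner noise
    thickness_amplitude: float = 0.02    # peak |delta| of the smooth field
    thickness_corr_mm: float = 10.0      # correlation length of the field
    air_gap_max_mm: float = 0.0          # azimuthal air-gap profile amplitude
    air_gap_azimuth_deg: float = 180.0   # azimuth of the widest gap
    source_offset_mm: float = 0.0        # lateral dwell displacement
    source_offset_azimuth_deg: float = 0.0
    dpi: float = 72.0
    seed: int = 0

    def __post_init__(self):
        if self.thickness_amplitude > 0.05:
            raise ValueError("|delta| amplitude above physical bound 0.05")
        if self.air_gap_max_mm > 0.5:
            raise ValueError("air gap above physical bound 0.5 mm")


def _thickness_field(shape, pitch_mm, amplitude, corr_mm, rng):
    """Smooth multiplicative disturbance field, zero-mean, peak ~amplitude."""
    if amplitude == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    sigma_px = corr_mm / pitch_mm
    smooth = gaussian_filter(white, sigma=sigma_px, mode="wrap")
    smooth -= smooth.mean()
    peak = np.max(np.abs(smooth))
    return smooth * (amplitude / peak) if peak > 0 else smooth


def _expose(dose, delta, curves, noise_rel, rng):
    """Pixel values from dose (H, W), disturbance (H, W): uint16 (H, W, 3)."""
    H, W = dose.shape
    px = np.empty((H, W, 3), np.uint16)
    for k, ch in enumerate(CHANNELS):
        X = curves[ch].response(dose) * (1.0 + delta)
        if noise_rel > 0:
            X = X * (1.0 + noise_rel * rng.standard_normal(dose.shape))
        px[..., k] = np.clip(np.rint(X * MAX_PV), 0, MAX_PV).astype(np.uint16)
    return px


def simulate_calibration_set(config: SimulationConfig,
                             piece_size_px: int = 64):
    """Uniformly irradiated calibration pieces, one per dose level.

    Returns ``(films, doses)``: a list of FilmImage pieces and the
    ground-truth doses.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    pitch = 25.4 / config.dpi
    films, doses = [], []
    for D in config.calibration_doses:
        delta = _thickness_field((piece_size_px, piece_size_px), pitch,
                                 config.thickness_amplitude,
                                 config.thickness_corr_mm, rng)
        dose = np.full((piece_size_px, piece_size_px), float(D))
        px = _expose(dose, delta, config.true_curves, config.pv_noise_rel, rng)
        films.append(FilmImage(px, dpi=config.dpi,
                               metadata={"dose_cGy": float(D),
                                         "seed": config.seed}))
        doses.append(float(D))
    return films, doses


def calibration_responses(films, n_border_px: int = 8):
    """Mean response and standard error per channel from the central region
    of each calibration piece, in fit_calibration's input layout."""
    resp = {ch: ([], []) for ch in CHANNELS}
    for film in films:
        X = film.response[n_border_px:-n_border_px, n_border_px:-n_border_px, :]
        for k, ch in enumerate(CHANNELS):
            vals = X[..., k].ravel()
            resp[ch][0].append(vals.mean())
            resp[ch][1].append(vals.std(ddof=1) / np.sqrt(vals.size))
    return {ch: (np.array(m), np.array(s)) for ch, (m, s) in resp.items()}


def simulate_wrapped_film(plan: Plan, applicator: ApplicatorModel,
                          source: SourceModel, config: SimulationConfig,
                          height_px: int = 120,
                          center_z_mm: float = 95.0):
    """Unwrapped scan of a film wrapped around the applicator.

    The film is a rectangle at ``config.dpi``; width spans exactly one
    circumference of the active layer, rows map to z centered on
    ``center_z_mm``.  The per-pixel dose is the TG-43 dose at the active
    layer (nominal radius = outer radius + half the 0.27 mm film, plus the
    azimuthal air-gap profile), with the dwells optionally displaced
    laterally by the configured source offset.  Returns the scan and the
    ground-truth DoseMap.
    """
    if plan.dwell_times.max() == plan.dwell_times.min() == 1.0 \
            and "scale_s" not in plan.normalization:
        raise ValueError("plan must be optimized before simulating a film")
    rng = np.random.default_rng(config.seed)
    pitch = 25.4 / config.dpi
    film_mid_mm = 0.27 / 2.0
    r_nominal = applicator.outer_radius + film_mid_mm
    width_px = int(round(2.0 * np.pi * r_nominal / pitch))

    az = 2.0 * np.pi * np.arange(width_px) / width_px
    gap = (config.air_gap_max_mm * 0.5
           * (1.0 + np.cos(az - np.deg2rad(config.air_gap_azimuth_deg))))
    radius = r_nominal + gap                                    # (W,)
    z = center_z_mm + (np.arange(height_px) - (height_px - 1) / 2.0) * pitch

    A, Z = np.meshgrid(az, z, indexing="xy")                    # (H, W)
    R = np.broadcast_to(radius, A.shape)
    pts = np.stack([R * np.cos(A), R * np.sin(A), Z], axis=-1).reshape(-1, 3)

    dwells = plan.dwells
    if config.source_offset_mm != 0.0:
        shift = config.source_offset_mm * np.array(
            [np.cos(np.deg2rad(config.source_offset_azimuth_deg)),
             np.sin(np.deg2rad(config.source_offset_azimuth_deg)), 0.0])
        dwells = [DwellPosition(d.center + shift, d.dwell_time,
                                d.axis_direction, d.channel_id)
                  for d in dwells]

    dose = dose_from_plan(source, dwells, pts).reshape(height_px, width_px)
    delta = _thickness_field(dose.shape, pitch, config.thickness_amplitude,
                             config.thickness_corr_mm, rng)
    px = _expose(dose, delta, config.true_curves, config.pv_noise_rel, rng)
    film = FilmImage(px, dpi=config.dpi,
                     metadata={"seed": config.seed,
                               "loading": plan.loading_mode,
                               "wrap_radius_mm": r_nominal})
    truth = DoseMap(dose, np.zeros_like(dose), delta, pitch)
    return film, truth
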