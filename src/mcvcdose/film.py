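"""Radiochromic (EBT3-like) film calibration, dose inversion and uncertainty.

The normalized scanner response of a film pixel in one color channel is
modeled by the rational form

    X(D) = (a + b D) / (c + D),

with D in cGy and X the pixel value divided by 65535.  ``a``, ``b`` and
``c`` are fitted per channel by effective-variance least squares.  Unknown
doses are recovered by triple-channel analysis: the red, green and blue
responses of a pixel share one multiplicative thickness disturbance
``(1 + delta)``, and (D, delta) are solved iteratively so the three
channels agree; the final dose is the uncertainty-weighted mean of the
per-channel inversions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

MAX_PV = 65535.0
CHANNELS = ("red", "green", "blue")


class SaturationError(ValueError):
    """Response outside the attainable range of the calibration curve."""


@dataclass
class CalibrationCurve:
    """Per-channel rational response curve X(D) = (a + bD)/(c + D)."""

    channel: str
    a: float
    b: float
    c: float
    parameter_covariance: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 3)))
    dose_domain: tuple = (0.0, 1000.0)

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.b * self.c >= self.a:
            warnings.warn("calibration curve is not strictly decreasing "
                          "(b*c >= a)", stacklevel=2)
        x_lo = self.response(self.dose_domain[1])
        x_hi = self.response(self.dose_domain[0])
        if not (0.0 < x_lo and x_hi <= 1.0):
            raise ValueError("response must stay in (0, 1] over the dose domain")
        self.parameter_covariance = np.asarray(self.parameter_covariance, float)

    # -- forward / inverse -------------------------------------------------

    def response(self, dose):
        dose = np.asarray(dose, float)
        out = (self.a + self.b * dose) / (self.c + dose)
        return out.item() if out.ndim == 0 else out

    def response_deriv(self, dose):
        dose = np.asarray(dose, float)
        out = (self.b * self.c - self.a) / (self.c + dose) ** 2
        return out.item() if out.ndim == 0 else out

    def dose(self, X, clip: bool = False):
        """Invert the response: D = (a - cX)/(X - b).

        Outside the attainable open interval (X(Dmax), X(0)) the inversion
        either raises :class:`SaturationError` or, with ``clip=True``,
        clamps to the dose domain.
        """
        X = np.asarray(X, float)
        lo, hi = self.response(self.dose_domain[1]), self.response(self.dose_domain[0])
        if clip:
            X = np.clip(X, lo, hi)
        else:
            if np.any(X > hi):
                raise SaturationError(f"{self.channel}: response above the "
                                      "unexposed level (dose would be negative)")
            if np.any(X < lo):
                raise SaturationError(f"{self.channel}: response below the "
                                      "maximum-dose level (saturated)")
        out = (self.a - self.c * X) / (X - self.b)
        if clip:
            out = np.clip(out, *self.dose_domain)
        return out.item() if out.ndim == 0 else out

    def dose_rel_uncertainty(self, dose, sigma_X=0.0):
        """k=1 relative dose uncertainty from the fit covariance plus
        response noise, propagated through the inverse curve."""
        dose = np.atleast_1d(np.asarray(dose, float))
        X = self.response(dose)
        denom = X - self.b
        # jacobian of D(X; a, b, c) at the curve
        dD_da = 1.0 / denom
        dD_db = (self.a - self.c * X) / denom**2
        dD_dc = -X / denom
        J = np.stack([dD_da, dD_db, dD_dc], axis=-1)
        var = np.einsum("...i,ij,...j->...", J, self.parameter_covariance, J)
        dD_dX = 1.0 / self.response_deriv(dose)
        var = var + (dD_dX * np.asarray(sigma_X, float)) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.sqrt(var) / np.abs(dose)
        rel[dose == 0] = np.inf
        return rel if rel.size > 1 else rel.item()

    def to_dict(self) -> dict:
        return {"channel": self.channel, "a": self.a, "b": self.b, "c": self.c,
                "parameter_covariance": self.parameter_covariance.tolist(),
                "dose_domain": list(self.dose_domain)}

    @classmethod
    def from_dict(cls, obj) -> "CalibrationCurve":
        return cls(obj["channel"], obj["a"], obj["b"], obj["c"],
                   np.asarray(obj["parameter_covariance"], float),
                   tuple(obj["dose_domain"]))


def save_curves(curves: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump({ch: c.to_dict() for ch, c in curves.items()}, fh, indent=1)


def load_curves(path) -> dict:
    with open(path) as fh:
        return {ch: CalibrationCurve.from_dict(o) for ch, o in json.load(fh).items()}


@dataclass
class FilmImage:
    """48-bit RGB scan: H x W x 3 16-bit pixel values."""

    pixels: np.ndarray
    dpi: float = 72.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if px.min() < 0 or px.max() > 65535:
            raise ValueError("pixel values must be within [0, 65535]")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        self.pixels = px.astype(np.uint16)

    @property
    def pixel_pitch_mm(self) -> float:
        return 25.4 / self.dpi

    @property
    def response(self) -> np.ndarray:
        """Normalized response X = PV / 65535, float (H, W, 3)."""
        return self.pixels.astype(float) / MAX_PV

    def save_tiff(self, path) -> None:
        import tifffile
        tifffile.imwrite(path, self.pixels,
                         resolution=(self.dpi, self.dpi), photometric="rgb")

    @classmethod
    def load_tiff(cls, path, dpi: float = 72.0) -> "FilmImage":
        import tifffile
        return cls(tifffile.imread(path), dpi=dpi)


@dataclass
class DoseMap:
    """Reconstructed per-pixel dose with uncertainty and disturbance maps."""

    dose: np.ndarray                   # cGy
    rel_uncertainty_k1: np.ndarray     # standard (k=1), relative
    disturbance: np.ndarray            # thickness factor delta
    pixel_pitch_mm: float
    valid: np.ndarray | None = None

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.isfinite(self.dose)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.dose).to_csv(path, index=False, header=False,
                                       float_format="%.3f")

    def save_tiff16(self, path, sidecar_path=None) -> None:
        """16-bit scaled TIFF plus a JSON sidecar recording the scale."""
        import tifffile
        peak = float(np.nanmax(self.dose))
        scale = peak / 65535.0 if peak > 0 else 1.0
        img = np.clip(np.nan_to_num(self.dose) / scale, 0,
                      65535).astype(np.uint16)
        tifffile.imwrite(path, img)
        sidecar = sidecar_path or str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump({"units": "cGy", "cGy_per_count": scale,
                       "pixel_pitch_mm": self.pixel_pitch_mm}, fh, indent=1)


# ---------------------------------------------------------------------------
# calibration fitting

def load_calibration_csv(path):
    """Read a calibration table (columns dose_cGy, X_<ch>, sX_<ch> per
    channel) into the (doses, responses) layout of fit_calibration."""
    df = pd.read_csv(path)
    responses = {ch: (df[f"X_{ch}"].to_numpy(float),
                      df[f"sX_{ch}"].to_numpy(float)) for ch in CHANNELS}
    return df["dose_cGy"].to_numpy(float), responses


def _pack_responses(responses):
    """Accept {channel: (X, sX)} or a (n, 2)-like per channel."""
    X = np.column_stack([np.asarray(responses[ch][0], float) for ch in CHANNELS])
    sX = np.column_stack([np.asarray(responses[ch][1], float) for ch in CHANNELS])
    return X, sX


def fit_calibration(doses, responses, dose_uncertainties=None,
                    dose_domain=(0.0, 1000.0)) -> dict:
    """Fit X(D) = (a + bD)/(c + D) per channel by effective-variance least
    squares.

    Parameters
    ----------
    doses : array
        Delivered dose levels, cGy; at least 4 distinct levels including 0.
    responses : mapping
        ``{channel: (X_mean, X_sigma)}`` arrays over the dose levels.
    dose_uncertainties : array, optional
        One-sigma dose delivery uncertainties (same length); the effective
        variance per point is sigma_X^2 + (dX/dD)^2 sigma_D^2.

    Returns
    -------
    dict of channel -> CalibrationCurve (with parameter covariance from the
    Jacobian at the optimum).
    """
    D = np.asarray(doses, float)
    if len(np.unique(D)) < 4 or not np.any(D == 0):
        raise ValueError("need >= 4 distinct dose levels including 0")
    sD = np.zeros_like(D) if dose_uncertainties is None \
        else np.asarray(dose_uncertainties, float)
    X, sX = _pack_responses(responses)
    if np.any(X <= 0) or np.any(X > 1):
        raise ValueError("responses must be in (0, 1]")

    curves = {}
    for k, ch in enumerate(CHANNELS):
        x, sx = X[:, k], sX[:, k]
        order = np.argsort(D)
        if np.any(np.diff(x[order]) > 0):
            warnings.warn(f"{ch}: mean responses are not monotone in dose",
                          stacklevel=2)
        # start from the exact solution of three well-separated points
        a0, b0, c0 = _initial_guess(D, x)

        def weights(p):
            a, b, c = p
            dXdD = (b * c - a) / (c + D) ** 2
            w = sx**2 + (dXdD * sD) ** 2
            w[w <= 0] = max(np.max(w), 1e-12) * 1e-6 + 1e-18
            return np.sqrt(w)

        def resid(p, w):
            a, b, c = p
            return ((a + b * D) / (c + D) - x) / w

        p = np.array([a0, b0, c0])
        for _ in range(4):  # effective-variance outer loop
            w = weights(p)
            sol = least_squares(resid, p, args=(w,), method="lm",
                                xtol=1e-14, ftol=1e-14)
            if np.max(np.abs(sol.x - p)) < 1e-12 * np.max(np.abs(p)):
                p = sol.x
                break
            p = sol.x
        if not sol.success:
            raise RuntimeError(f"{ch}: calibration fit failed: {sol.message}")
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J)
        except np.linalg.LinAlgError:
            cov = np.full((3, 3), np.nan)
        curves[ch] = CalibrationCurve(ch, *p, parameter_covariance=cov,
                                      dose_domain=tuple(dose_domain))
    return curves


def _initial_guess(D, x):
    """Exact (a, b, c) through the min/median/max dose points."""
    idx = np.argsort(D)
    i0, i1, i2 = idx[0], idx[len(idx) // 2], idx[-1]
    A = np.array([[1.0, D[i], -x[i]] for i in (i0, i1, i2)])
    rhs = np.array([x[i] * D[i] for i in (i0, i1, i2)])
    try:
        a, b, c = np.linalg.solve(A, rhs)
        if c > 0:
            return a, b, c
    except np.linalg.LinAlgError:
        pass
    return x[i0] * 300.0, x[i2], 300.0


# ---------------------------------------------------------------------------
# simple response transforms

def optical_density(X):
    """Net optical density OD = -log10(X) of a normalized response."""
    X = np.asarray(X, float)
    if np.any(X <= 0):
        raise ValueError("response must be positive")
    out = -np.log10(X)
    return out.item() if out.ndim == 0 else out


def invert_response(X, curve: CalibrationCurve):
    """Algebraic inverse of the calibration curve (see CalibrationCurve.dose)."""
    return curve.dose(X)


def apply_output_correction(doses, measured_over_expected: float):
    """Scale delivered doses by the linac output ratio (sanity window 0.9-1.1)."""
    if not 0.9 < measured_over_expected < 1.1:
        raise ValueError("output correction factor outside (0.9, 1.1)")
    return np.asarray(doses, float) * measured_over_expected


def expanded_uncertainty(values, type_a: float, type_b_rel: float,
                         k: float = 2.0) -> float:
    """Expanded uncertainty k*sqrt(typeA^2 + (typeB_rel*mean)^2)."""
    if k <= 0:
        raise ValueError("coverage factor must be positive")
    mean = float(np.mean(values))
    return k * float(np.hypot(type_a, type_b_rel * mean))


# ---------------------------------------------------------------------------
# triple-channel reconstruction

def triple_channel_dose_map(responses: np.ndarray, curves: dict,
                            sigma_X_rel: float = 0.003,
                            delta_bound: float = 0.1,
                            tol_cGy: float = 0.1,
                            max_iter: int = 50):
    """Vectorized triple-channel (D, delta) solve for an array of pixels.

    ``responses`` has shape (..., 3) in channel order red, green, blue.  The
    measured response is modeled as X_ch(D) * (1 + delta) with a single
    disturbance shared by the channels.  Alternates a dose update (weighted
    mean of per-channel inversions, weights 1/u_rel^2 from the calibration
    covariance) with a closed-form log-space least-squares delta update,
    until the dose moves by less than ``tol_cGy`` or ``max_iter`` sweeps.

    Returns ``(dose, delta, rel_u_k1, valid, converged)`` arrays of the
    leading shape.
    """
    Xm = np.asarray(responses, float)
    shape = Xm.shape[:-1]
    Xm = Xm.reshape(-1, 3)
    clist = [curves[ch] for ch in CHANNELS]

    delta = np.zeros(len(Xm))
    dose = np.full(len(Xm), np.nan)
    converged = np.zeros(len(Xm), bool)
    u_rel_comb = np.full(len(Xm), np.nan)

    for it in range(max_iter):
        D_ch = np.empty_like(Xm)
        w_ch = np.empty_like(Xm)
        Xcorr = Xm / (1.0 + delta)[:, None]
        for k, c in enumerate(clist):
            D_ch[:, k] = c.dose(Xcorr[:, k], clip=True)
            u = c.dose_rel_uncertainty(np.maximum(D_ch[:, k], 1.0),
                                       sigma_X=sigma_X_rel * Xcorr[:, k])
            w_ch[:, k] = 1.0 / np.maximum(u, 1e-12) ** 2
        new_dose = np.sum(w_ch * D_ch, axis=1) / np.sum(w_ch, axis=1)
        moved = ~converged & (~np.isfinite(dose)
                              | (np.abs(new_dose - dose) >= tol_cGy))
        dose = new_dose
        u_rel_comb = 1.0 / np.sqrt(np.sum(w_ch, axis=1)) / np.maximum(dose, 1e-9)
        converged |= ~moved
        # delta update: least squares on log responses across channels
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.log(Xm) - np.log(np.column_stack(
                [c.response(dose) for c in clist]))
        delta = np.expm1(np.mean(logs, axis=1))
        delta = np.clip(delta, -0.5, 0.5)
        if np.all(converged):
            break

    # flag pixels whose corrected response fell outside the attainable range
    in_range = np.ones(len(Xm), bool)
    Xcorr = Xm / (1.0 + delta)[:, None]
    for k, c in enumerate(clist):
        lo, hi = c.response(c.dose_domain[1]), c.response(c.dose_domain[0])
        in_range &= (Xcorr[:, k] > lo) & (Xcorr[:, k] < hi)
    valid = (converged & in_range & (np.abs(delta) <= delta_bound)
             & np.isfinite(dose))
    return (dose.reshape(shape), delta.reshape(shape),
            u_rel_comb.reshape(shape), valid.reshape(shape),
            converged.reshape(shape))


def triple_channel_dose(pixel_responses, curves: dict, **kw):
    """Single-pixel convenience wrapper: returns (dose, delta, rel_u_k1)."""
    dose, delta, u, valid, conv = triple_channel_dose_map(
        np.asarray(pixel_responses, float)[None, :], curves, **kw)
    if not conv[0]:
        warnings.warn("triple-channel solve did not converge", stacklevel=2)
    return dose[0], delta[0], u[0]


def reconstruct_dose_map(image: FilmImage, curves: dict,
                         sigma_X_rel: float = 0.003,
                         delta_bound: float = 0.1) -> DoseMap:
    """Invert a scanned film to a DoseMap by triple-channel analysis."""
    dose, delta, u, valid, conv = triple_channel_dose_map(
        image.response, curves, sigma_X_rel=sigma_X_rel,
        delta_bound=delta_bound)
    return DoseMap(dose, u, delta, image.pixel_pitch_mm, valid=valid & conv)
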