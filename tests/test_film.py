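"""Film calibration fitting, response inversion, triple-channel analysis
and the uncertainty budget."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcvcdose import (CalibrationCurve, apply_output_correction,
                      expanded_uncertainty, fit_calibration, invert_response,
                      load_curves, optical_density, save_curves,
                      triple_channel_dose)
from mcvcdose.film import CHANNELS, SaturationError

DOSES = np.array([0., 25., 50., 75., 100., 150., 200., 300., 400., 500.,
                  600., 800., 1000.])


def synth_responses(curves, noise_rel=0.0, rng=None):
    resp = {}
    for ch in CHANNELS:
        X = curves[ch].response(DOSES)
        if noise_rel:
            X = X * (1.0 + noise_rel * rng.standard_normal(len(DOSES)))
        resp[ch] = (X, np.full(len(DOSES), max(noise_rel, 1e-4) * X.mean()))
    return resp


def grid_search_calibration(D, x, truth, span=0.1, n=41):
    """Independent coarse grid search for the best (a, b, c) near truth."""
    a0, b0, c0 = truth
    best, arg = np.inf, None
    for a in np.linspace(a0 * (1 - span), a0 * (1 + span), n):
        for b in np.linspace(b0 * (1 - 3 * span), b0 * (1 + 3 * span), n):
            for c in np.linspace(c0 * (1 - span), c0 * (1 + span), n):
                sse = np.sum(((a + b * D) / (c + D) - x) ** 2)
                if sse < best:
                    best, arg = sse, (a, b, c)
    return arg


class TestFitCalibration:
    def test_noiseless_self_consistency(self, true_curves):
        fitted = fit_calibration(DOSES, synth_responses(true_curves))
        for ch in CHANNELS:
            t, f = true_curves[ch], fitted[ch]
            assert f.a == pytest.approx(t.a, rel=1e-6)
            assert f.b == pytest.approx(t.b, rel=1e-6)
            assert f.c == pytest.approx(t.c, rel=1e-6)

    def test_zero_dose_response_is_a_over_c(self, true_curves):
        fitted = fit_calibration(DOSES, synth_responses(true_curves))
        for ch in CHANNELS:
            f = fitted[ch]
            assert f.response(0.0) == pytest.approx(f.a / f.c, rel=1e-12)

    def test_noisy_recovery_and_grid_search_oracle(self, true_curves):
        rng = np.random.default_rng(42)
        resp = synth_responses(true_curves, noise_rel=0.005, rng=rng)
        fitted = fit_calibration(DOSES, resp)
        for ch in ("red", "green"):  # most sensitive channels
            t, f = true_curves[ch], fitted[ch]
            sd = np.sqrt(np.diag(f.parameter_covariance))
            for i, p in enumerate("abc"):
                # each parameter within 3 standard errors of truth
                assert abs(getattr(f, p) - getattr(t, p)) < 3 * sd[i]
            ga, gb, gc = grid_search_calibration(
                DOSES, resp[ch][0], (t.a, t.b, t.c))
            # fit at least as good as the independent grid optimum
            sse_fit = np.sum((f.response(DOSES) - resp[ch][0]) ** 2)
            sse_grid = np.sum(((ga + gb * DOSES) / (gc + DOSES)
                               - resp[ch][0]) ** 2)
            assert sse_fit <= sse_grid * (1 + 1e-6)

    def test_too_few_levels_rejected(self, true_curves):
        with pytest.raises(ValueError):
            fit_calibration([0.0, 100.0, 200.0],
                            {ch: (np.array([0.9, 0.7, 0.6]),
                                  np.array([1e-3] * 3)) for ch in CHANNELS})

    def test_non_monotone_warns(self, true_curves):
        resp = synth_responses(true_curves)
        x, s = resp["red"]
        x = x.copy(); x[3] = x[2] + 0.05  # break monotonicity
        resp["red"] = (np.clip(x, 0, 1), s)
        with pytest.warns(UserWarning, match="monotone"):
            fit_calibration(DOSES, resp)

    def test_effective_variance_uses_dose_uncertainty(self, true_curves):
        resp = synth_responses(true_curves)
        a = fit_calibration(DOSES, resp)
        b = fit_calibration(DOSES, resp,
                            dose_uncertainties=0.01 * DOSES + 0.5)
        # noiseless data: same optimum either way
        assert a["red"].a == pytest.approx(b["red"].a, rel=1e-6)

    def test_curve_json_round_trip(self, true_curves, tmp_path):
        fitted = fit_calibration(DOSES, synth_responses(true_curves))
        path = tmp_path / "curves.json"
        save_curves(fitted, path)
        back = load_curves(path)
        for ch in CHANNELS:
            assert back[ch].a == pytest.approx(fitted[ch].a, rel=1e-12)
            np.testing.assert_allclose(back[ch].parameter_covariance,
                                       fitted[ch].parameter_covariance)


class TestOpticalDensity:
    def test_values(self):
        assert optical_density(1.0) == 0.0
        assert optical_density(0.1) == pytest.approx(1.0, rel=1e-12)
        assert optical_density(0.9 / 300.0) == pytest.approx(
            -np.log10(0.003), rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            optical_density(0.0)


class TestInvertResponse:
    def test_zero_dose(self, true_curves):
        c = true_curves["red"]
        assert invert_response(c.a / c.c, c) == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_250(self, true_curves):
        c = true_curves["green"]
        assert invert_response(c.response(250.0), c) == pytest.approx(
            250.0, abs=1e-10)

    def test_closed_form_500(self, true_curves):
        c = true_curves["blue"]
        X = (c.a + 500.0 * c.b) / (c.c + 500.0)
        assert invert_response(X, c) == pytest.approx(500.0, abs=1e-9)

    def test_saturation_sides_identified(self, true_curves):
        c = true_curves["red"]
        with pytest.raises(SaturationError, match="negative"):
            invert_response(c.response(0.0) + 1e-6, c)
        with pytest.raises(SaturationError, match="saturated"):
            invert_response(c.response(1000.0) - 1e-6, c)

    @given(d1=st.floats(1.0, 999.0), d2=st.floats(1.0, 999.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_strictly_decreasing(self, d1, d2, true_curves):
        c = true_curves["red"]
        x1, x2 = c.response(d1), c.response(d2)
        if x1 < x2:
            assert invert_response(x1, c) > invert_response(x2, c)


def grid_search_dose_delta(responses, curves, D_range, delta_range):
    """Exhaustive 2-D (D, delta) search minimizing response misfit."""
    best, arg = np.inf, None
    for D in np.arange(*D_range):
        model = np.array([curves[ch].response(D) for ch in CHANNELS])
        for delta in np.arange(*delta_range):
            sse = np.sum((responses - model * (1 + delta)) ** 2)
            if sse < best:
                best, arg = sse, (D, delta)
    return arg


class TestTripleChannel:
    def fitted(self, true_curves):
        return fit_calibration(DOSES, synth_responses(true_curves))

    def test_consistent_channels(self, true_curves):
        curves = self.fitted(true_curves)
        X = np.array([true_curves[ch].response(400.0) for ch in CHANNELS])
        dose, delta, _ = triple_channel_dose(X, curves)
        assert dose == pytest.approx(400.0, abs=0.1)
        assert delta == pytest.approx(0.0, abs=1e-4)

    def test_disturbed_pixel_grid_search_oracle(self, true_curves):
        curves = self.fitted(true_curves)
        X = np.array([true_curves[ch].response(400.0)
                      for ch in CHANNELS]) * 1.02
        dose, delta, _ = triple_channel_dose(X, curves)
        assert dose == pytest.approx(400.0, rel=0.01)
        assert delta == pytest.approx(0.02, abs=0.005)
        gD, gdelta = grid_search_dose_delta(
            X, curves, (380.0, 420.0, 0.25), (0.0, 0.04, 2.5e-4))
        assert dose == pytest.approx(gD, abs=1.0)
        assert delta == pytest.approx(gdelta, abs=1e-3)

    @pytest.mark.parametrize("delta", [-0.03, 0.03])
    def test_common_scaling_identifiability(self, true_curves, delta):
        curves = self.fitted(true_curves)
        X0 = np.array([true_curves[ch].response(300.0) for ch in CHANNELS])
        d0, _, _ = triple_channel_dose(X0, curves)
        d1, est, _ = triple_channel_dose(X0 * (1 + delta), curves)
        assert d1 == pytest.approx(d0, rel=0.01)
        assert est == pytest.approx(delta, abs=0.005)


class TestUncertaintyBudget:
    def test_zero_components(self):
        assert expanded_uncertainty([100.0], 0.0, 0.0) == 0.0

    def test_arithmetic(self):
        assert expanded_uncertainty([100.0], 3.0, 0.04, k=2) == pytest.approx(
            10.0, rel=1e-12)

    def test_tg43_mean_dose_budget_scale(self):
        # 3.4% type B on a ~500 cGy mean reproduces the ±35 cGy scale
        U = expanded_uncertainty([500.0], 0.0, 0.034, k=2)
        assert U == pytest.approx(34.0, abs=0.01)
        assert abs(U - 35.0) < 2.0

    def test_invalid_coverage(self):
        with pytest.raises(ValueError):
            expanded_uncertainty([1.0], 1.0, 0.0, k=0)


class TestOutputCorrection:
    def test_identity_and_scale(self):
        assert apply_output_correction([500.0], 1.0)[0] == 500.0
        assert apply_output_correction([500.0], 1.02)[0] == pytest.approx(
            510.0, rel=1e-12)

    def test_sanity_window(self):
        with pytest.raises(ValueError):
            apply_output_correction([500.0], 1.2)

    def test_refit_on_scaled_doses_shifts_dose_axis(self, true_curves):
        resp = synth_responses(true_curves)
        base = fit_calibration(DOSES, resp)
        scaled = fit_calibration(apply_output_correction(DOSES, 1.02), resp)
        X = true_curves["red"].response(400.0)
        assert scaled["red"].dose(X) == pytest.approx(
            1.02 * base["red"].dose(X), rel=1e-4)


class TestCalibrationCSV:
    def test_csv_layout_round_trip(self, true_curves, tmp_path):
        import pandas as pd
        from mcvcdose.film import load_calibration_csv
        resp = synth_responses(true_curves)
        rows = {"dose_cGy": DOSES}
        for ch in CHANNELS:
            rows[f"X_{ch}"], rows[f"sX_{ch}"] = resp[ch]
        path = tmp_path / "cal.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        doses, responses = load_calibration_csv(path)
        np.testing.assert_allclose(doses, DOSES)
        fitted = fit_calibration(doses, responses)
        assert fitted["red"].a == pytest.approx(true_curves["red"].a,
                                                rel=1e-6)


class TestDoseMapExport:
    def test_tiff16_with_sidecar(self, tmp_path):
        import json
        from mcvcdose import DoseMap
        dose = np.linspace(0, 600, 12).reshape(3, 4)
        dm = DoseMap(dose, np.zeros_like(dose), np.zeros_like(dose),
                     25.4 / 72)
        path = tmp_path / "map.tiff"
        dm.save_tiff16(path)
        import tifffile
        img = tifffile.imread(path)
        meta = json.loads((tmp_path / "map.tiff.json").read_text())
        back = img.astype(float) * meta["cGy_per_count"]
        np.testing.assert_allclose(back, dose, atol=0.01)
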