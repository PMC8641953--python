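"""pRF model fields, predicted responses and size definitions.

The key check is oracle equivalence: the vectorized prediction must match an
explicit double loop over pixels to 1e-10 relative tolerance.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prfmap.models import (
    MODELS,
    PRFParams,
    normalized_suppression,
    predict_from_stimulus,
    predict_response,
    prf_field,
    prf_size,
)


def brute_force_response(params, stim):
    """Independent oracle: explicit pixel loops, no vectorization."""
    ppd = stim.protocol.pixels_per_dva
    out = np.zeros(stim.n_frames)
    for t in range(stim.n_frames):
        acc = 0.0
        for i in range(stim.frames.shape[1]):
            for j in range(stim.frames.shape[2]):
                if stim.frames[t, i, j]:
                    x, y = stim.xgrid[i, j], stim.ygrid[i, j]
                    d2 = (x - params.x0) ** 2 + (y - params.y0) ** 2
                    g = np.exp(-d2 / (2 * params.sigma1**2))
                    if params.model == "DoG":
                        g -= params.amp_surround * np.exp(-d2 / (2 * params.sigma2**2))
                    acc += g
        drive = acc / ppd**2
        if params.exponent != 1.0:
            drive = max(drive, 0.0) ** params.exponent
        out[t] = params.gain * drive
    return out


def make_params(model, **kw):
    base = dict(x0=1.0, y0=-0.5, sigma1=1.2, gain=2.0)
    if model == "DoG":
        base.update(sigma2=3.0, amp_surround=0.4)
    if model == "CSS":
        base.update(exponent=0.5)
    base.update(kw)
    return PRFParams(model, **base)


class TestField:
    def test_peak_value_is_one_at_center(self):
        p = make_params("P-LIN")
        val = prf_field(p, np.array([[p.x0]]), np.array([[p.y0]]))
        assert val[0, 0] == 1.0

    def test_value_at_one_sigma(self):
        p = make_params("P-LIN")
        val = prf_field(p, np.array([[p.x0 + p.sigma1]]), np.array([[p.y0]]))
        assert val[0, 0] == pytest.approx(np.exp(-0.5))

    def test_dog_field_negative_far_from_center(self):
        # with a = 1 and a broad surround the field is negative outside the
        # center lobe, approaching -exp(-d^2 / 2 sigma2^2)
        p = make_params("DoG", sigma1=0.5, sigma2=10.0, amp_surround=1.0)
        x = np.array([[p.x0 + 5.0]])
        y = np.array([[p.y0]])
        val = prf_field(p, x, y)[0, 0]
        assert val < 0
        assert val == pytest.approx(-np.exp(-25.0 / (2 * 100.0)), rel=1e-3)


class TestPredictions:
    @pytest.mark.parametrize("model", MODELS)
    def test_matches_brute_force_oracle(self, model, toy_stim):
        p = make_params(model)
        fast = predict_from_stimulus(p, toy_stim)
        slow = brute_force_response(p, toy_stim)
        np.testing.assert_allclose(fast, slow, rtol=1e-10)

    def test_zero_frame_gives_zero(self, toy_stim):
        zero = np.zeros((1,) + toy_stim.frames.shape[1:], dtype=np.uint8)
        for model in MODELS:
            p = make_params(model)
            pred = predict_response(p, zero, toy_stim.xgrid, toy_stim.ygrid, 1)
            assert pred[0] == 0.0

    def test_css_subadditive_on_disjoint_stimuli(self, toy_stim):
        p = make_params("CSS", x0=0.0, y0=0.0, sigma1=3.0, exponent=0.5)
        xg, yg = toy_stim.xgrid, toy_stim.ygrid
        s1 = (xg < 0).astype(np.uint8)[None]
        s2 = (xg >= 0).astype(np.uint8)[None]
        both = s1 | s2
        r1 = predict_response(p, s1, xg, yg, 1)[0]
        r2 = predict_response(p, s2, xg, yg, 1)[0]
        r12 = predict_response(p, both, xg, yg, 1)[0]
        assert r12 < r1 + r2

    def test_linear_models_additive_on_disjoint_stimuli(self, toy_stim):
        xg, yg = toy_stim.xgrid, toy_stim.ygrid
        s1 = (xg < 0).astype(np.uint8)[None]
        s2 = (xg >= 0).astype(np.uint8)[None]
        for model in ("P-LIN", "U-LIN", "DoG"):
            p = make_params(model, x0=0.5, y0=0.0)
            r1 = predict_response(p, s1, xg, yg, 1)[0]
            r2 = predict_response(p, s2, xg, yg, 1)[0]
            r12 = predict_response(p, (s1 | s2), xg, yg, 1)[0]
            assert r12 == pytest.approx(r1 + r2, rel=1e-12)

    def test_css_with_unit_exponent_equals_plin(self, toy_stim):
        p_css = make_params("CSS", exponent=1.0)
        p_lin = make_params("P-LIN")
        np.testing.assert_array_equal(
            predict_from_stimulus(p_css, toy_stim),
            predict_from_stimulus(p_lin, toy_stim),
        )

    def test_dog_with_zero_surround_equals_plin(self, toy_stim):
        p_dog = make_params("DoG", amp_surround=0.0)
        p_lin = make_params("P-LIN")
        np.testing.assert_allclose(
            predict_from_stimulus(p_dog, toy_stim),
            predict_from_stimulus(p_lin, toy_stim),
            rtol=1e-12,
        )

    def test_distant_prf_response_negligible(self, small_fmri_stim):
        # pRF centered 10 sigma outside every on-pixel responds at < 1e-8 of
        # a well-driven pRF's peak response
        far = PRFParams("P-LIN", x0=18.0, y0=18.0, sigma1=1.0, gain=1.0)
        near = PRFParams("P-LIN", x0=0.0, y0=0.0, sigma1=1.0, gain=1.0)
        r_far = predict_from_stimulus(far, small_fmri_stim)
        r_near = predict_from_stimulus(near, small_fmri_stim)
        assert r_far.max() < 1e-8 * r_near.max()

    def test_prediction_resolution_independent(self):
        from prfmap.stimulus import make_protocol, render_effective_stimulus

        p = make_params("CSS", x0=0.5, y0=-1.0, sigma1=1.5)
        preds = []
        for ppd in (4, 8):
            stim = render_effective_stimulus(
                make_protocol(
                    aperture_diameter=8, bar_width=2, n_steps_per_sweep=9,
                    step_duration=1.0, sweep_directions=(0.0, 90.0),
                    pixels_per_dva=ppd,
                )
            )
            preds.append(predict_from_stimulus(p, stim))
        np.testing.assert_allclose(preds[0], preds[1], rtol=0.05)

    def test_grid_mismatch_raises(self, toy_stim):
        p = make_params("P-LIN")
        with pytest.raises(ValueError, match="grid"):
            predict_response(p, toy_stim.frames, toy_stim.xgrid[:4, :4],
                             toy_stim.ygrid[:4, :4], 1)


class TestSize:
    def test_linear_size_is_sigma(self):
        assert prf_size(make_params("P-LIN", sigma1=2.0))[0] == 2.0

    def test_css_size_matches_fitted_point_response_profile(self):
        # oracle: evaluate the point-stimulus response exp(-d^2/2s^2)^n on a
        # fine 1-D grid and fit a Gaussian to read off its SD
        from scipy.optimize import curve_fit

        sigma, n = 2.0, 0.25
        d = np.linspace(-20, 20, 2001)
        profile = np.exp(-(d**2) / (2 * sigma**2)) ** n
        popt, _ = curve_fit(
            lambda x, s: np.exp(-(x**2) / (2 * s**2)), d, profile, p0=[1.0]
        )
        fitted_sd = abs(popt[0])
        p = make_params("CSS", sigma1=sigma, exponent=n)
        assert prf_size(p)[0] == pytest.approx(sigma / np.sqrt(n), rel=1e-12)
        assert prf_size(p)[0] == pytest.approx(fitted_sd, rel=1e-6)

    def test_dog_reports_center_and_surround(self):
        p = make_params("DoG", sigma1=1.0, sigma2=3.0)
        assert prf_size(p) == (1.0, 3.0)

    def test_normalized_suppression_volume_ratio(self):
        p = make_params("DoG", sigma1=1.0, sigma2=3.0, amp_surround=0.5)
        assert normalized_suppression(p) == pytest.approx(4.5)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(model="P-LIN", x0=0, y0=0, sigma1=-1.0),
            dict(model="DoG", x0=0, y0=0, sigma1=2.0, sigma2=1.0),
            dict(model="DoG", x0=0, y0=0, sigma1=1.0, sigma2=2.0, amp_surround=-0.1),
            dict(model="CSS", x0=0, y0=0, sigma1=1.0, exponent=0.0),
            dict(model="P-LIN", x0=0, y0=0, sigma1=1.0, gain=-1.0),
            dict(model="U-LIN", x0=0, y0=0, sigma1=1.0, exponent=0.5),
            dict(model="GAUSS2", x0=0, y0=0, sigma1=1.0),
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            PRFParams(**kw)

    def test_ulin_negative_gain_allowed(self):
        p = PRFParams("U-LIN", 0.0, 0.0, 1.0, gain=-0.31)
        assert p.gain == -0.31

    def test_record_round_trip(self):
        p = make_params("DoG")
        rec = p.to_record()
        assert rec["ecc"] == pytest.approx(np.hypot(p.x0, p.y0))
        assert PRFParams.from_record(rec) == p

    @given(
        x0=st.floats(-5, 5), y0=st.floats(-5, 5),
        sigma=st.floats(0.2, 4.0), n=st.floats(0.1, 1.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_size_scales_inverse_sqrt_exponent(self, x0, y0, sigma, n):
        p = PRFParams("CSS", x0, y0, sigma, gain=1.0, exponent=n)
        assert prf_size(p)[0] == pytest.approx(sigma / np.sqrt(n), rel=1e-9)
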