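import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddlibs.calibration import (
    EvaluationMetrics,
    baseline_sd,
    cross_validate,
    lod_eq3,
    peak_area,
    peak_height,
    pls_fit,
    pls_predict,
    r_squared_eq2,
    rmse_eq1,
    select_n_factors,
    univariate_fit,
)
from ddlibs.dataset import Spectrum


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

class TestRmse:
    def test_hand_example(self):
        # residuals (1, -1, 0), m = 3: sqrt(2 / 2) = 1
        assert rmse_eq1([1.0, 2.0, 3.0], [0.0, 3.0, 3.0]) == pytest.approx(1.0)

    def test_perfect_prediction(self):
        assert rmse_eq1([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_constant_residual_closed_form(self):
        # residuals all c: |c| * sqrt(m / (m - 1))
        m, c = 7, -0.3
        actual = np.arange(m, dtype=float)
        value = rmse_eq1(actual, actual + c)
        assert value == pytest.approx(abs(c) * math.sqrt(m / (m - 1)))

    def test_m1_denominator_not_m(self):
        # distinguishes the m-1 convention from the usual RMSE
        value = rmse_eq1([0.0, 0.0], [1.0, 1.0])
        assert value == pytest.approx(math.sqrt(2.0))  # not 1.0

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            rmse_eq1([1.0], [1.0])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31), m=st.integers(2, 40))
    def test_matches_brute_force(self, seed, m):
        r = np.random.default_rng(seed)
        a, p = r.standard_normal((2, m))
        brute = math.sqrt(sum((x - y) ** 2 for x, y in zip(a, p)) / (m - 1))
        assert rmse_eq1(a, p) == pytest.approx(brute, abs=1e-12)


class TestRSquared:
    def test_perfect(self):
        assert r_squared_eq2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_is_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert r_squared_eq2(a, np.full(3, a.mean())) == pytest.approx(0.0)

    def test_hand_example(self):
        # SSE = 1, SST = 2 -> 0.5
        assert r_squared_eq2([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_can_be_negative(self):
        assert r_squared_eq2([1.0, 2.0, 3.0], [3.0, 3.0, -2.0]) < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared_eq2([2.0, 2.0], [1.0, 2.0])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31), m=st.integers(3, 40))
    def test_matches_brute_force(self, seed, m):
        r = np.random.default_rng(seed)
        a, p = r.standard_normal((2, m))
        sse = sum((x - y) ** 2 for x, y in zip(a, p))
        sst = sum((x - np.mean(a)) ** 2 for x in a)
        assert r_squared_eq2(a, p) == pytest.approx(1 - sse / sst, abs=1e-12)


class TestLod:
    def test_zero_sd(self):
        assert lod_eq3(0.0, 1.0) == 0.0

    def test_unit_case(self):
        assert lod_eq3(1.0, 3.3) == pytest.approx(1.0)

    def test_arithmetic(self):
        assert lod_eq3(0.5, 5.0) == pytest.approx(0.33)

    def test_zero_slope(self):
        with pytest.raises(ValueError, match="slope"):
            lod_eq3(1.0, 0.0)


class TestEvaluationMetrics:
    def test_rejects_negative_rmse(self):
        with pytest.raises(ValueError):
            EvaluationMetrics(rmsecv=-0.1)

    def test_rejects_r2_above_one(self):
        with pytest.raises(ValueError):
            EvaluationMetrics(r_squared=1.5)


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

class TestPLS:
    def test_exact_single_direction_fit(self, rng):
        # zero-mean orthogonal predictors: the first weight vector points
        # exactly at the informative column, so one factor fits exactly
        raw = rng.standard_normal((20, 6))
        x, _ = np.linalg.qr(raw - raw.mean(axis=0))
        y = 2.0 * x[:, 3] + 1.0
        model = pls_fit(x, y, 1)
        assert np.max(np.abs(model.predict(x) - y)) < 1e-8

    def test_training_residual_nesting(self, rng):
        x = rng.standard_normal((15, 10))
        y = rng.standard_normal(15)
        residuals = []
        for a in range(1, 11):
            m = pls_fit(x, y, a)
            residuals.append(float(np.sum((m.predict(x) - y) ** 2)))
        assert all(r2 <= r1 + 1e-10 for r1, r2 in zip(residuals, residuals[1:]))

    @pytest.mark.parametrize("a", [1, 2, 4])
    def test_matches_reference_implementation(self, rng, a):
        from sklearn.cross_decomposition import PLSRegression

        x = rng.standard_normal((25, 8))
        y = x @ rng.standard_normal(8) + 0.2 * rng.standard_normal(25)
        ours = pls_fit(x, y, a)
        ref = PLSRegression(n_components=a, scale=False).fit(x, y)
        x_new = rng.standard_normal((10, 8))
        np.testing.assert_allclose(
            ours.predict(x_new), ref.predict(x_new).ravel(), atol=1e-6
        )

    def test_factor_bounds(self, rng):
        x = rng.standard_normal((10, 5))
        y = rng.standard_normal(10)
        with pytest.raises(ValueError):
            pls_fit(x, y, 0)
        with pytest.raises(ValueError):
            pls_fit(x, y, 6)  # > p

    def test_degenerate_x(self):
        with pytest.raises(ValueError, match="degenerate"):
            pls_fit(np.ones((5, 3)), np.arange(5.0), 1)

    def test_predict_training_reproduces_fit(self, rng):
        x = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        m = pls_fit(x, y, 2)
        np.testing.assert_allclose(m.predict(x), pls_predict(m, x))

    def test_mean_row_predicts_mean_y(self, rng):
        x = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        m = pls_fit(x, y, 2)
        assert m.predict(x.mean(axis=0)[None, :])[0] == pytest.approx(
            y.mean()
        )

    def test_row_independence(self, rng):
        x = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        m = pls_fit(x, y, 2)
        x_new = rng.standard_normal((5, 4))
        doubled = np.vstack([x_new, x_new[2]])
        preds = m.predict(doubled)
        assert preds[-1] == preds[2]

    def test_dimension_mismatch(self, rng):
        m = pls_fit(rng.standard_normal((10, 4)), rng.standard_normal(10), 1)
        with pytest.raises(ValueError, match="variables"):
            m.predict(rng.standard_normal((3, 5)))


class TestCrossValidate:
    def test_noiseless_linear_loo(self, rng):
        # rank-one predictors: every training subset stays one-component
        t = rng.standard_normal(15)
        x = np.outer(t, rng.uniform(0.5, 2.0, 5))
        y = 3.0 * t - 1.0
        assert cross_validate(x, y, 1, scheme="loo") < 1e-6

    def test_loo_fits_n_models(self, rng, monkeypatch):
        import ddlibs.calibration as cal

        calls = []
        original = cal.pls_fit

        def counting(x, y, a):
            calls.append(x.shape[0])
            return original(x, y, a)

        monkeypatch.setattr(cal, "pls_fit", counting)
        x = rng.standard_normal((9, 4))
        y = rng.standard_normal(9)
        cal.cross_validate(x, y, 1, scheme="loo")
        assert len(calls) == 9
        assert all(c == 8 for c in calls)

    def test_kfold_close_to_loo_on_easy_data(self, rng):
        x = rng.standard_normal((40, 5))
        y = x @ np.array([1.0, 0.5, 0.0, 0.0, 0.0]) + 0.05 * rng.standard_normal(40)
        loo = cross_validate(x, y, 2, scheme="loo")
        kf = cross_validate(x, y, 2, scheme="kfold", k=5, seed=1)
        assert kf == pytest.approx(loo, rel=0.5)

    def test_kfold_deterministic(self, rng):
        x = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        a = cross_validate(x, y, 2, scheme="kfold", k=4, seed=7)
        b = cross_validate(x, y, 2, scheme="kfold", k=4, seed=7)
        assert a == b

    def test_out_of_fold_scoring_leakage_guard(self, rng):
        # duplicating one sample changes loo: its duplicate is in training
        x = rng.standard_normal((12, 4))
        y = x[:, 0] + 0.5 * rng.standard_normal(12)
        base = cross_validate(x, y, 1, scheme="loo")
        x_dup = np.vstack([x, x[0]])
        y_dup = np.append(y, y[0])
        dup = cross_validate(x_dup, y_dup, 1, scheme="loo")
        assert dup != pytest.approx(base, abs=1e-12)

    def test_select_n_factors_prefers_true_rank(self, rng):
        x = rng.standard_normal((30, 8))
        beta = np.zeros(8)
        beta[:2] = [1.0, -1.0]
        y = x @ beta + 0.2 * rng.standard_normal(30)
        best, path = select_n_factors(x, y, max_factors=6)
        assert path.size == 6
        # argmin contract with ties to the smaller count
        assert path[best - 1] == path.min()
        assert best == int(np.argmin(path)) + 1
        # two factors already explain most of what any count explains
        assert path[1] < 2.0 * path.min()


# ---------------------------------------------------------------------------
# peak features
# ---------------------------------------------------------------------------

def _lorentzian_spectrum(center=766.57, fwhm=0.3, amp=100.0, shift=0.0):
    wl = np.linspace(751.90, 774.86, 512)
    it = amp / (1.0 + (2.0 * (wl - center - shift) / fwhm) ** 2)
    return Spectrum(wl, it)


class TestPeakHeight:
    def test_lorentzian_amplitude(self):
        s = _lorentzian_spectrum()
        h = peak_height(s, 766.57, half_width=0.5)
        # grid sampling can miss the apex by at most half a grid step
        step = s.wavelengths[1] - s.wavelengths[0]
        floor = 100.0 / (1.0 + (step / 0.3) ** 2)
        assert floor <= h <= 100.0

    def test_shift_robustness(self):
        h0 = peak_height(_lorentzian_spectrum(), 766.57)
        h1 = peak_height(_lorentzian_spectrum(shift=0.05), 766.57)
        assert h1 == pytest.approx(h0, rel=0.05)

    def test_zero_spectrum(self):
        wl = np.linspace(751.90, 774.86, 512)
        assert peak_height(Spectrum(wl, np.zeros(512)), 766.57) == 0.0

    def test_empty_window(self):
        s = _lorentzian_spectrum()
        with pytest.raises(ValueError, match="no grid points"):
            peak_height(s, 900.0, half_width=0.1)


class TestPeakArea:
    def test_rectangle_pulse(self):
        wl = np.linspace(0.0, 10.0, 1001)
        it = np.where((wl >= 4.0) & (wl <= 6.0), 1.0, 0.0)
        area = peak_area(Spectrum(wl, it), [5.0], half_width=1.5)
        assert area == pytest.approx(2.0, rel=0.02)

    def test_zero_spectrum(self):
        wl = np.linspace(0.0, 10.0, 101)
        assert peak_area(Spectrum(wl, np.zeros(101)), [5.0]) == 0.0

    def test_lorentzian_truncated_closed_form(self):
        # integral over +-L of amp / (1 + (2x/w)^2) = amp * w * arctan(2L/w)
        amp, w = 50.0, 0.4
        s = _lorentzian_spectrum(center=763.0, fwhm=w, amp=amp)
        area = peak_area(s, [763.0], half_width=5 * w)
        expected = amp * w * math.atan(10.0)
        assert area == pytest.approx(expected, rel=0.02)

    def test_overlapping_windows_merged(self):
        s = _lorentzian_spectrum(center=766.57)
        merged = peak_area(s, [766.5, 766.7], half_width=0.5)
        single = peak_area(s, [766.6], half_width=0.6)
        # merged window [766.0, 767.2] equals one window of the same span
        assert merged == pytest.approx(single, rel=1e-6)

    def test_linear_endpoint_baseline_removes_offset(self):
        wl = np.linspace(0.0, 10.0, 1001)
        peak = 1.0 / (1.0 + (2.0 * (wl - 5.0) / 0.5) ** 2)
        tilted = peak + 3.0 + 0.2 * wl
        raw = peak_area(Spectrum(wl, peak), [5.0], half_width=2.0)
        corrected = peak_area(
            Spectrum(wl, tilted), [5.0], half_width=2.0,
            baseline="linear_endpoints",
        )
        # the chord also removes the Lorentzian tail value at the endpoints
        endpoint = 1.0 / (1.0 + (2.0 * 2.0 / 0.5) ** 2)
        assert corrected == pytest.approx(raw - 4.0 * endpoint, rel=0.02)


class TestBaselineSd:
    def test_constant_baseline(self):
        wl = np.linspace(751.90, 774.86, 512)
        s = Spectrum(wl, np.full(512, 7.0))
        assert baseline_sd(s, (755.0, 760.0)) == 0.0

    def test_white_noise_estimate(self, rng):
        wl = np.linspace(0.0, 199.0, 200) + 500.0
        s = Spectrum(wl, rng.normal(0.0, 1.0, 200))
        est = baseline_sd(s, (500.0, 699.0), peak_windows=[])
        assert 0.85 <= est <= 1.15

    def test_overlap_with_peak_window_rejected(self):
        s = _lorentzian_spectrum()
        with pytest.raises(ValueError, match="overlaps"):
            baseline_sd(s, (766.0, 767.0))


class TestUnivariate:
    def test_collinear_r2_one(self):
        m = univariate_fit([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert m.r_squared == pytest.approx(1.0)
        assert m.slope == pytest.approx(2.0)

    def test_constant_y_zero_slope(self):
        m = univariate_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert m.slope == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols(self):
        m = univariate_fit([1.0, 2.0, 3.0], [1.0, 2.0, 2.0])
        assert m.slope == pytest.approx(0.5)
        assert m.r_squared == pytest.approx(0.75)

    def test_degenerate_features(self):
        with pytest.raises(ValueError, match="degenerate"):
            univariate_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_concentration_inversion(self):
        m = univariate_fit([0.4, 0.6, 0.8], [40.0, 60.0, 80.0])
        np.testing.assert_allclose(
            m.predict_concentration([50.0, 70.0]), [0.5, 0.7]
        )
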