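"""Baseline correction, fraction-unfolded curves, derivatives and diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thmap import (
    BaselineError,
    THTrace,
    UndefinedTmError,
    apparent_tm,
    compute_fraction_unfolded,
    fit_baselines,
    hysteresis_diagnostics,
    smooth_derivative,
)
from thmap.preprocess import BaselineModel, FractionCurve

from conftest import make_theta_trace, sigmoid_theta


def ramp_theta(start=35.0, stop=55.0):
    """Piecewise-linear transition: exactly 0 below `start`, 1 above `stop`."""
    return lambda T: np.clip((T - start) / (stop - start), 0.0, 1.0)


def _signal_trace(theta_fn, folded=(0.50, 0.0010), unfolded=(0.80, 0.0008), n=171):
    T = np.linspace(0.0, 85.0, n)
    th = theta_fn(T)
    f = folded[0] + folded[1] * T
    u = unfolded[0] + unfolded[1] * T
    return THTrace(temperature=T, signal=f * (1 - th) + u * th, scan_rate=1.0, direction="melt")


class TestBaselines:
    def test_exact_line_recovered(self):
        trace = _signal_trace(ramp_theta(35, 55))
        bl = fit_baselines(trace, folded_range=(0, 10), unfolded_range=(75, 85))
        assert bl.folded_intercept == pytest.approx(0.50, abs=1e-10)
        assert bl.folded_slope == pytest.approx(0.0010, abs=1e-10)
        assert bl.unfolded_intercept == pytest.approx(0.80, abs=1e-10)
        assert bl.unfolded_slope == pytest.approx(0.0008, abs=1e-10)

    def test_constant_signal_zero_slopes(self):
        T = np.linspace(0, 85, 100)
        trace = THTrace(temperature=T, signal=np.full_like(T, 0.7), scan_rate=1.0, direction="melt")
        bl = fit_baselines(trace)
        assert bl.folded_slope == pytest.approx(0.0, abs=1e-12)
        assert bl.unfolded_slope == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_within_three_standard_errors(self):
        """Monte-Carlo: OLS slope error stays within 3 SE at sigma = 0.002."""
        rng = np.random.default_rng(42)
        T = np.linspace(0.0, 85.0, 171)
        sigma = 0.002
        true_slope = 0.0010
        sel = (T >= 0) & (T <= 12.75)  # lowest 15 % of the span
        x = T[sel] - T[sel].mean()
        se = sigma / np.sqrt((x**2).sum())
        misses = 0
        for _ in range(200):
            sig = 0.50 + true_slope * T + rng.normal(0, sigma, T.size)
            trace = THTrace(temperature=T, signal=sig, scan_rate=1.0, direction="melt")
            bl = fit_baselines(trace)
            if abs(bl.folded_slope - true_slope) > 3 * se:
                misses += 1
        assert misses <= 5  # ~0.3 % expected beyond 3 SE; allow a little slack

    def test_overlapping_ranges_rejected(self):
        trace = _signal_trace(sigmoid_theta())
        with pytest.raises(BaselineError, match="overlap"):
            fit_baselines(trace, folded_range=(0, 50), unfolded_range=(40, 85))

    def test_sparse_range_rejected(self):
        trace = _signal_trace(sigmoid_theta())
        with pytest.raises(BaselineError, match=">= 3"):
            fit_baselines(trace, folded_range=(0.0, 0.6), unfolded_range=(80, 85))


class TestFractionUnfolded:
    def test_midpoint_signal_gives_half(self):
        trace = _signal_trace(ramp_theta(35, 55))
        bl = fit_baselines(trace, (0, 10), (75, 85))
        theta = compute_fraction_unfolded(trace, bl).theta_U
        i = np.argmin(np.abs(trace.temperature - 45.0))
        assert theta[i] == pytest.approx(0.5, abs=1e-6)

    def test_signal_on_folded_line_gives_zero(self):
        trace = _signal_trace(lambda T: np.zeros_like(T))
        bl = BaselineModel(0.50, 0.0010, 0.80, 0.0008, (0, 10), (75, 85))
        theta = compute_fraction_unfolded(trace, bl).theta_U
        np.testing.assert_allclose(theta, 0.0, atol=1e-12)

    def test_roundtrip_matches_generator_theta(self):
        theta_fn = ramp_theta(30, 60)
        trace = _signal_trace(theta_fn)
        bl = fit_baselines(trace, (0, 10), (75, 85))
        theta = compute_fraction_unfolded(trace, bl).theta_U
        # baselines are exact on a noiseless trace, so theta is the input theta
        assert np.max(np.abs(theta - theta_fn(trace.temperature))) < 1e-9

    def test_intersecting_baselines_rejected(self):
        trace = _signal_trace(sigmoid_theta())
        bad = BaselineModel(0.50, 0.010, 0.80, -0.010, (0, 10), (75, 85))
        with pytest.raises(BaselineError, match="intersect"):
            compute_fraction_unfolded(trace, bad)

    @given(a=st.floats(0.1, 5.0), b=st.floats(-1.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_signal_invariance(self, a, b):
        """theta_U is unchanged by signal -> a*signal + b with matching baselines."""
        theta_fn = sigmoid_theta(tm=45, width=3)
        trace = _signal_trace(theta_fn)
        bl = BaselineModel(0.50, 0.0010, 0.80, 0.0008, (0, 10), (75, 85))
        bl2 = BaselineModel(
            a * 0.50 + b, a * 0.0010, a * 0.80 + b, a * 0.0008, (0, 10), (75, 85)
        )
        t2 = trace.with_signal(a * trace.signal + b)
        th1 = compute_fraction_unfolded(trace, bl).theta_U
        th2 = compute_fraction_unfolded(t2, bl2).theta_U
        np.testing.assert_allclose(th1, th2, atol=1e-9)


class TestSmoothDerivative:
    def test_linear_theta_exact_derivative(self):
        trace = make_theta_trace(lambda T: 0.01 * T + 0.2, lo=20, hi=70, n=101)
        curve = smooth_derivative(FractionCurve.from_trace(trace, trace.signal))
        np.testing.assert_allclose(curve.dtheta_dT, 0.01, atol=1e-12)

    def test_quadratic_exact_for_polyorder_two(self):
        # sample on the resampling grid itself so interpolation is exact
        trace = make_theta_trace(lambda T: 1e-4 * T**2, lo=20, hi=70, n=101)
        curve = smooth_derivative(FractionCurve.from_trace(trace, trace.signal), polyorder=2)
        np.testing.assert_allclose(curve.dtheta_dT, 2e-4 * curve.temperature, rtol=1e-8)

    def test_noisy_sigmoid_derivative_close_to_truth(self):
        rng = np.random.default_rng(3)
        T = np.linspace(10, 80, 281)
        theta = sigmoid_theta(tm=45, width=4)(T)
        noisy = theta + rng.normal(0, 0.002, T.size)
        trace = THTrace(temperature=T, signal=noisy, scan_rate=1.0, direction="melt")
        curve = smooth_derivative(FractionCurve.from_trace(trace, trace.signal), window=2.5)
        truth = sigmoid_theta(tm=45, width=4)
        d_true = (truth(curve.temperature + 1e-4) - truth(curve.temperature - 1e-4)) / 2e-4
        rms = np.sqrt(np.mean((curve.dtheta_dT - d_true) ** 2))
        assert rms < 0.05 * np.max(np.abs(d_true))

    def test_window_exceeding_span_rejected(self):
        trace = make_theta_trace(sigmoid_theta(), lo=49, hi=51, n=20)
        from thmap import THDataError

        with pytest.raises(THDataError, match="window"):
            smooth_derivative(FractionCurve.from_trace(trace, trace.signal), window=10.0)


class TestTemperatureLag:
    def test_signed_correction_and_zero_default(self):
        from thmap import correct_temperature_lag

        melt = make_theta_trace(sigmoid_theta(), "melt", scan_rate=2.0)
        anneal = make_theta_trace(sigmoid_theta(), "anneal", scan_rate=2.0)
        lam = 0.1  # minutes of sample lag behind the block
        np.testing.assert_allclose(
            correct_temperature_lag(melt, lam).temperature, melt.temperature - 0.2
        )
        np.testing.assert_allclose(
            correct_temperature_lag(anneal, lam).temperature, anneal.temperature + 0.2
        )
        assert correct_temperature_lag(melt, 0.0) is melt


class TestApparentTm:
    def test_linear_interpolation_between_grid_points(self):
        curve = FractionCurve(
            temperature=np.array([45.0, 46, 47, 48, 49, 50, 51, 52, 53, 54.0]),
            theta_U=np.array([0.0, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 0.9, 0.95, 1.0]),
        )
        assert apparent_tm(curve) == pytest.approx(49.5)

    def test_no_crossing_is_error(self):
        curve = FractionCurve(temperature=np.linspace(0, 10, 11), theta_U=np.full(11, 0.2))
        with pytest.raises(UndefinedTmError):
            apparent_tm(curve)


class TestHysteresisDiagnostics:
    def test_identical_curves_inadequate(self):
        theta = sigmoid_theta(tm=50, width=3)
        melt = smooth_derivative(
            FractionCurve.from_trace(make_theta_trace(theta, "melt"), make_theta_trace(theta, "melt").signal)
        )
        anneal = smooth_derivative(
            FractionCurve.from_trace(
                make_theta_trace(theta, "anneal"), make_theta_trace(theta, "anneal").signal
            )
        )
        report = hysteresis_diagnostics([melt, anneal])
        assert report.tm_shift == pytest.approx(0.0, abs=1e-9)
        assert not report.adequate

    def test_threshold_semantics(self):
        """Shift 0.99 °C inadequate; 1.01 °C with slope ratio >= 3 adequate."""

        def curves(shift, anneal_width, melt_width=3.0):
            melt_t = make_theta_trace(sigmoid_theta(tm=50 + shift, width=melt_width), "melt")
            ann_t = make_theta_trace(sigmoid_theta(tm=50, width=anneal_width), "anneal")
            return [
                smooth_derivative(FractionCurve.from_trace(melt_t, melt_t.signal)),
                smooth_derivative(FractionCurve.from_trace(ann_t, ann_t.signal)),
            ]

        # narrow anneal => steep anneal slope => ratio >= 3 where melt is flat
        report = hysteresis_diagnostics(curves(1.01, anneal_width=0.8, melt_width=4.0))
        assert report.adequate
        report = hysteresis_diagnostics(curves(0.99, anneal_width=0.8, melt_width=4.0))
        assert not report.adequate

    def test_simulated_hysteretic_tetramer_adequate(self, tetramer_dataset):
        from thmap import preprocess_dataset

        curves = preprocess_dataset(tetramer_dataset, signal_is_theta=True)
        report = hysteresis_diagnostics(curves)
        assert report.adequate
        assert report.tm_shift >= 1.0 and report.slope_ratio >= 3.0
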