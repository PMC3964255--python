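"""Per-curve fitting: starts, round-trip recovery, goodness indicator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from maekin.estimators import (DegenerateDataError, DelayedLogisticExtraction,
                               FirstOrderExtraction)
from maekin.fitting import (ExtractionCurve, InsufficientDataError, fit_curve,
                            gof_ratio, initial_guess)
from maekin.models import (FirstOrderParams, LogisticParams,
                           first_order_yield, logistic_yield)


def _curve(times, yields, factor="power", level=550.0):
    return ExtractionCurve(factor, level, np.asarray(times, float),
                           np.asarray(yields, float))


class TestExtractionCurve:
    def test_rejects_nonincreasing_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _curve([1, 5, 5, 10], [0, 1, 2, 3])

    def test_rejects_negative_yields(self):
        with pytest.raises(ValueError, match=">= 0"):
            _curve([1, 5, 10], [0.1, -0.2, 0.3])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="equally long"):
            _curve([1, 5], [0.1, 0.2, 0.3])


class TestInitialGuess:
    def test_logistic_delay_guess_within_one_grid_step(self, time_grid,
                                                       logistic_550):
        curve = _curve(time_grid, logistic_yield(time_grid, logistic_550))
        guess = initial_guess(curve, "logistic")
        step = np.max(np.diff(time_grid))
        assert abs(guess.tau - logistic_550.tau) <= step

    def test_all_zero_curve_is_degenerate(self, time_grid):
        curve = _curve(time_grid, np.zeros_like(time_grid))
        with pytest.raises(DegenerateDataError):
            initial_guess(curve, "first_order")

    def test_monotone_curve_asymptote_guess_is_last_point(self, time_grid,
                                                          first_order_550):
        y = first_order_yield(time_grid, first_order_550)
        guess = initial_guess(_curve(time_grid, y), "first_order")
        assert guess.y_max == y[-1]


class TestRoundTripRecovery:
    def test_first_order_reference_row(self, time_grid, first_order_550):
        y = first_order_yield(time_grid, first_order_550)
        fit = fit_curve(_curve(time_grid, y), "first_order")
        assert fit.params.y_max == pytest.approx(first_order_550.y_max, rel=1e-6)
        assert fit.params.k_m == pytest.approx(first_order_550.k_m, rel=1e-6)
        assert fit.gof < 1e-8
        assert fit.converged

    def test_logistic_reference_row(self, time_grid, logistic_550):
        y = logistic_yield(time_grid, logistic_550)
        fit = fit_curve(_curve(time_grid, y), "logistic")
        assert fit.params.y_max == pytest.approx(logistic_550.y_max, rel=1e-6)
        assert fit.params.k_m == pytest.approx(logistic_550.k_m, rel=1e-6)
        assert fit.params.tau == pytest.approx(logistic_550.tau, rel=1e-6)
        assert fit.gof < 1e-8

    def test_single_point_curve_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_curve(_curve([10.0], [0.5]), "first_order")

    def test_minimum_point_counts(self, time_grid, logistic_550):
        y = logistic_yield(time_grid, logistic_550)
        with pytest.raises(InsufficientDataError):
            fit_curve(_curve(time_grid[:4], y[:4]), "logistic")
        with pytest.raises(InsufficientDataError):
            fit_curve(_curve(time_grid[:3], y[:3]), "first_order")

    def test_explicit_init_is_honoured(self, time_grid, logistic_550):
        y = logistic_yield(time_grid, logistic_550)
        init = LogisticParams(0.5, 0.2, 20.0)
        fit = fit_curve(_curve(time_grid, y), "logistic", init=init)
        assert fit.params.y_max == pytest.approx(logistic_550.y_max, rel=1e-6)


def test_determinism_bit_identical(time_grid, logistic_550, rng):
    """Identical inputs and tolerances give bit-identical results."""
    y = np.clip(logistic_yield(time_grid, logistic_550)
                + rng.normal(0, 0.01, time_grid.shape), 0, None)
    a = fit_curve(_curve(time_grid, y), "logistic")
    b = fit_curve(_curve(time_grid, y), "logistic")
    assert a.params == b.params
    assert a.rms == b.rms and a.gof == b.gof and a.n_iter == b.n_iter


def test_small_curve_objective_matches_grid_search(rng):
    """On a 6-point curve the optimizer is at least as good as an exhaustive
    grid search over a parameter bounding box (the brute-force oracle)."""
    times = np.array([2.0, 10.0, 25.0, 45.0, 70.0, 110.0])
    truth = FirstOrderParams(0.8, 0.06)
    y = first_order_yield(times, truth) + rng.normal(0, 0.02, times.shape)
    y = np.clip(y, 0, None)
    fit = fit_curve(_curve(times, y), "first_order")
    sse_fit = len(times) * fit.rms ** 2

    y_grid = np.linspace(0.4, 1.2, 161)
    k_grid = np.linspace(0.01, 0.2, 191)
    sse = np.array([[np.sum((ym * -np.expm1(-k * times) - y) ** 2)
                     for k in k_grid] for ym in y_grid])
    assert sse_fit <= sse.min() + 1e-9


def test_stochastic_parameter_recovery(time_grid, logistic_550):
    """200 noisy replicates at the 550 W truth: median relative parameter
    error < 5% and the mean goodness indicator brackets the published ~0.02."""
    rng = np.random.default_rng(550)
    errs, gofs = [], []
    truth = np.array([logistic_550.y_max, logistic_550.k_m, logistic_550.tau])
    clean = logistic_yield(time_grid, logistic_550)
    for _ in range(200):
        y = np.clip(clean + rng.normal(0, 0.01, time_grid.shape), 0, None)
        fit = fit_curve(_curve(time_grid, y), "logistic")
        est = np.array([fit.params.y_max, fit.params.k_m, fit.params.tau])
        errs.append(np.abs(est - truth) / truth)
        gofs.append(fit.gof)
    med = np.median(np.vstack(errs), axis=0)
    assert np.all(med < 0.05), med
    assert 0.01 <= np.mean(gofs) <= 0.04


class TestGofRatio:
    def test_zero_rms_is_perfect(self):
        assert gof_ratio(0.0, 0.5) == 0.0

    def test_rms_equal_to_asymptote_is_one(self):
        assert gof_ratio(0.5, 0.5) == 1.0

    def test_hand_summed_residual_vector(self):
        resid = np.array([0.01, -0.01, 0.02, 0.0, -0.02])
        rms = float(np.sqrt(np.mean(resid ** 2)))
        # brute-force mean of squares: (1+1+4+0+4)e-4 / 5 = 2e-4
        assert rms == pytest.approx(0.014142135623730950, rel=1e-14)
        assert gof_ratio(rms, 0.5) == pytest.approx(0.0282842712474619,
                                                    rel=1e-14)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            gof_ratio(0.1, 0.0)
        with pytest.raises(ValueError):
            gof_ratio(-0.1, 1.0)

    @given(c=st.floats(1e-6, 1e6), rms=st.floats(0, 10.0),
           y_max=st.floats(1e-6, 1e3))
    def test_scale_invariance(self, c, rms, y_max):
        assert gof_ratio(c * rms, c * y_max) == pytest.approx(
            gof_ratio(rms, y_max), rel=1e-9)


def test_estimator_sklearn_contract(time_grid, logistic_550):
    """get_params/set_params round trip and predict after fit."""
    est = DelayedLogisticExtraction(tol=1e-10, max_iter=500)
    params = est.get_params()
    assert params["tol"] == 1e-10
    est.set_params(max_iter=300)
    assert est.get_params()["max_iter"] == 300
    y = logistic_yield(time_grid, logistic_550)
    est.fit(time_grid, y)
    np.testing.assert_allclose(est.predict(time_grid), y, atol=1e-8)
    assert est.covariance_.shape == (3, 3)


def test_sklearn_clone_compatible():
    from sklearn.base import clone
    est = FirstOrderExtraction(tol=1e-8, multistart=True, random_state=3)
    cl = clone(est)
    assert cl.get_params() == est.get_params()


def test_multistart_matches_single_start_on_clean_data(time_grid,
                                                       logistic_550):
    y = logistic_yield(time_grid, logistic_550)
    single = fit_curve(_curve(time_grid, y), "logistic")
    multi = fit_curve(_curve(time_grid, y), "logistic", multistart=True,
                      random_state=0)
    assert multi.params.y_max == pytest.approx(single.params.y_max, rel=1e-8)
    assert multi.params.k_m == pytest.approx(single.params.k_m, rel=1e-8)
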