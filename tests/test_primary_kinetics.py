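import numpy as np
import pytest

from aslt.errors import ValidationError
from aslt.primary_kinetics import (
    fit_first_order,
    fit_weibull,
    fit_zero_order,
    select_primary_model,
)
from aslt.study_data import DegradationSeries, normalize_retention


def series_from(times, conc, T=35.0):
    return DegradationSeries(T, np.asarray(times, float), np.asarray(conc, float))


def pearson_r2(x, y):
    """Independent oracle: squared Pearson correlation from raw moments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    return sxy**2 / (np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))


def weibull_grid_oracle(t, y, b_range=(1e-4, 1.0), n_range=(0.05, 2.0)):
    """Dense grid search + local polish, independent of the fitting path."""
    from scipy.optimize import minimize

    best = None
    for b in np.geomspace(*b_range, 200):
        for n in np.linspace(*n_range, 150):
            sse = float(np.sum((y - np.exp(-b * t**n)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, b, n)
    res = minimize(
        lambda p: float(np.sum((y - np.exp(-p[0] * t ** p[1])) ** 2)),
        [best[1], best[2]],
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 5000},
    )
    return res.x


class TestZeroOrder:
    def test_exact_line_recovered(self):
        t = np.arange(6.0)
        s = series_from(t, 100 - 2 * t)
        fit = fit_zero_order(s)
        assert fit.k1 == pytest.approx(2.0, abs=1e-12)
        assert fit.c0 == pytest.approx(100.0, abs=1e-10)
        assert fit.metrics.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_zero_rate(self):
        fit = fit_zero_order(series_from([0, 1, 2, 3], [50] * 4))
        assert fit.k1 == 0.0

    def test_reference_regression_coefficients_recovered(self):
        # exact data from the camu camu 35 degC zero-order line
        t = np.arange(0.0, 22.0, 3.0)
        fit = fit_zero_order(series_from(t, 1024.5 - 8.8722 * t))
        assert fit.k1 == pytest.approx(8.8722, abs=1e-9)
        assert fit.c0 == pytest.approx(1024.5, abs=1e-9)

    def test_r2_equals_squared_pearson_oracle(self, weibull_series):
        s = weibull_series()
        fit = fit_zero_order(s)
        assert fit.metrics.r2 == pytest.approx(
            pearson_r2(s.times, s.concentrations), abs=1e-12
        )

    def test_increasing_series_flagged_non_degrading(self):
        fit = fit_zero_order(series_from([0, 1, 2, 3], [10, 11, 12, 13]))
        assert fit.non_degrading


class TestFirstOrder:
    def test_exact_exponential_recovered(self):
        t = np.arange(8.0)
        fit = fit_first_order(series_from(t, 200 * np.exp(-0.1 * t)))
        assert fit.k2 == pytest.approx(0.1, abs=1e-12)
        assert fit.metrics.r2 == pytest.approx(1.0, abs=1e-12)

    def test_reference_log_line_recovered(self):
        # exact data from the camu camu 35 degC first-order line
        t = np.arange(0.0, 22.0, 3.0)
        fit = fit_first_order(series_from(t, np.exp(6.9313 - 0.0093 * t)))
        assert fit.k2 == pytest.approx(0.0093, abs=1e-9)
        assert np.log(fit.c0) == pytest.approx(6.9313, abs=1e-9)

    def test_r2_matches_pearson_on_log_scale(self, weibull_series):
        s = weibull_series()
        fit = fit_first_order(s)
        assert fit.metrics.r2 == pytest.approx(
            pearson_r2(s.times, np.log(s.concentrations)), abs=1e-12
        )


class TestWeibull:
    def test_reference_parameters_recovered_from_noiseless_data(self, weibull_series):
        s = weibull_series(b=0.07695, n=0.36305)
        fit = fit_weibull(s)
        assert fit.b == pytest.approx(0.07695, abs=1e-6)
        assert fit.n == pytest.approx(0.36305, abs=1e-6)
        assert fit.metrics.r2 == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_grid_oracle(self, weibull_series):
        rng = np.random.default_rng(3)
        s = weibull_series(b=0.05, n=0.5)
        noisy = DegradationSeries(
            s.temperature_c,
            s.times,
            s.concentrations * (1 + np.concatenate([[0], rng.normal(0, 0.01, 7)])),
        )
        fit = fit_weibull(noisy)
        ret = normalize_retention(noisy)
        b_o, n_o = weibull_grid_oracle(ret.times[1:], ret.retention[1:])
        assert fit.b == pytest.approx(b_o, rel=1e-4)
        assert fit.n == pytest.approx(n_o, rel=1e-4)

    def test_pure_exponential_gives_unit_shape(self):
        t = np.arange(6.0)
        fit = fit_weibull(series_from(t, 100 * np.exp(-t)))
        assert fit.b == pytest.approx(1.0, abs=1e-8)
        assert fit.n == pytest.approx(1.0, abs=1e-8)

    def test_predicted_retention_matches_measured_endpoint(self):
        # Weibull curve at the 35 degC reference parameters vs the measured
        # day-21 retention 863.54/1090.17
        y21 = np.exp(-0.07695 * 21**0.36305)
        assert y21 == pytest.approx(863.54 / 1090.17, abs=1e-3)

    @pytest.mark.parametrize("scale", [0.01, 100.0])
    def test_invariant_to_concentration_rescaling(self, weibull_series, scale):
        s = weibull_series(b=0.1, n=0.7)
        fit1 = fit_weibull(s)
        fit2 = fit_weibull(
            DegradationSeries(s.temperature_c, s.times, s.concentrations * scale)
        )
        assert fit1.b == pytest.approx(fit2.b, rel=1e-10)
        assert fit1.n == pytest.approx(fit2.n, rel=1e-10)

    def test_nests_first_order_on_retention(self):
        # Weibull with free n can never fit retention worse than exp(-kt)
        rng = np.random.default_rng(11)
        for _ in range(50):
            b = rng.uniform(0.01, 0.3)
            n = rng.uniform(0.2, 1.5)
            t = np.arange(0.0, 22.0, 3.0)
            y = np.exp(-b * t**n) + np.concatenate([[0], rng.normal(0, 0.01, 7)])
            y = np.clip(y, 1e-6, None)
            y[0] = 1.0
            s = DegradationSeries(35.0, t, 100 * y)
            wfit = fit_weibull(s)
            sse_w = wfit.metrics.mse * 7
            # best exp(-kt) on the same retention points: OLS on log scale is
            # not the LS optimum, so use a 1-d scan for the oracle
            ks = np.linspace(1e-4, 2.0, 4000)
            sse_f = min(
                float(np.sum((y[1:] - np.exp(-k * t[1:])) ** 2)) for k in ks
            )
            assert sse_w <= sse_f + 1e-10


class TestModelSelection:
    def test_argmax_r2(self, weibull_series):
        s = weibull_series(b=0.07695, n=0.36305)
        fits = [fit_zero_order(s), fit_first_order(s), fit_weibull(s)]
        assert select_primary_model(fits).model == "weibull"

    def test_tie_prefers_simpler_model(self):
        # noiseless exponential: first-order and Weibull both fit exactly
        t = np.arange(6.0)
        s = series_from(t, 100 * np.exp(-0.1 * t))
        fits = [fit_first_order(s), fit_weibull(s)]
        assert select_primary_model(fits).model == "first"

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            select_primary_model([])


class TestValidation:
    def test_degenerate_time_grid_rejected(self):
        # bypass the container's own grid check to exercise the fitter's guard
        s = DegradationSeries.__new__(DegradationSeries)
        object.__setattr__(s, "temperature_c", 35.0)
        object.__setattr__(s, "times", np.array([0.0, 0.0, 0.0]))
        object.__setattr__(s, "concentrations", np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValidationError, match="degenerate"):
            fit_zero_order(s)
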