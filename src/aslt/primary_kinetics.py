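"""Primary degradation models fitted per storage temperature.

Three model families describe an isothermal concentration-time trajectory:

* zero-order:   C(t) = C0 - k1 t          (linear in C)
* first-order:  ln C(t) = ln C0 - k2 t    (linear in ln C)
* Weibull:      Y(t) = C(t)/C0 = exp(-b t^n)

The Weibull family is a survival-type decay: ``b`` (day^-n) is a rate-like
scale parameter, ``n`` a dimensionless shape parameter. With n = 1 it
reduces to first-order decay; n < 1 means the apparent degradation rate
slows over storage time (initial rapid loss, then stabilization), the
pattern typical of vitamin C in complex juice matrices.

The best model per temperature is selected by the coefficient of
determination R^2; near-ties go to the simpler family.

Goodness-of-fit conventions, applied uniformly:

* MSE = SSE / (number of fitted points), no degrees-of-freedom correction;
  RMSE = sqrt(MSE).
* For the linear fits, R^2 is the squared Pearson correlation of the
  response with time (equivalently 1 - SSE/SST for OLS).
* For the Weibull fit, R^2 = 1 - SSE/SST with SST about the mean fitted
  retention. The t = 0 point has a structurally zero residual (Y(0) = 1 by
  construction, C0 is not a free parameter), so it is excluded from both
  SSE and SST to avoid inflating R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import optimize, stats

from .errors import FitFailureError, ValidationError
from .study_data import DegradationSeries, RetentionSeries, normalize_retention

#: bounds for the Weibull scale and shape parameters
WEIBULL_B_BOUNDS = (1e-8, 10.0)
WEIBULL_N_BOUNDS = (0.01, 5.0)

#: models ordered by complexity (kinetic parameter count) for tie-breaking
_COMPLEXITY = {"zero": 1, "first": 1, "weibull": 2}
_TIE_R2 = 1e-4


@dataclass(frozen=True)
class FitMetrics:
    """R^2, MSE and RMSE of a fit on its response scale."""

    r2: float
    mse: float
    rmse: float

    def __post_init__(self):
        if self.mse < 0:
            raise ValidationError(f"mse must be >= 0, got {self.mse}")
        if abs(self.rmse - sqrt(self.mse)) > 1e-12 * max(1.0, self.rmse):
            raise ValidationError("rmse must equal sqrt(mse)")


@dataclass(frozen=True)
class PrimaryFit:
    """A fitted primary model at one temperature.

    Exactly one parameter set is populated depending on ``model``: ``k1``
    (mg/100 mL/day) for zero-order, ``k2`` (1/day) for first-order, or
    ``(b, n)`` for Weibull. ``c0`` is the fitted intercept for the linear
    models and the measured time-0 concentration for Weibull.
    ``non_degrading`` flags series whose overall trend increases —
    fits still run but downstream shelf-life math is meaningless there.
    """

    model: str
    temperature_c: float
    c0: float
    metrics: FitMetrics
    response_scale: str
    k1: float | None = None
    k2: float | None = None
    b: float | None = None
    n: float | None = None
    non_degrading: bool = False

    def predict_concentration(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        if self.model == "zero":
            return self.c0 - self.k1 * t
        if self.model == "first":
            return self.c0 * np.exp(-self.k2 * t)
        return self.c0 * np.exp(-self.b * t**self.n)

    def predict_retention(self, times) -> np.ndarray:
        return self.predict_concentration(times) / self.c0


def _linear_fit(t: np.ndarray, y: np.ndarray):
    """OLS of y on t; returns slope, intercept, r2 (squared Pearson), sse."""
    if np.ptp(t) == 0:
        raise ValidationError("degenerate design: all times equal")
    res = stats.linregress(t, y)
    fitted = res.intercept + res.slope * t
    sse = float(np.sum((y - fitted) ** 2))
    return res.slope, res.intercept, float(res.rvalue**2), sse


def _is_non_degrading(series: DegradationSeries) -> bool:
    slope, *_ = _linear_fit(series.times, series.concentrations)
    return slope > 0


def fit_zero_order(series: DegradationSeries) -> PrimaryFit:
    """Fit C(t) = C0 - k1 t by ordinary least squares of C on t."""
    t, c = series.times, series.concentrations
    slope, intercept, r2, sse = _linear_fit(t, c)
    mse = sse / t.size
    return PrimaryFit(
        model="zero",
        temperature_c=series.temperature_c,
        c0=float(intercept),
        k1=float(-slope),
        metrics=FitMetrics(r2=r2, mse=mse, rmse=sqrt(mse)),
        response_scale="concentration",
        non_degrading=slope > 0,
    )


def fit_first_order(series: DegradationSeries) -> PrimaryFit:
    """Fit ln C(t) = ln C0 - k2 t by OLS of ln C on t."""
    t = series.times
    logc = np.log(series.concentrations)
    slope, intercept, r2, sse = _linear_fit(t, logc)
    mse = sse / t.size
    return PrimaryFit(
        model="first",
        temperature_c=series.temperature_c,
        c0=float(np.exp(intercept)),
        k2=float(-slope),
        metrics=FitMetrics(r2=r2, mse=mse, rmse=sqrt(mse)),
        response_scale="log-concentration",
        non_degrading=slope > 0,
    )


def _weibull_retention(t, b, n):
    return np.exp(-b * t**n)


def _retention_metrics(t_pos, y_pos, b, n) -> FitMetrics:
    resid = y_pos - _weibull_retention(t_pos, b, n)
    sse = float(resid @ resid)
    sst = float(np.sum((y_pos - y_pos.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse < 1e-20 else 0.0)
    mse = sse / t_pos.size
    return FitMetrics(r2=r2, mse=mse, rmse=sqrt(mse))


def fit_weibull(series: DegradationSeries | RetentionSeries) -> PrimaryFit:
    """Fit the Weibull retention model Y(t) = exp(-b t^n) per temperature.

    The series is normalized so Y(0) = 1 with C0 fixed to the measured
    time-0 value; the sum of squared retention residuals over the t > 0
    points is minimized by bounded nonlinear least squares. The starting
    point is (b = k2 from a first-order pre-fit floored at 1e-4, n = 1);
    if the local solver fails, a log-spaced (b, n) grid multi-start refines
    the best cell.
    """
    if isinstance(series, RetentionSeries):
        ret = series
        c0 = 1.0
        non_degrading = ret.retention[-1] > ret.retention[0]
    else:
        ret = normalize_retention(series)
        c0 = series.c0
        non_degrading = _is_non_degrading(series)

    t_pos = ret.times[1:]
    y_pos = ret.retention[1:]

    # first-order pre-fit on retention gives the rate-scale starting value
    k2_init = max(-_linear_fit(t_pos, np.log(y_pos))[0], 1e-4)
    b0 = float(np.clip(k2_init, *WEIBULL_B_BOUNDS))

    lo = (WEIBULL_B_BOUNDS[0], WEIBULL_N_BOUNDS[0])
    hi = (WEIBULL_B_BOUNDS[1], WEIBULL_N_BOUNDS[1])

    def resid(p):
        return _weibull_retention(t_pos, p[0], p[1]) - y_pos

    def solve(x0):
        return optimize.least_squares(
            resid, x0, bounds=(lo, hi), ftol=1e-10, xtol=1e-12, gtol=1e-10
        )

    best = solve([b0, 1.0])
    if not best.success or not np.isfinite(best.cost):
        best = None

    # grid multi-start: either the local solve failed, or we accept it
    if best is None:
        b_grid = np.geomspace(1e-4, 5.0, 12)
        n_grid = np.geomspace(0.05, 4.0, 10)
        cand = None
        for bg in b_grid:
            for ng in n_grid:
                r = resid([bg, ng])
                sse = float(r @ r)
                if cand is None or sse < cand[0]:
                    cand = (sse, bg, ng)
        refined = solve([cand[1], cand[2]])
        if not refined.success:
            raise FitFailureError(
                "Weibull fit failed to converge after grid multi-start",
                best_params=tuple(refined.x),
                best_sse=2 * float(refined.cost),
            )
        best = refined

    b_hat, n_hat = float(best.x[0]), float(best.x[1])
    return PrimaryFit(
        model="weibull",
        temperature_c=ret.temperature_c,
        c0=c0,
        b=b_hat,
        n=n_hat,
        metrics=_retention_metrics(t_pos, y_pos, b_hat, n_hat),
        response_scale="retention",
        non_degrading=non_degrading,
    )


def fit_all_primary(series: DegradationSeries) -> list[PrimaryFit]:
    """Fit all three primary models to one series."""
    return [fit_zero_order(series), fit_first_order(series), fit_weibull(series)]


def select_primary_model(fits: list[PrimaryFit]) -> PrimaryFit:
    """Pick the fit with the highest R^2; ties within 1e-4 go to the model
    with fewer kinetic parameters (zero/first before Weibull)."""
    if not fits:
        raise ValueError("no fits to select from")
    best_r2 = max(f.metrics.r2 for f in fits)
    contenders = [f for f in fits if best_r2 - f.metrics.r2 <= _TIE_R2]
    return min(contenders, key=lambda f: (_COMPLEXITY[f.model], -f.metrics.r2))
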