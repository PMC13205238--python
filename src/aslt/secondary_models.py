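"""Secondary models: temperature dependence of a kinetic quantity.

Two parameterizations of how a positive quantity q (the Weibull scale
parameter b, or a shelf life t80) varies with storage temperature:

* Arrhenius: q(T) = q0 exp(-Ea / (R (T + 273.15))), fitted as OLS of
  ln q on reciprocal absolute temperature. The slope gives the activation
  energy Ea (kJ/mol) — the sensitivity of the quantity to temperature.
  For a rate-like quantity that grows with temperature the slope is
  negative and Ea = -slope * R; for a shelf life, which shrinks with
  temperature, the orientation flips and Ea = +slope * R.

* Log-logistic (Corradini & Peleg): b(T) = ln(1 + exp(k3 (T - Tc))),
  a smooth activation curve in Celsius with characteristic temperature Tc
  and sensitivity constant k3, fitted by bounded nonlinear least squares.

With the typical accelerated-storage design of only three temperature
levels, either secondary fit has one residual degree of freedom; fits
carry ``n_points`` so consumers can flag low-confidence extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, sqrt

import numpy as np
from scipy import optimize, stats

from .errors import FitFailureError, ValidationError
from .primary_kinetics import FitMetrics

#: universal gas constant, J/(mol K)
R_GAS = 8.314

KELVIN_OFFSET = 273.15

LOGLOGISTIC_K3_BOUNDS = (1e-4, 5.0)
LOGLOGISTIC_TC_BOUNDS = (-50.0, 300.0)


@dataclass(frozen=True)
class ArrheniusFit:
    """OLS of ln(q) on 1/(T + 273.15).

    ``ea_kj_mol`` is -slope*R/1000 for orientation ``"rate"`` and
    +slope*R/1000 for ``"shelf_life"``; ``pre_exponential`` is
    exp(intercept) on the q scale. ``se_ea_kj_mol`` is the OLS slope
    standard error scaled by R (dof = n - 2), absent when n == 2.
    """

    slope: float
    intercept: float
    orientation: str
    ea_kj_mol: float
    pre_exponential: float
    r2: float
    n_points: int
    se_ea_kj_mol: float | None = None


@dataclass(frozen=True)
class LogLogisticFit:
    """Fitted b(T) = ln(1 + exp(k3 (T - Tc))) with metrics on the b scale."""

    k3: float
    tc: float
    metrics: FitMetrics
    n_points: int


def fit_arrhenius(points, orientation: str = "rate") -> ArrheniusFit:
    """Fit ln(q) = intercept + slope / (T + 273.15) to (temperature_c, q) pairs.

    Parameters
    ----------
    points : sequence of (float, float)
        Temperature in Celsius paired with a positive quantity.
    orientation : {"rate", "shelf_life"}
        Sign convention for the activation energy (see module docstring).
    """
    if orientation not in ("rate", "shelf_life"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    pts = [(float(T), float(q)) for T, q in points]
    if len(pts) < 2:
        raise ValidationError(f"need >= 2 points, got {len(pts)}")
    temps = np.array([T for T, _ in pts])
    qs = np.array([q for _, q in pts])
    if len(set(temps.tolist())) != temps.size:
        raise ValidationError("temperatures must be distinct")
    if np.any(qs <= 0):
        raise ValidationError("all quantities must be positive for the log transform")

    x = 1.0 / (temps + KELVIN_OFFSET)
    y = np.log(qs)
    res = stats.linregress(x, y)
    sign = -1.0 if orientation == "rate" else 1.0
    ea = sign * res.slope * R_GAS / 1000.0
    se = None if temps.size == 2 else float(res.stderr) * R_GAS / 1000.0
    return ArrheniusFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        orientation=orientation,
        ea_kj_mol=float(ea),
        pre_exponential=float(np.exp(res.intercept)),
        r2=float(res.rvalue**2),
        n_points=int(temps.size),
        se_ea_kj_mol=se,
    )


def predict_arrhenius(fit: ArrheniusFit, temperature_c: float) -> float:
    """Evaluate the fitted regression line: exp(intercept + slope/(T+273.15)).

    At a fitted temperature this returns the line's value, not necessarily
    the observed point.
    """
    return exp(fit.intercept + fit.slope / (float(temperature_c) + KELVIN_OFFSET))


def evaluate_log_logistic(k3: float, tc: float, temperature_c) -> float | np.ndarray:
    """Evaluate b(T) = ln(1 + exp(k3 (T - Tc))) (softplus), overflow-safe.

    For large positive arguments x the identity x + ln(1 + exp(-x)) is used,
    so k3 (T - Tc) = 1000 returns ~1000 instead of overflowing.
    """
    x = k3 * (np.asarray(temperature_c, dtype=float) - tc)
    # softplus(x) = max(x, 0) + log1p(exp(-|x|)) is finite for any x
    out = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    return float(out) if out.ndim == 0 else out


def log_logistic_metrics(k3: float, tc: float, points) -> FitMetrics:
    """Goodness of fit of given (k3, Tc) against observed (T, b) pairs.

    MSE = SSE/n (no dof correction); R^2 = 1 - SSE/SST with SST about the
    mean observed b.
    """
    temps = np.array([float(T) for T, _ in points])
    bs = np.array([float(b) for _, b in points])
    pred = evaluate_log_logistic(k3, tc, temps)
    sse = float(np.sum((bs - pred) ** 2))
    sst = float(np.sum((bs - bs.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse < 1e-20 else 0.0)
    mse = sse / temps.size
    return FitMetrics(r2=r2, mse=mse, rmse=sqrt(mse))


def fit_log_logistic(points) -> LogLogisticFit:
    """Fit (k3, Tc) of the log-logistic curve to (temperature_c, b) pairs.

    Bounded nonlinear least squares with a coarse multi-start grid over
    (k3, Tc); the best grid cell seeds a local refinement. Needs >= 3
    points (two free parameters).
    """
    pts = [(float(T), float(b)) for T, b in points]
    if len(pts) < 3:
        raise ValidationError(f"need >= 3 points for a 2-parameter fit, got {len(pts)}")
    temps = np.array([T for T, _ in pts])
    bs = np.array([b for _, b in pts])

    lo = (LOGLOGISTIC_K3_BOUNDS[0], LOGLOGISTIC_TC_BOUNDS[0])
    hi = (LOGLOGISTIC_K3_BOUNDS[1], LOGLOGISTIC_TC_BOUNDS[1])

    def resid(p):
        return evaluate_log_logistic(p[0], p[1], temps) - bs

    best = None
    for k3_0 in np.geomspace(1e-3, 2.0, 8):
        for tc_0 in np.linspace(-40.0, 280.0, 9):
            sol = optimize.least_squares(
                resid, [k3_0, tc_0], bounds=(lo, hi), ftol=1e-10, xtol=1e-12, gtol=1e-10
            )
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise FitFailureError("log-logistic fit failed from every start")

    k3, tc = float(best.x[0]), float(best.x[1])
    return LogLogisticFit(
        k3=k3, tc=tc, metrics=log_logistic_metrics(k3, tc, pts), n_points=len(pts)
    )
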