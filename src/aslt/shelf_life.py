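"""Retention-threshold shelf life and its Arrhenius extrapolation.

Shelf life is defined as the time for the analyte to fall to a retention
fraction f of its initial concentration; with the conventional nutritional
threshold f = 0.80 this is t80. Inverting the Weibull retention model
Y(t) = exp(-b t^n) at Y = f gives the closed form

    t_f = ((-ln f) / b) ** (1 / n).

Shelf lives computed at the accelerated storage temperatures are then
regressed as ln(t_f) on reciprocal absolute temperature (an Arrhenius-type
secondary model) and the fitted line is evaluated at lower, unmeasured
storage temperatures. Predictions outside the fitted temperature span are
annotated as extrapolations: with only a handful of accelerated
temperatures they are indicative estimates, not guarantees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import StageError, ValidationError
from .primary_kinetics import (
    PrimaryFit,
    fit_all_primary,
    select_primary_model,
)
from .secondary_models import (
    ArrheniusFit,
    LogLogisticFit,
    fit_arrhenius,
    fit_log_logistic,
    predict_arrhenius,
)
from .study_data import StorageDataset

DEFAULT_THRESHOLD = 0.80


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (18.5 -> 19)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -round_half_away(-x)


@dataclass(frozen=True)
class ShelfLifeRow:
    temperature_c: float
    b: float
    n: float
    t_threshold_days: float
    t_threshold_days_rounded: int


@dataclass(frozen=True)
class ShelfLifeTable:
    """Per-temperature shelf life at a retention threshold f."""

    threshold_fraction: float
    rows: tuple[ShelfLifeRow, ...]


@dataclass(frozen=True)
class PredictionRow:
    temperature_c: float
    t_threshold_days: float
    t_threshold_days_rounded: int
    extrapolated: bool


@dataclass(frozen=True)
class ShelfLifePrediction:
    """Arrhenius fit of ln(t_f) vs 1/T plus predictions at target temperatures."""

    arrhenius: ArrheniusFit
    threshold_fraction: float
    fitted_span_c: tuple[float, float]
    predictions: tuple[PredictionRow, ...] = ()


def retention_time(b: float, n: float, f: float = DEFAULT_THRESHOLD) -> float:
    """Time in days for Weibull retention exp(-b t^n) to reach fraction f.

    With f = 0.80 this is the t80 shelf life.
    """
    if not b > 0:
        raise ValidationError(f"b must be > 0, got {b}")
    if not n > 0:
        raise ValidationError(f"n must be > 0, got {n}")
    if not 0 < f < 1:
        raise ValidationError(f"threshold fraction must be in (0, 1), got {f}")
    return ((-math.log(f)) / b) ** (1.0 / n)


def build_shelf_life_table(
    weibull_fits: list[PrimaryFit], f: float = DEFAULT_THRESHOLD
) -> ShelfLifeTable:
    """One shelf-life row per temperature from fitted Weibull parameters.

    Rounded values use round-half-away-from-zero to the nearest day; the
    unrounded values are kept for the secondary regression.
    """
    temps = [fit.temperature_c for fit in weibull_fits]
    if len(set(temps)) != len(temps):
        raise ValidationError(f"duplicate temperatures: {sorted(temps)}")
    rows = []
    for fit in sorted(weibull_fits, key=lambda x: x.temperature_c):
        if fit.model != "weibull":
            raise ValidationError(
                f"shelf-life table needs Weibull fits, got {fit.model!r} "
                f"at {fit.temperature_c} degC"
            )
        t = retention_time(fit.b, fit.n, f)
        rows.append(
            ShelfLifeRow(
                temperature_c=fit.temperature_c,
                b=fit.b,
                n=fit.n,
                t_threshold_days=t,
                t_threshold_days_rounded=round_half_away(t),
            )
        )
    return ShelfLifeTable(threshold_fraction=f, rows=tuple(rows))


def fit_shelf_life_arrhenius(table: ShelfLifeTable) -> ShelfLifePrediction:
    """Regress ln(t_f) on 1/(T + 273.15) over the table's unrounded values.

    Unrounded shelf lives are used deliberately: integer rounding before the
    log-linear regression visibly shifts the slope.
    """
    if len(table.rows) < 2:
        raise ValidationError(f"need >= 2 rows, got {len(table.rows)}")
    pts = [(r.temperature_c, r.t_threshold_days) for r in table.rows]
    fit = fit_arrhenius(pts, orientation="shelf_life")
    temps = [r.temperature_c for r in table.rows]
    return ShelfLifePrediction(
        arrhenius=fit,
        threshold_fraction=table.threshold_fraction,
        fitted_span_c=(min(temps), max(temps)),
    )


def predict_shelf_life(
    pred: ShelfLifePrediction, temperatures_c
) -> ShelfLifePrediction:
    """Evaluate the fitted Arrhenius line at the requested temperatures.

    Returns a copy of ``pred`` with prediction rows attached; temperatures
    outside the fitted span are flagged ``extrapolated``.
    """
    lo, hi = pred.fitted_span_c
    rows = []
    for T in temperatures_c:
        t = predict_arrhenius(pred.arrhenius, T)
        rows.append(
            PredictionRow(
                temperature_c=float(T),
                t_threshold_days=t,
                t_threshold_days_rounded=round_half_away(t),
                extrapolated=not (lo <= float(T) <= hi),
            )
        )
    return ShelfLifePrediction(
        arrhenius=pred.arrhenius,
        threshold_fraction=pred.threshold_fraction,
        fitted_span_c=pred.fitted_span_c,
        predictions=tuple(rows),
    )


@dataclass
class PipelineResult:
    """All intermediate results of the accelerated shelf-life pipeline,
    keyed by stage. Stages that could not run hold the error under
    ``errors`` instead."""

    primary_fits: dict = field(default_factory=dict)  # temp -> [PrimaryFit x3]
    selected: dict = field(default_factory=dict)  # temp -> PrimaryFit
    weibull_fits: dict = field(default_factory=dict)  # temp -> PrimaryFit
    arrhenius_b: ArrheniusFit | None = None
    log_logistic_b: LogLogisticFit | None = None
    shelf_life_table: ShelfLifeTable | None = None
    shelf_life_prediction: ShelfLifePrediction | None = None
    errors: dict = field(default_factory=dict)  # stage -> StageError


def run_aslt_pipeline(
    dataset: StorageDataset,
    f: float = DEFAULT_THRESHOLD,
    target_temperatures=(5, 10, 15, 20, 25, 30),
) -> PipelineResult:
    """Full accelerated shelf-life analysis of a multi-temperature study.

    Per temperature: normalize to retention, fit zero-order, first-order
    and Weibull primary models, select the best by R^2. Across
    temperatures: fit Arrhenius and log-logistic secondary models on the
    Weibull scale parameter b(T), build the shelf-life table at threshold
    f, regress ln(t_f) vs 1/T, and predict shelf life at the target
    temperatures. Secondary stages need >= 2 temperatures; when a stage
    fails its error is recorded and later stages are skipped, but the
    per-temperature primary fits are always returned.
    """
    result = PipelineResult()
    for series in sorted(dataset.series, key=lambda s: s.temperature_c):
        T = series.temperature_c
        try:
            fits = fit_all_primary(series)
        except Exception as err:  # noqa: BLE001 - report per-stage
            result.errors[f"primary@{T}"] = StageError(f"primary@{T}", err)
            continue
        result.primary_fits[T] = fits
        result.selected[T] = select_primary_model(fits)
        result.weibull_fits[T] = next(ft for ft in fits if ft.model == "weibull")

    b_points = [(T, ft.b) for T, ft in result.weibull_fits.items()]

    def stage(name, func):
        try:
            return func()
        except Exception as err:  # noqa: BLE001
            result.errors[name] = StageError(name, err)
            return None

    if len(b_points) < 2:
        result.errors["secondary"] = StageError(
            "secondary",
            ValidationError(
                f"need >= 2 temperatures for secondary models, got {len(b_points)}"
            ),
        )
        return result

    result.arrhenius_b = stage("arrhenius_b", lambda: fit_arrhenius(b_points, "rate"))
    result.log_logistic_b = stage("log_logistic_b", lambda: fit_log_logistic(b_points))
    result.shelf_life_table = stage(
        "shelf_life_table",
        lambda: build_shelf_life_table(list(result.weibull_fits.values()), f),
    )
    if result.shelf_life_table is not None:
        result.shelf_life_prediction = stage(
            "shelf_life_prediction",
            lambda: predict_shelf_life(
                fit_shelf_life_arrhenius(result.shelf_life_table), target_temperatures
            ),
        )
    return result
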