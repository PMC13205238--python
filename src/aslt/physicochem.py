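"""Analytical-chemistry utilities: titratable acidity, external-standard
HPLC calibration, and the Pearson correlation screen.

Titratable acidity converts an NaOH titration to g citric acid per
100 mL sample:

    TA = V * N * 0.06404 * 100 / V_sample

with V the titrant volume (mL), N the titrant normality (eq/L) and
0.06404 g/meq the milliequivalent weight of citric acid. Note the
milliequivalent (not equivalent, 64.04 g/eq) weight: with V in mL the
product V*N is in milliequivalents, and 0.06404 g/meq puts the result on
the conventional g/100 mL scale.

Calibration follows the external-standard convention: OLS of detector
peak area on standard concentration, inverted to quantify unknowns, with
LOD/LOQ either from supplied baseline noise (3 sigma/slope and
10 sigma/slope) or, as a fallback, from the calibration residual standard
deviation (3.3 sigma/slope and 10 sigma/slope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import stats

from .errors import ValidationError

#: milliequivalent weight of citric acid, g/meq
CITRIC_ACID_MEQ_WEIGHT = 0.06404


@dataclass(frozen=True)
class TitrationRecord:
    """One acid-base titration: titrant volume/normality and sample volume."""

    naoh_volume_ml: float
    normality: float = 0.1
    sample_volume_ml: float = 10.0
    acid_factor: float = CITRIC_ACID_MEQ_WEIGHT

    def __post_init__(self):
        if self.naoh_volume_ml < 0:
            raise ValidationError("titrant volume cannot be negative")
        if self.normality <= 0 or self.acid_factor <= 0:
            raise ValidationError("normality and acid factor must be positive")
        if self.sample_volume_ml <= 0:
            raise ValidationError("sample volume must be positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted peak-area vs concentration line with detection limits."""

    slope: float  # area per (mg/L)
    intercept: float  # area
    r2: float
    lod_mg_l: float
    loq_mg_l: float
    concentration_range: tuple[float, float]

    def __post_init__(self):
        if self.slope <= 0:
            raise ValidationError(f"calibration slope must be positive, got {self.slope}")
        if self.lod_mg_l >= self.loq_mg_l:
            raise ValidationError("LOD must be below LOQ")


def titratable_acidity(rec: TitrationRecord) -> float:
    """Titratable acidity in g citric acid per 100 mL sample."""
    return rec.naoh_volume_ml * rec.normality * rec.acid_factor * 100.0 / rec.sample_volume_ml


def fit_calibration(standards, noise_sd: float | None = None) -> CalibrationCurve:
    """Fit an external-standard calibration line to (mg/L, peak area) pairs.

    ``noise_sd`` is a measured baseline-noise standard deviation on the
    area scale; when given, LOD/LOQ = 3/10 sigma_noise / slope (the
    signal-to-noise definition). Otherwise the calibration residual SD
    (dof = n - 2) stands in, with the conventional 3.3/10 factors.
    """
    pts = [(float(c), float(a)) for c, a in standards]
    if len(pts) < 3:
        raise ValidationError(f"need >= 3 standards, got {len(pts)}")
    conc = np.array([c for c, _ in pts])
    area = np.array([a for _, a in pts])
    if len(set(conc.tolist())) != conc.size:
        raise ValidationError("standard concentrations must be distinct")

    res = stats.linregress(conc, area)
    if res.slope <= 0:
        raise ValidationError(f"non-positive calibration slope ({res.slope})")
    resid = area - (res.intercept + res.slope * conc)
    dof = conc.size - 2
    sigma = sqrt(float(resid @ resid) / dof) if dof > 0 else 0.0

    if noise_sd is not None:
        lod = 3.0 * noise_sd / res.slope
        loq = 10.0 * noise_sd / res.slope
    else:
        lod = 3.3 * sigma / res.slope
        loq = 10.0 * sigma / res.slope
    if loq <= lod:  # exact fit: sigma == 0; report degenerate but ordered limits
        loq = lod + 1e-12
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        lod_mg_l=float(lod),
        loq_mg_l=float(loq),
        concentration_range=(float(conc.min()), float(conc.max())),
    )


def quantify_from_area(
    curve: CalibrationCurve, area: float, dilution_factor: float = 1.0
) -> float:
    """Back-calculate an analyte concentration in mg/100 mL from a peak area.

    Inverts the calibration line (mg/L), multiplies by the sample dilution
    factor, and converts mg/L -> mg/100 mL (divide by 10). A warning is
    emitted for areas outside the calibrated response range, and for
    non-positive back-calculated concentrations (below-range signal).
    """
    lo_area = curve.intercept + curve.slope * curve.concentration_range[0]
    hi_area = curve.intercept + curve.slope * curve.concentration_range[1]
    if not lo_area <= area <= hi_area:
        warnings.warn(
            f"peak area {area:g} outside calibrated response range "
            f"[{lo_area:g}, {hi_area:g}]",
            stacklevel=2,
        )
    mg_per_l = (area - curve.intercept) / curve.slope * dilution_factor
    if mg_per_l <= 0:
        warnings.warn(
            f"back-calculated concentration {mg_per_l:g} mg/L is below range",
            stacklevel=2,
        )
    return mg_per_l / 10.0


#: |r| thresholds for the qualitative correlation labels
CORRELATION_CLASSES = (("strong", 0.70), ("moderate", 0.40), ("weak", 0.0))


def classify_correlation(r: float) -> str:
    """Label |r| >= 0.70 strong, 0.40-0.69 moderate, < 0.40 weak."""
    a = abs(r)
    for label, cut in CORRELATION_CLASSES:
        if a >= cut:
            return label
    return "weak"


def pearson_r(x, y) -> float:
    """Product-moment correlation between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError(f"need >= 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a zero-variance vector")
    return float(stats.pearsonr(x, y).statistic)
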