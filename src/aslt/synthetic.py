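"""Synthetic degradation-study generator and parameter-recovery harness.

Generates multi-temperature storage studies with the statistical structure
the analysis assumes: a known primary decay curve (zero-order, first-order
or Weibull) per temperature, evaluated on an isothermal sampling schedule,
with replicate measurement noise on a chosen scale. Every public entry
point takes an explicit seed; there is no hidden global randomness, and
identical (config, seed) yields bit-identical datasets.

What the generator emulates: the accelerated-storage design (three
temperatures with denser sampling at hotter conditions, triplicates),
Weibull-shaped retention decay, and small homoscedastic measurement error.
What it does not: autocorrelated instrument drift, heteroscedastic error
growing with degradation, batch effects, or non-isothermal profiles —
conclusions from these simulations speak to the estimator, not to every
feature of real chromatographic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import benchmarks
from .errors import ValidationError
from .shelf_life import retention_time, run_aslt_pipeline
from .study_data import DegradationSeries, StorageDataset

NOISE_MODELS = ("additive-retention", "additive-concentration", "proportional")

#: default replicate noise SD on the retention scale
DEFAULT_NOISE_SD = 0.005

#: positivity floor as a fraction of c0
_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class SimulationConfig:
    """True parameters and design of a simulated degradation study.

    ``params`` maps temperature (degC) to the model's true parameters:
    ``{"k1": ...}`` for zero-order, ``{"k2": ...}`` for first-order, or
    ``{"b": ..., "n": ...}`` for Weibull. ``schedule`` maps temperature to
    sampling times in days (starting at 0). Noise is added per replicate on
    the scale named by ``noise_model``; ``noise_sd`` is on that same scale.
    ``heteroscedastic`` optionally scales the noise SD linearly with the
    degraded fraction (1 - Y), so later samples are noisier.
    """

    model: str
    params: dict[float, dict[str, float]]
    c0: float
    schedule: dict[float, tuple[float, ...]]
    seed: int
    replicates: int = 3
    noise_model: str = "additive-retention"
    noise_sd: float = DEFAULT_NOISE_SD
    heteroscedastic: bool = False
    label: str = "synthetic"
    physicochem_coupling: dict | None = None

    def __post_init__(self):
        if self.model not in ("zero", "first", "weibull"):
            raise ValidationError(f"unknown model {self.model!r}")
        if self.noise_model not in NOISE_MODELS:
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if set(self.params) != set(self.schedule):
            raise ValidationError("params and schedule must cover the same temperatures")
        for T, times in self.schedule.items():
            if times[0] != 0:
                raise ValidationError(f"schedule at {T} degC must start at 0")


def _mean_retention(model: str, p: dict[str, float], c0: float, t: np.ndarray) -> np.ndarray:
    if model == "zero":
        return 1.0 - p["k1"] * t / c0
    if model == "first":
        return np.exp(-p["k2"] * t)
    return np.exp(-p["b"] * t ** p["n"])


def simulate_study(config: SimulationConfig) -> StorageDataset:
    """Draw one synthetic study; replicate values are averaged per time point.

    Concentrations are truncated at a floor of 1e-6 * c0 so the positivity
    invariant of the containers always holds.
    """
    rng = np.random.default_rng(config.seed)
    series = []
    floor = _FLOOR_FRACTION * config.c0
    for T in sorted(config.schedule):
        t = np.asarray(config.schedule[T], dtype=float)
        mean_ret = _mean_retention(config.model, config.params[T], config.c0, t)
        mean_conc = config.c0 * mean_ret
        reps = np.empty((config.replicates, t.size))
        for r in range(config.replicates):
            eps = rng.standard_normal(t.size)
            if config.heteroscedastic:
                eps = eps * (1.0 + (1.0 - mean_ret))
            if config.noise_model == "additive-retention":
                reps[r] = config.c0 * (mean_ret + config.noise_sd * eps)
            elif config.noise_model == "additive-concentration":
                reps[r] = mean_conc + config.noise_sd * eps
            else:  # proportional
                reps[r] = mean_conc * (1.0 + config.noise_sd * eps)
        reps = np.maximum(reps, floor)
        conc = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1) if config.replicates > 1 else None
        # the containers require an exact time-0 anchor; keep the noisy
        # replicate mean there (it IS the measured C0), just positive
        series.append(
            DegradationSeries(
                temperature_c=float(T),
                times=t,
                concentrations=conc,
                replicate_sd=sd,
                analyte_label=config.label,
            )
        )
    return StorageDataset(
        series=series,
        metadata={"generator": "aslt.synthetic", "model": config.model, "seed": config.seed},
    )


def reference_config(matrix: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Simulation config matching a reference juice matrix.

    Uses the matrix's fitted Weibull (b, n) per temperature as truth, its
    measured initial concentration, the standard accelerated-storage
    schedules, triplicates, and additive-retention noise (sd 0.005).
    Keyword overrides replace any config field.
    """
    if matrix not in benchmarks.MATRICES:
        raise ValidationError(f"unknown matrix {matrix!r}; options: {benchmarks.MATRICES}")
    cfg = SimulationConfig(
        model="weibull",
        params={T: {"b": b, "n": n} for T, (b, n) in benchmarks.WEIBULL[matrix].items()},
        c0=benchmarks.C0[matrix],
        schedule=dict(benchmarks.SCHEDULES),
        seed=seed,
        label=f"vitamin C ({matrix})",
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class RecoverySummary:
    """Parameter-recovery results across replicate simulated studies."""

    n_studies: int
    n_failed: int
    # per temperature: arrays of estimates across studies
    b_rel_err: dict[float, np.ndarray] = field(default_factory=dict)
    n_rel_err: dict[float, np.ndarray] = field(default_factory=dict)
    ea_estimates: np.ndarray | None = None
    ea_true: float | None = None
    t80_rel_err: dict[float, np.ndarray] = field(default_factory=dict)

    def median_abs_rel_err(self, which: str) -> dict[float, float]:
        src = self.b_rel_err if which == "b" else self.n_rel_err
        return {T: float(np.median(np.abs(v))) for T, v in src.items()}


def recovery_experiment(
    config: SimulationConfig, n_replicate_studies: int, seed: int
) -> RecoverySummary:
    """Simulate many studies, run the full pipeline on each, and summarize
    how well the true parameters are recovered.

    Reports per-temperature relative errors of (b, n) and t80, and the
    spread of the fitted activation energy around the truth implied by the
    configured b(T). Pipeline failures are counted, not fatal. Only
    Weibull-truth configs have a defined (b, n) recovery target.
    """
    if n_replicate_studies < 1:
        raise ValidationError("n_replicate_studies must be >= 1")
    if config.model != "weibull":
        raise ValidationError("recovery_experiment expects a Weibull-truth config")

    from .secondary_models import fit_arrhenius  # local: avoid cycle at import time

    temps = sorted(config.params)
    true_ea = fit_arrhenius(
        [(T, config.params[T]["b"]) for T in temps], orientation="rate"
    ).ea_kj_mol
    true_t80 = {
        T: retention_time(config.params[T]["b"], config.params[T]["n"]) for T in temps
    }

    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_replicate_studies)
    b_err = {T: [] for T in temps}
    n_err = {T: [] for T in temps}
    t80_err = {T: [] for T in temps}
    ea_hat = []
    n_failed = 0
    for s in seeds:
        ds = simulate_study(replace(config, seed=int(s)))
        res = run_aslt_pipeline(ds)
        if res.errors or res.arrhenius_b is None or res.shelf_life_table is None:
            n_failed += 1
            continue
        for T in temps:
            fit = res.weibull_fits[T]
            b_err[T].append(fit.b / config.params[T]["b"] - 1.0)
            n_err[T].append(fit.n / config.params[T]["n"] - 1.0)
        for row in res.shelf_life_table.rows:
            t80_err[row.temperature_c].append(
                row.t_threshold_days / true_t80[row.temperature_c] - 1.0
            )
        ea_hat.append(res.arrhenius_b.ea_kj_mol)

    return RecoverySummary(
        n_studies=n_replicate_studies,
        n_failed=n_failed,
        b_rel_err={T: np.array(v) for T, v in b_err.items()},
        n_rel_err={T: np.array(v) for T, v in n_err.items()},
        ea_estimates=np.array(ea_hat),
        ea_true=true_ea,
        t80_rel_err={T: np.array(v) for T, v in t80_err.items()},
    )
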