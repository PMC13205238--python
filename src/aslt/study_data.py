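"""Containers and I/O for multi-temperature isothermal degradation studies.

A study stores one concentration-time trajectory per storage temperature
(a :class:`DegradationSeries`), grouped in a :class:`StorageDataset`. The
on-disk format is a long CSV with columns ``temperature_C, time_days,
replicate, concentration``; replicate rows for the same (temperature, time)
cell are averaged on read, with the per-cell standard deviation retained.

Times are in days, temperatures in degrees Celsius, concentrations in
mg/100 mL throughout. Kelvin conversion happens only inside the secondary
(temperature-dependence) models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

REQUIRED_COLUMNS = ("temperature_C", "time_days", "concentration")


@dataclass(frozen=True)
class DegradationSeries:
    """One temperature's analyte concentration trajectory.

    Parameters
    ----------
    temperature_c : float
        Storage temperature in degrees Celsius.
    times : ndarray
        Sampling times in days; strictly increasing, starting at 0. The
        time-0 point supplies the initial concentration C0 used for
        normalization.
    concentrations : ndarray
        Mean analyte concentration per sampling time (mg/100 mL), > 0.
    replicate_sd : ndarray or None
        Per-time standard deviation across replicates, when replicates
        were measured.
    analyte_label : str
        Free-text analyte name (default ``"vitamin C"``).
    """

    temperature_c: float
    times: np.ndarray
    concentrations: np.ndarray
    replicate_sd: np.ndarray | None = None
    analyte_label: str = "vitamin C"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)
        if self.replicate_sd is not None:
            object.__setattr__(
                self, "replicate_sd", np.asarray(self.replicate_sd, dtype=float)
            )
        if times.size != conc.size:
            raise ValidationError(
                f"times ({times.size}) and concentrations ({conc.size}) differ in length"
            )
        if times.size < 3:
            raise ValidationError(f"need >= 3 time points, got {times.size}")
        if times[0] != 0:
            raise ValidationError(
                f"first sampling time must be 0 (supplies C0), got {times[0]}"
            )
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        bad = np.flatnonzero(conc <= 0)
        if bad.size:
            raise ValidationError(
                f"non-positive concentration at row index {bad[0]} "
                f"(value {conc[bad[0]]!r})"
            )

    @property
    def c0(self) -> float:
        """Initial concentration C0 (the time-0 measurement)."""
        return float(self.concentrations[0])


@dataclass(frozen=True)
class RetentionSeries:
    """Normalized trajectory Y(t) = C(t)/C0 at one temperature."""

    temperature_c: float
    times: np.ndarray
    retention: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        ret = np.asarray(self.retention, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "retention", ret)
        if ret[0] != 1.0:
            raise ValidationError(f"retention at time 0 must be exactly 1, got {ret[0]}")
        if np.any(ret <= 0):
            raise ValidationError("all retention values must be > 0")


@dataclass
class StorageDataset:
    """A collection of degradation series at distinct storage temperatures."""

    series: list[DegradationSeries]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        temps = [s.temperature_c for s in self.series]
        if len(set(temps)) != len(temps):
            raise ValidationError(f"duplicate temperatures in dataset: {sorted(temps)}")

    @property
    def temperatures(self) -> list[float]:
        return [s.temperature_c for s in self.series]

    def get(self, temperature_c: float) -> DegradationSeries:
        for s in self.series:
            if s.temperature_c == temperature_c:
                return s
        raise KeyError(f"no series at {temperature_c} degC")


@dataclass(frozen=True)
class PhysicochemSeries:
    """Co-measured physicochemical trajectory: pH, titratable acidity, Brix."""

    temperature_c: float
    times: np.ndarray
    ph: np.ndarray
    acidity: np.ndarray  # g citric acid / 100 mL
    brix: np.ndarray

    def __post_init__(self):
        for name in ("times", "ph", "acidity", "brix"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("ph", "acidity", "brix"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite value in {name}")
        if np.any(self.acidity < 0) or np.any(self.brix < 0):
            raise ValidationError("acidity and brix must be non-negative")


def read_study(path, format: str = "csv-long") -> StorageDataset:
    """Read a long-format degradation study CSV into a :class:`StorageDataset`.

    Replicate rows sharing a (temperature, time) cell are averaged; the
    per-cell standard deviation (ddof=1) is kept as ``replicate_sd``. Each
    temperature must include a time-0 row.
    """
    if format != "csv-long":
        raise FormatError(f"unsupported format {format!r}; only 'csv-long'")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    series = []
    for temp, group in df.groupby("temperature_C", sort=True):
        cell = group.groupby("time_days", sort=True)["concentration"]
        means = cell.mean()
        has_reps = (cell.count() > 1).any()
        sds = cell.std(ddof=1).to_numpy() if has_reps else None
        times = means.index.to_numpy(dtype=float)
        if times[0] != 0:
            raise ValidationError(
                f"temperature {temp}: no time-0 row (first time is {times[0]})"
            )
        series.append(
            DegradationSeries(
                temperature_c=float(temp),
                times=times,
                concentrations=means.to_numpy(),
                replicate_sd=sds,
            )
        )
    return StorageDataset(series=series, metadata={"source": str(path)})


def write_study(dataset: StorageDataset, path) -> None:
    """Write a dataset back to the long CSV layout (one row per mean point).

    Replicate-level values are not reconstructed; the written file holds the
    per-time means, so ``read_study(write_study(d))`` round-trips the means.
    """
    rows = []
    for s in dataset.series:
        for t, c in zip(s.times, s.concentrations):
            rows.append(
                {
                    "temperature_C": s.temperature_c,
                    "time_days": t,
                    "replicate": 1,
                    "concentration": c,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def normalize_retention(series: DegradationSeries) -> RetentionSeries:
    """Normalize a concentration series to retention Y(t) = C(t)/C0.

    Y(0) is exactly 1 by construction. Scale-invariant: multiplying all
    concentrations by a positive constant leaves the result unchanged.
    """
    c0 = series.c0
    if c0 <= 0:
        raise ValidationError(f"C0 must be positive, got {c0}")
    ret = series.concentrations / c0
    ret[0] = 1.0
    return RetentionSeries(
        temperature_c=series.temperature_c, times=series.times.copy(), retention=ret
    )
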