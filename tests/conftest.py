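import numpy as np
import pytest

from aslt import benchmarks
from aslt.primary_kinetics import FitMetrics, PrimaryFit
from aslt.study_data import DegradationSeries


@pytest.fixture
def weibull_series():
    """Noiseless Weibull-decay series on the 21-day/3-day schedule."""

    def make(b=0.07695, n=0.36305, c0=1090.17, temperature_c=35.0):
        t = np.arange(0.0, 22.0, 3.0)
        return DegradationSeries(
            temperature_c=temperature_c,
            times=t,
            concentrations=c0 * np.exp(-b * t**n),
        )

    return make


@pytest.fixture
def reference_weibull_fits():
    """PrimaryFit objects carrying a matrix's reference (b, n) values."""

    def make(matrix):
        return [
            PrimaryFit(
                model="weibull",
                temperature_c=T,
                c0=benchmarks.C0[matrix],
                b=b,
                n=n,
                metrics=FitMetrics(r2=1.0, mse=0.0, rmse=0.0),
                response_scale="retention",
            )
            for T, (b, n) in sorted(benchmarks.WEIBULL[matrix].items())
        ]

    return make


@pytest.fixture
def study_csv(tmp_path):
    """Write a small triplicate long-format study CSV; returns its path."""
    rows = ["temperature_C,time_days,replicate,concentration"]
    rng = np.random.default_rng(7)
    for T, k2 in ((35, 0.01), (45, 0.02), (55, 0.04)):
        for t in (0, 2, 4, 6):
            for rep in (1, 2, 3):
                c = 100.0 * np.exp(-k2 * t) + rng.normal(0, 0.05)
                rows.append(f"{T},{t},{rep},{c:.6f}")
    path = tmp_path / "study.csv"
    path.write_text("\n".join(rows) + "\n")
    return path
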