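"""Reference parameter sets for two tropical juice matrices.

Fitted Weibull, log-logistic and Arrhenius parameters for vitamin C
degradation in camu camu and naranjilla juices under a standard
accelerated-storage design (35 degC for 21 d sampled every 3 d, 45 degC
for 14 d every 2 d, 55 degC for 7 d daily, triplicate measurements).
These serve as defaults for the synthetic generator and as worked-example
inputs for the built-in consistency check.
"""

from __future__ import annotations

MATRICES = ("camu_camu", "naranjilla")

#: sampling schedule per storage temperature (days, including time 0)
SCHEDULES: dict[float, tuple[float, ...]] = {
    35.0: tuple(float(t) for t in range(0, 22, 3)),
    45.0: tuple(float(t) for t in range(0, 15, 2)),
    55.0: tuple(float(t) for t in range(0, 8, 1)),
}

#: initial vitamin C concentration, mg/100 mL
C0: dict[str, float] = {
    "camu_camu": 1090.17,
    "naranjilla": 43.47,
}

#: fitted Weibull (b, n) per storage temperature (degC)
WEIBULL: dict[str, dict[float, tuple[float, float]]] = {
    "camu_camu": {
        35.0: (0.07695, 0.36305),
        45.0: (0.1377, 0.22699),
        55.0: (0.16037, 0.30987),
    },
    "naranjilla": {
        35.0: (0.00804, 0.96644),
        45.0: (0.04493, 0.56064),
        55.0: (0.13250, 0.23923),
    },
}

#: fitted log-logistic (k3, Tc) of b(T)
LOG_LOGISTIC: dict[str, tuple[float, float]] = {
    "camu_camu": (0.03386, 105.46),
    "naranjilla": (0.11997, 71.26),
}

#: reference activation energies (kJ/mol) of the b(T) Arrhenius fit
EA_B: dict[str, float] = {"camu_camu": 31.05, "naranjilla": 117.8}

#: reference activation energies (kJ/mol) of the t80 Arrhenius fit
EA_T80: dict[str, float] = {"camu_camu": 78.3, "naranjilla": 52.9}

#: reference rounded t80 shelf lives (days) per temperature
T80_DAYS: dict[str, dict[float, int]] = {
    "camu_camu": {35.0: 19, 45.0: 8, 55.0: 3},
    "naranjilla": {35.0: 31, 45.0: 17, 55.0: 9},
}


def b_points(matrix: str) -> list[tuple[float, float]]:
    """(temperature_c, b) pairs for a matrix, sorted by temperature."""
    return [(T, bn[0]) for T, bn in sorted(WEIBULL[matrix].items())]
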