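"""Synthetic drying datasets with the statistical structure the pipeline assumes.

The study's raw measurements were never deposited, so every downstream
stage is exercised against generated data: Page-form drying curves with
additive Gaussian noise, first-order-lag surface-temperature traces, a
3-method x 4-temperature quality table with replicate scatter at realistic
magnitudes, and quintuplicate CIELAB readings with optional injected
outliers.  All generators are pure functions of (spec, seed).

Per-method kinetic defaults are anchored to the printed study conditions:
activation energies of 25.3 / 32.1 / 38.7 kJ/mol for microwave-vacuum,
pulsed-vacuum and hot-air drying, and 40 degC drying times of 150 / 640 /
480 min, with Page exponents in the typical thin-layer range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import R_GAS, DryingCurve
from .quality import INDICATOR_COLUMNS, ColorMeasurement, QualityTable

__all__ = [
    "METHOD_DEFAULTS",
    "FRESH_COLOR",
    "SyntheticSpec",
    "generate_drying_curve",
    "generate_temperature_trace",
    "generate_quality_table",
]

#: Fresh-sample CIELAB reference (L*, a*, b*).
FRESH_COLOR = ColorMeasurement(31.82, -21.23, 19.51)

#: Final dry-basis moisture ratio at which a run terminates
#: (0.11 kg/kg safe level over the 2.03 kg/kg initial content).
TARGET_MR = 0.11 / 2.03

#: Per-method kinetic and instrumentation defaults: apparent activation
#: energy (J/mol), Page exponent, drying time at 40 degC (min), gravimetric
#: sampling interval (min), surface-temperature lag time constant (min).
METHOD_DEFAULTS = {
    "MVD": {"ea": 25_300.0, "n": 1.10, "t40_min": 150.0, "sampling_min": 5.0, "tau_min": 2.5},
    "PVD": {"ea": 32_100.0, "n": 0.95, "t40_min": 640.0, "sampling_min": 10.0, "tau_min": 8.0},
    "HAD": {"ea": 38_700.0, "n": 1.15, "t40_min": 480.0, "sampling_min": 10.0, "tau_min": 5.0},
}

#: Treatment-mean quality indicators (dE, dehiscence %, volatile oil
#: mL/10 g, amide mg/g) per method and temperature, reproducing the printed
#: assay table of the study: dE responds convexly to temperature, the
#: dehiscence rate rises monotonically, and oil/amide peak near 60 degC.
QUALITY_PROFILE = {
    ("MVD", 40): (6.73, 97.87, 0.90, 25.39),
    ("MVD", 50): (3.75, 98.09, 1.00, 24.84),
    ("MVD", 60): (3.81, 99.10, 1.50, 28.63),
    ("MVD", 70): (5.59, 99.31, 1.00, 23.09),
    ("PVD", 40): (4.40, 91.46, 0.70, 24.83),
    ("PVD", 50): (2.52, 97.19, 0.75, 26.28),
    ("PVD", 60): (4.37, 98.20, 0.75, 28.65),
    ("PVD", 70): (5.70, 98.31, 0.70, 25.94),
    ("HAD", 40): (3.07, 97.10, 0.80, 24.31),
    ("HAD", 50): (5.44, 98.20, 0.95, 25.48),
    ("HAD", 60): (5.86, 98.43, 1.00, 27.60),
    ("HAD", 70): (8.68, 99.77, 0.90, 26.49),
}

#: Treatment-mean CIELAB coordinates per method and temperature.
COLOR_PROFILE = {
    ("MVD", 40): (25.94, -17.68, 16.35),
    ("MVD", 50): (28.91, -18.24, 17.39),
    ("MVD", 60): (29.42, -17.17, 18.07),
    ("MVD", 70): (28.74, -16.49, 16.17),
    ("PVD", 40): (30.23, -17.72, 16.22),
    ("PVD", 50): (30.06, -18.27, 18.41),
    ("PVD", 60): (28.19, -18.65, 16.86),
    ("PVD", 70): (29.48, -16.63, 15.46),
    ("HAD", 40): (28.94, -20.11, 17.80),
    ("HAD", 50): (26.38, -19.30, 17.48),
    ("HAD", 60): (31.35, -16.43, 14.99),
    ("HAD", 70): (26.58, -16.20, 13.58),
}

#: Replicate standard deviations at the magnitudes of the printed table.
REPLICATE_SD = {"delta_e": 0.20, "dehiscence_rate": 0.50,
                "volatile_oil": 0.06, "amide": 0.35, "color": 0.30}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study: one drying method, four temperatures.

    The Page rate constant at each temperature comes from the Arrhenius pair
    (k0, ea); k0 defaults to the value that reproduces the method's 40 degC
    drying time.  Fixed seed implies byte-identical output.
    """

    method: str = "MVD"
    temperatures: tuple = (40.0, 50.0, 60.0, 70.0)
    k0: Optional[float] = None            # 1/min; None -> anchored default
    ea: Optional[float] = None            # J/mol; None -> method default
    page_n: Optional[float] = None        # None -> method default
    sampling_interval_min: Optional[float] = None
    noise_mr: float = 0.01                # additive Gaussian sigma on MR
    trace_tau_min: Optional[float] = None  # first-order-lag time constant
    trace_noise: float = 0.5              # degC
    initial_temperature: float = 20.0     # degC
    initial_moisture: float = 2.03        # kg/kg dry basis
    n_indicator_replicates: int = 3
    n_color_replicates: int = 5
    replicate_sd_scale: float = 1.0       # scales all replicate SDs (0 -> exact means)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHOD_DEFAULTS:
            raise ValueError(f"unknown method {self.method!r}")
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ValueError("temperatures must be distinct")
        if self.noise_mr < 0 or self.trace_noise < 0:
            raise ValueError("noise levels must be non-negative")

    @property
    def defaults(self) -> dict:
        return METHOD_DEFAULTS[self.method]

    @property
    def ea_value(self) -> float:
        return self.defaults["ea"] if self.ea is None else self.ea

    @property
    def n_value(self) -> float:
        return self.defaults["n"] if self.page_n is None else self.page_n

    @property
    def k0_value(self) -> float:
        if self.k0 is not None:
            return self.k0
        # anchor: drying to the target MR at 40 degC in the printed time
        n = self.n_value
        t40 = self.defaults["t40_min"]
        k40 = -math.log(TARGET_MR) / t40**n
        return k40 * math.exp(self.ea_value / (R_GAS * (40.0 + 273.15)))

    def rate_constant(self, temperature_c: float) -> float:
        """Page rate constant k(T), 1/min, from the Arrhenius pair."""
        return self.k0_value * math.exp(
            -self.ea_value / (R_GAS * (temperature_c + 273.15))
        )

    def _rng(self, *tags: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *tags])


def generate_drying_curve(spec: SyntheticSpec, temperature_c: float) -> DryingCurve:
    """A noisy Page-form drying curve at one temperature.

    MR_t = clip(exp(-k t^n) + N(0, sigma), 0, 1) at the method's sampling
    interval, truncated once the noise-free MR reaches the target level;
    the matching first-order-lag surface-temperature trace is attached.
    """
    k = spec.rate_constant(temperature_c)
    n = spec.n_value
    dt = spec.sampling_interval_min or spec.defaults["sampling_min"]
    t_end = (-math.log(TARGET_MR) / k) ** (1.0 / n)
    times_min = np.arange(0.0, t_end, dt)
    times_min = np.append(times_min, t_end)
    mr_true = np.exp(-k * times_min**n)
    rng = spec._rng(int(round(temperature_c * 10)), 1)
    mr = mr_true + rng.normal(0.0, spec.noise_mr, size=mr_true.shape) if spec.noise_mr else mr_true.copy()
    mr = np.clip(mr, 0.0, 1.0)
    mr[0] = 1.0  # the initial weighing defines M0
    trace = generate_temperature_trace(spec, temperature_c, times_min)
    return DryingCurve(
        times_h=times_min / 60.0,
        moisture=mr * spec.initial_moisture,
        surface_temperature=trace,
        method=spec.method,
        temperature=temperature_c,
    )


def generate_temperature_trace(
    spec: SyntheticSpec, temperature_c: float, times_min: Sequence[float]
) -> np.ndarray:
    """First-order-lag surface temperature toward the drying set point.

    T(t) = T_set - (T_set - T0) exp(-t/tau) + N(0, sigma_T); emulates the
    rapid initial heating and plateau of the monitored surface temperature.
    """
    t = np.asarray(times_min, dtype=float)
    tau = spec.trace_tau_min or spec.defaults["tau_min"]
    trace = temperature_c - (temperature_c - spec.initial_temperature) * np.exp(-t / tau)
    if spec.trace_noise:
        rng = spec._rng(int(round(temperature_c * 10)), 2)
        trace = trace + rng.normal(0.0, spec.trace_noise, size=trace.shape)
    return trace


def generate_quality_table(
    specs: "SyntheticSpec | Sequence[SyntheticSpec]",
    outlier: "tuple | None" = None,
) -> tuple[QualityTable, pd.DataFrame]:
    """Replicate-sampled quality table plus replicate-level color readings.

    ``specs`` is one spec (its seed governs all three methods) or one per
    method; every method x temperature treatment receives indicator means
    from the study-shaped response profile with Gaussian replicate scatter.
    ``outlier`` = (treatment, channel, n_sigma) injects a deviant color
    replicate (channel in {"L", "a", "b"}) into the first replicate for
    outlier-screening exercises.

    Returns ``(table, colors)`` where ``colors`` has one row per replicate
    with columns treatment/replicate/L/a/b.
    """
    if isinstance(specs, SyntheticSpec):
        spec_by_method = {m: replace(specs, method=m) for m in METHOD_DEFAULTS}
    else:
        spec_by_method = {s.method: s for s in specs}

    mean_rows, sd_rows, color_rows, index = [], [], [], []
    for (method, temp), indicators in QUALITY_PROFILE.items():
        spec = spec_by_method.get(method)
        if spec is None:
            continue
        treatment = f"{method}-{temp:g}"
        rng = spec._rng(int(temp * 10), 3)
        n_rep = spec.n_indicator_replicates
        scale = spec.replicate_sd_scale
        reps = {
            col: rng.normal(mu, scale * REPLICATE_SD[col], size=n_rep)
            for col, mu in zip(INDICATOR_COLUMNS, indicators)
        }
        reps["dehiscence_rate"] = np.clip(reps["dehiscence_rate"], 0.0, 100.0)
        reps["volatile_oil"] = np.maximum(reps["volatile_oil"], 0.0)
        mean_rows.append([reps[c].mean() for c in INDICATOR_COLUMNS])
        sd_rows.append([reps[c].std(ddof=1) for c in INDICATOR_COLUMNS])
        index.append(treatment)

        lab_mean = COLOR_PROFILE[(method, temp)]
        lab = rng.normal(lab_mean, scale * REPLICATE_SD["color"],
                         size=(spec.n_color_replicates, 3))
        if outlier is not None and outlier[0] == treatment:
            channel = {"L": 0, "a": 1, "b": 2}[outlier[1]]
            lab[0, channel] += outlier[2] * REPLICATE_SD["color"]
        for r, (L, a, b) in enumerate(lab):
            color_rows.append(
                {"treatment": treatment, "replicate": r, "L": L, "a": a, "b": b}
            )

    means = pd.DataFrame(mean_rows, index=index, columns=list(INDICATOR_COLUMNS))
    sds = pd.DataFrame(sd_rows, index=index, columns=list(INDICATOR_COLUMNS))
    colors = pd.DataFrame(color_rows)
    return QualityTable(means=means, sds=sds), colors
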