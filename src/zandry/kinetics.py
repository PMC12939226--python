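"""Thin-layer drying kinetics: moisture ratio, drying rate, Page and Arrhenius fits.

The drying-progress variable is the moisture ratio MR = M_t / M_0 (dry-basis
moisture normalized to its initial value).  Thin-layer curves are fitted to
the Page model MR = exp(-k t^n) with t in minutes, and the temperature
dependence of the rate constant k is summarized by an apparent activation
energy through the Arrhenius law k = k0 exp(-Ea / (R T)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "R_GAS",
    "DryingCurve",
    "PageFit",
    "ArrheniusFit",
    "moisture_ratio",
    "drying_rate",
    "fit_page",
    "fit_arrhenius",
]

#: Universal gas constant, J/(mol*K).
R_GAS = 8.314

_PAGE_N_BOUNDS = (0.2, 4.0)


@dataclass
class DryingCurve:
    """A gravimetric drying curve: dry-basis moisture versus time in hours.

    ``surface_temperature`` (degC, same length) is optional; ``method`` and
    ``temperature`` are labels (drying mode and set temperature in degC).
    """

    times_h: np.ndarray
    moisture: np.ndarray
    surface_temperature: Optional[np.ndarray] = None
    method: str = ""
    temperature: Optional[float] = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.moisture = np.asarray(self.moisture, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.shape != self.moisture.shape:
            raise ValueError("times and moisture must be matching 1-D arrays")
        if len(self.times_h) and self.times_h[0] != 0.0:
            raise ValueError("curve must start at t = 0")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.moisture) and self.moisture[0] <= 0:
            raise ValueError("initial moisture must be positive")
        if np.any(self.moisture < 0):
            raise ValueError("moisture must be non-negative")
        if self.surface_temperature is not None:
            self.surface_temperature = np.asarray(self.surface_temperature, float)
            if self.surface_temperature.shape != self.times_h.shape:
                raise ValueError("surface_temperature length mismatch")

    @property
    def times_min(self) -> np.ndarray:
        return self.times_h * 60.0

    @property
    def initial_moisture(self) -> float:
        return float(self.moisture[0])


@dataclass(frozen=True)
class PageFit:
    """Page-model parameters with goodness of fit (k in 1/min)."""

    k: float
    n: float
    r2: float
    rmse: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("rate constant k must be positive")
        if not _PAGE_N_BOUNDS[0] <= self.n <= _PAGE_N_BOUNDS[1]:
            raise ValueError("Page exponent n outside fit bounds")

    def predict(self, times_min: np.ndarray) -> np.ndarray:
        t = np.asarray(times_min, dtype=float)
        return np.exp(-self.k * np.power(t, self.n))


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius summary of rate constants: k0 (1/min), Ea (J/mol), R^2."""

    k0: float
    ea: float
    r2: float

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("pre-exponential factor must be positive")

    def predict(self, temperature_c: "float | np.ndarray") -> "float | np.ndarray":
        t_k = np.asarray(temperature_c, dtype=float) + 273.15
        k = self.k0 * np.exp(-self.ea / (R_GAS * t_k))
        return k if k.ndim else float(k)


def moisture_ratio(curve: DryingCurve) -> np.ndarray:
    """MR_t = M_t / M_0 (dimensionless, MR[0] == 1)."""
    m0 = curve.initial_moisture
    if m0 <= 0:
        raise ValueError("initial moisture must be positive")
    return curve.moisture / m0


def drying_rate(curve: DryingCurve) -> tuple[np.ndarray, np.ndarray]:
    """Interval drying rate DR = (M_t1 - M_t2)/(t2 - t1), kg/kg per hour.

    Returns ``(midpoints_h, rates)`` with one value per consecutive interval.
    """
    dt = np.diff(curve.times_h)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    rates = -np.diff(curve.moisture) / dt
    midpoints = curve.times_h[:-1] + 0.5 * dt
    return midpoints, rates


def _r2_rmse(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    resid = observed - predicted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return r2, float(np.sqrt(np.mean(resid**2)))


def fit_page(
    curve_or_mr: "DryingCurve | Sequence[float]",
    times_min: Optional[Sequence[float]] = None,
) -> PageFit:
    """Nonlinear least-squares fit of MR = exp(-k t^n), t in minutes.

    Accepts either a :class:`DryingCurve` (times converted from hours) or an
    MR series with explicit ``times_min``.  Initialized from the log-log
    linearization ln(-ln MR) = ln k + n ln t over interior points; k and n
    are estimated jointly, n bounded to [0.2, 4].
    """
    if isinstance(curve_or_mr, DryingCurve):
        mr = moisture_ratio(curve_or_mr)
        t = curve_or_mr.times_min
    else:
        if times_min is None:
            raise ValueError("times_min required when passing a bare MR series")
        mr = np.asarray(curve_or_mr, dtype=float)
        t = np.asarray(times_min, dtype=float)
    if mr.shape != t.shape or mr.ndim != 1:
        raise ValueError("MR and time arrays must match")
    if len(mr) < 4:
        raise ValueError("at least 4 points are required for the Page fit")
    if np.any(mr <= 0) or np.any(mr > 1 + 1e-9):
        raise ValueError("MR values must lie in (0, 1]")

    interior = (t > 0) & (mr < 1.0)
    if interior.sum() < 2:
        raise ValueError("degenerate fit: the curve shows no drying")
    # log-log initializer; MR >= 1 noise is clipped here only
    mr_init = np.minimum(mr[interior], 1.0 - 1e-9)
    y = np.log(-np.log(mr_init))
    x = np.log(t[interior])
    n0, lnk0 = np.polyfit(x, y, 1)
    n0 = float(np.clip(n0, *_PAGE_N_BOUNDS))
    k0 = float(np.exp(np.clip(lnk0, -50.0, 10.0)))

    def resid(theta):
        ln_k, n = theta
        return np.exp(-np.exp(ln_k) * np.power(t, n)) - mr

    sol = least_squares(
        resid,
        x0=[np.log(k0), n0],
        bounds=([-50.0, _PAGE_N_BOUNDS[0]], [10.0, _PAGE_N_BOUNDS[1]]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    k_hat, n_hat = float(np.exp(sol.x[0])), float(sol.x[1])
    r2, rmse = _r2_rmse(mr, np.exp(-k_hat * np.power(t, n_hat)))
    return PageFit(k=k_hat, n=n_hat, r2=r2, rmse=rmse)


def fit_arrhenius(
    fits_or_k: "Sequence[PageFit] | Sequence[float]",
    temperatures_c: Sequence[float],
) -> ArrheniusFit:
    """Ordinary least squares of ln k on 1/T_K; Ea = -slope * R.

    ``fits_or_k`` is a sequence of :class:`PageFit` (their k is used) or of
    rate constants directly; ``temperatures_c`` are the matching drying
    temperatures in degC (>= 2 distinct values required).
    """
    ks = np.array(
        [f.k if isinstance(f, PageFit) else float(f) for f in fits_or_k], dtype=float
    )
    temps = np.asarray(temperatures_c, dtype=float)
    if ks.shape != temps.shape or ks.ndim != 1:
        raise ValueError("rate constants and temperatures must match")
    if len(np.unique(temps)) < 2:
        raise ValueError("at least 2 distinct temperatures are required")
    if np.any(ks <= 0):
        raise ValueError("all rate constants must be positive")
    inv_t = 1.0 / (temps + 273.15)
    slope, intercept = np.polyfit(inv_t, np.log(ks), 1)
    predicted = slope * inv_t + intercept
    r2, _ = _r2_rmse(np.log(ks), predicted)
    if np.allclose(np.log(ks), np.log(ks)[0]):
        r2 = 1.0  # zero-slope, perfectly explained degenerate case
    return ArrheniusFit(k0=float(np.exp(intercept)), ea=float(-slope * R_GAS), r2=r2)
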