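"""Physical properties and closure relations for Z. bungeanum drying.

This module is the single source of truth for the material constants of the
pericarp tissue (density, heat capacity, dielectric data, Antoine constants,
...) and for the closure relations the transport solver needs: saturation
vapor pressure, moisture-dependent liquid diffusivity, the volumetric heat
sources of the three heating modes, and the chamber-pressure schedule of
pulsed-vacuum operation.

Units are SI with two deliberate exceptions that follow field convention:
temperatures are handled in degrees Celsius throughout the solver and
converted to kelvin only inside the Antoine/Arrhenius evaluations, and
pressures are in kPa (absolute).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ATMOSPHERIC_PRESSURE_KPA",
    "DryingMode",
    "MaterialProperties",
    "PulsationSchedule",
    "antoine_saturation_pressure",
    "moisture_diffusivity",
    "microwave_volumetric_source",
    "infrared_volumetric_source",
    "chamber_pressure",
]

#: Standard atmosphere, kPa.
ATMOSPHERIC_PRESSURE_KPA = 101.325

#: Floor applied to the empirical diffusivity correlation, m^2/s.  The
#: correlation is negative for dry-basis moisture above exp(-8.247/39.41)
#: ~= 0.811 kg/kg; the floor keeps the moisture operator parabolic there.
DIFFUSIVITY_FLOOR = 1e-12


class DryingMode(str, enum.Enum):
    """Heating mode: hot air, pulsed-vacuum infrared, or microwave vacuum."""

    HAD = "HAD"
    PVD = "PVD"
    MVD = "MVD"

    @classmethod
    def coerce(cls, value: "DryingMode | str") -> "DryingMode":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper())


@dataclass(frozen=True)
class MaterialProperties:
    """Physical constants of the fruit tissue plus calibration scalars.

    Defaults reproduce the operating-parameter table of the study this
    package models.  ``diffusivity_scale`` (m^2*K) and ``absorbed_fraction``
    are calibration scalars: the first scales the empirical diffusivity
    correlation, the second multiplies the nominal source power and is
    normally refined against a reference drying curve
    (:func:`zandry.simulator.calibrate_source_fraction`).
    """

    density: float = 1030.0                    # kg/m^3
    specific_heat: float = 1569.0              # J/(kg*degC)
    thermal_conductivity: float = 0.55         # W/(m*degC)
    latent_heat: float = 2.32e6                # J/kg
    liquid_water_concentration: float = 707.61  # initial kg water / m^3
    evaporation_rate_constant: float = 1e-6    # dimensionless rate scalar
    absorption_coefficient: float = 0.9        # infrared absorptivity, 0-1
    radiation_intensity: float = 6.54e3        # W/m^2 incident infrared flux
    microwave_frequency: float = 2.45          # GHz (metadata)
    dielectric_constant: float = 40.0          # eps' (metadata)
    dielectric_loss: float = 17.0              # eps'' (metadata)
    antoine_a: float = 7.8087
    antoine_b: float = 1007.839
    antoine_c: float = -166.3583
    diffusivity_scale: float = 1e-9            # m^2*K, calibration scalar
    power_density: float = 8.0                 # W per g of sample (MVD)
    absorbed_fraction: float = 0.01            # eta, calibration factor
    ir_penetration_depth: float = 2e-3         # m, Beer-Lambert decay length

    def __post_init__(self) -> None:
        positive = (
            "density", "specific_heat", "thermal_conductivity", "latent_heat",
            "liquid_water_concentration", "evaporation_rate_constant",
            "radiation_intensity", "microwave_frequency", "dielectric_constant",
            "dielectric_loss", "antoine_a", "antoine_b", "power_density",
            "ir_penetration_depth",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.diffusivity_scale < 0:
            raise ValueError("diffusivity_scale must be non-negative")
        if not 0 < self.absorption_coefficient <= 1:
            raise ValueError("absorption_coefficient must be in (0, 1]")
        if not 0 < self.absorbed_fraction <= 1:
            raise ValueError("absorbed_fraction must be in (0, 1]")

    def replace(self, **changes) -> "MaterialProperties":
        """Return a copy with ``changes`` applied (frozen dataclass helper)."""
        import dataclasses

        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PulsationSchedule:
    """Periodic vacuum/atmospheric pressure cycle of the pulsed-vacuum dryer.

    The chamber alternates between a vacuum hold and an atmospheric hold;
    switches are smoothed with a quintic ramp (continuous second derivative)
    whose width is ``transition_width`` times the cycle period.
    """

    vacuum_duration: float = 900.0        # s
    atmospheric_duration: float = 300.0   # s
    vacuum_pressure: float = 10.0         # kPa absolute
    atmospheric_pressure: float = ATMOSPHERIC_PRESSURE_KPA
    transition_width: float = 0.08        # fraction of the cycle period

    def __post_init__(self) -> None:
        if self.vacuum_duration <= 0 or self.atmospheric_duration <= 0:
            raise ValueError("phase durations must be positive")
        if not self.vacuum_pressure < self.atmospheric_pressure:
            raise ValueError("vacuum_pressure must be below atmospheric_pressure")
        if not 0 < self.transition_width < 0.5:
            raise ValueError("transition_width must be in (0, 0.5)")

    @property
    def period(self) -> float:
        return self.vacuum_duration + self.atmospheric_duration


def antoine_saturation_pressure(
    temperature_k: "float | np.ndarray", props: MaterialProperties
) -> "float | np.ndarray":
    """Saturation vapor pressure in kPa at absolute temperature ``temperature_k``.

    Uses log10(p_kPa) = A - B/(C + T_K) with the tissue-specific constant
    set; strictly increasing in temperature.  Raises ``ValueError`` when
    ``C + T <= 0`` (below the correlation's validity range).
    """
    t = np.asarray(temperature_k, dtype=float)
    denom = props.antoine_c + t
    if np.any(denom <= 0.0):
        raise ValueError(
            "temperature below the validity range of the Antoine correlation"
        )
    p = 10.0 ** (props.antoine_a - props.antoine_b / denom)
    return p if p.ndim else float(p)


def moisture_diffusivity(
    moisture_db: "float | np.ndarray",
    temperature_k: "float | np.ndarray",
    props: MaterialProperties,
    floor: float = DIFFUSIVITY_FLOOR,
) -> "float | np.ndarray":
    """Liquid-water diffusivity, m^2/s, from the empirical correlation.

    D_w = r2 * (-39.41 ln(M) - 8.247) / T_K, clamped below at ``floor``
    (the correlation is negative for M > ~0.811 kg/kg dry basis).
    ``moisture_db`` is dry-basis moisture, kg water / kg dry solids.
    """
    m = np.asarray(moisture_db, dtype=float)
    t = np.asarray(temperature_k, dtype=float)
    if np.any(m <= 0) or np.any(t <= 0):
        raise ValueError("moisture and temperature must be strictly positive")
    raw = props.diffusivity_scale * (-39.41 * np.log(m) - 8.247) / t
    d = np.maximum(raw, floor)
    return d if d.ndim else float(d)


def microwave_volumetric_source(
    props: MaterialProperties, eta: "float | None" = None
) -> float:
    """Uniform volumetric microwave heat source, W/m^3.

    The dielectric field expression is deliberately not evaluated (no
    electromagnetic solve); the rated power density per unit sample mass is
    its macroscopic surrogate, scaled by the absorbed fraction ``eta``:
    Q = eta * P_mw[W/g] * 1000 * rho_m.
    """
    if eta is None:
        eta = props.absorbed_fraction
    return eta * props.power_density * 1000.0 * props.density


def infrared_volumetric_source(
    depth: "float | np.ndarray",
    props: MaterialProperties,
    eta: "float | None" = None,
    penetration_depth: "float | None" = None,
) -> "float | np.ndarray":
    """Beer-Lambert volumetric infrared deposition at ``depth`` below the surface.

    q(z) = eta * kappa * l_i / delta * exp(-z/delta), W/m^3.  The depth
    integral over [0, inf) equals the absorbed surface flux eta*kappa*l_i
    (flux conservation).  This is the planar form; the solver uses a
    spherically convergent variant on spherical geometry.
    """
    if eta is None:
        eta = props.absorbed_fraction
    delta = props.ir_penetration_depth if penetration_depth is None else penetration_depth
    z = np.asarray(depth, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    q = eta * props.absorption_coefficient * props.radiation_intensity / delta * np.exp(
        -z / delta
    )
    return q if q.ndim else float(q)


def _smoothstep5(x: np.ndarray) -> np.ndarray:
    """Quintic smoothstep on [0, 1]: C2-continuous ramp."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * x * (x * (6.0 * x - 15.0) + 10.0)


def chamber_pressure(
    t: "float | np.ndarray",
    schedule: PulsationSchedule,
    mode: "DryingMode | str",
) -> "float | np.ndarray":
    """Chamber (total) pressure in kPa at time ``t`` seconds.

    HAD holds atmospheric pressure, MVD holds the vacuum pressure, and PVD
    follows the periodic smoothed square wave of the pulsation schedule:
    a vacuum hold followed by an atmospheric hold, with quintic ramps of
    width ``transition_width * period`` centered on each switch, giving a
    C2-continuous pressure signal bounded by the two hold pressures.
    """
    mode = DryingMode.coerce(mode)
    scalar = np.ndim(t) == 0
    times = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(times < 0):
        raise ValueError("time must be non-negative")
    if mode is DryingMode.HAD:
        p = np.full_like(times, schedule.atmospheric_pressure)
    elif mode is DryingMode.MVD:
        p = np.full_like(times, schedule.vacuum_pressure)
    else:
        period = schedule.period
        w = schedule.transition_width * period
        half = 0.5 * w
        vd = schedule.vacuum_duration
        theta = np.mod(times, period)
        p_vac, p_atm = schedule.vacuum_pressure, schedule.atmospheric_pressure
        p = np.empty_like(theta)
        # ramp down (atm -> vac) centered on theta = 0 (== period)
        down_lead = theta >= period - half
        down_tail = theta < half
        # ramp up (vac -> atm) centered on theta = vd
        up = (theta >= vd - half) & (theta < vd + half)
        s_lead = _smoothstep5((theta - (period - half)) / w)
        s_tail = _smoothstep5((theta + half) / w)
        s_up = _smoothstep5((theta - (vd - half)) / w)
        p[:] = p_vac
        hold_atm = (theta >= vd + half) & (theta < period - half)
        p[hold_atm] = p_atm
        p[down_lead] = p_atm + (p_vac - p_atm) * s_lead[down_lead]
        p[down_tail] = p_atm + (p_vac - p_atm) * s_tail[down_tail]
        p[up] = p_vac + (p_atm - p_vac) * s_up[up]
    return float(p[0]) if scalar else p
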