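"""1-D finite-volume solver for coupled heat and moisture transport during drying.

The tissue is a rigid, homogeneous porous medium on a 1-D spherical (berry)
or planar (bulk layer) domain.  The solver advances

    rho_m C_p dT/dt = div(k_p grad T) + Q_mode - L_v G_evap
    dC_w/dt        = div(D_w grad C_w) - G_evap

with mode-specific volumetric sources (microwave: uniform; infrared:
Beer-Lambert deposition), a convective thermal boundary, a convective
moisture boundary whose outflux evaporates at the surface (latent sink in
the thermal boundary), and an evaporation sink driven by the gap between
the local saturation pressure and the pressure opposing evaporation
(chamber pressure under vacuum; ambient vapor partial pressure in hot air,
where the chamber holds dry air at ~101 kPa total but only ~1.6 kPa of
vapor).

Discretization: cell-centered finite volumes with harmonic-mean interface
diffusivities, implicit Euler in time with Picard iteration and adaptive
step halving.  Energy and mass ledgers are assembled from the same discrete
operators as the update, so their closure residuals are at solver precision
on every run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import solve_banded

from .kinetics import DryingCurve
from .properties import (
    ATMOSPHERIC_PRESSURE_KPA,
    DryingMode,
    MaterialProperties,
    PulsationSchedule,
    antoine_saturation_pressure,
    chamber_pressure,
    moisture_diffusivity,
)

__all__ = [
    "SimulationConfig",
    "FieldState",
    "SimulationResult",
    "SolverError",
    "CalibrationError",
    "CalibrationResult",
    "evaporation_sink",
    "simulate_drying",
    "extract_core_surface",
    "calibrate_source_fraction",
]

_KELVIN = 273.15


class SolverError(RuntimeError):
    """Implicit step failed to converge at the minimum step size."""

    def __init__(self, message: str, state: "FieldState | None" = None):
        super().__init__(message)
        self.state = state


class CalibrationError(RuntimeError):
    """Calibration could not bracket a minimum; widen the parameter bounds."""


@dataclass
class SimulationConfig:
    """Drying scenario description.

    ``air_temperature`` is the drying-air set point for hot air and the
    chamber-gas set temperature for the vacuum modes (degC).  Geometry is a
    sphere (``characteristic_size`` = radius; berry-level fields) or a slab
    (= half-thickness; bulk-layer fields), with the symmetry plane/center at
    coordinate 0 and the exposed surface at ``characteristic_size``.
    """

    mode: DryingMode = DryingMode.MVD
    air_temperature: float = 50.0            # degC
    geometry: str = "sphere"                 # "sphere" | "slab"
    characteristic_size: float = 2.5e-3      # m (radius or half-thickness)
    n_nodes: int = 40
    t_end: float = 7200.0                    # s
    max_step: float = 60.0                   # s
    rel_tol: float = 0.01
    abs_tol: float = 0.001
    initial_temperature: float = 20.0        # degC
    initial_moisture: float = 2.03           # kg/kg dry basis
    target_moisture: float = 0.11            # kg/kg dry basis
    equilibrium_moisture: float = 0.01       # kg/kg dry basis
    heat_transfer_coeff: float = 25.0        # W/(m^2*degC)
    mass_transfer_coeff: float = 0.025       # m/s
    ambient_vapor_pressure: float = 1.57     # kPa, opposes evaporation in hot air
    #: thermostat band (degC): the volumetric source ramps linearly to zero
    #: between the set temperature and set + band, mirroring the regulated
    #: power delivery of the real dryers (whose set point is a temperature,
    #: not a power); None runs the source unregulated.
    source_control_band: Optional[float] = 2.0
    schedule: PulsationSchedule = field(default_factory=PulsationSchedule)
    seed: int = 0                            # reserved (solver is deterministic)

    def __post_init__(self) -> None:
        self.mode = DryingMode.coerce(self.mode)
        if self.geometry not in ("sphere", "slab"):
            raise ValueError("geometry must be 'sphere' or 'slab'")
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be at least 10")
        if self.t_end <= 0 or self.max_step <= 0:
            raise ValueError("t_end and max_step must be positive")
        if not 0 < self.target_moisture < self.initial_moisture:
            raise ValueError("target_moisture must lie in (0, initial_moisture)")
        if self.characteristic_size <= 0:
            raise ValueError("characteristic_size must be positive")
        if self.heat_transfer_coeff < 0 or self.mass_transfer_coeff < 0:
            raise ValueError("transfer coefficients must be non-negative")


@dataclass
class FieldState:
    """Nodal fields at one instant (temperatures degC, concentrations kg/m^3)."""

    time: float
    coordinates: np.ndarray          # cell-center coordinate, m (0 = core)
    nodal_temperature: np.ndarray
    nodal_water_concentration: np.ndarray
    dry_matter_density: float        # kg dry solids / m^3 (C_w = M * rho_dry)
    chamber_pressure: float
    geometry: str = "sphere"

    @property
    def nodal_moisture(self) -> np.ndarray:
        """Dry-basis moisture per node, kg/kg."""
        return self.nodal_water_concentration / self.dry_matter_density


@dataclass
class SimulationResult:
    """Field histories, summary series and conservation ledgers of one run."""

    config: SimulationConfig
    props: MaterialProperties
    times: np.ndarray                    # s, accepted steps (first entry 0)
    coordinates: np.ndarray              # cell centers, m
    temperature_history: np.ndarray      # (n_times, n_nodes) degC
    concentration_history: np.ndarray    # (n_times, n_nodes) kg/m^3
    surface_temperature: np.ndarray      # face value, degC
    core_temperature: np.ndarray         # innermost cell, degC
    mr_mean: np.ndarray                  # volume-mean moisture ratio
    delta_mr: np.ndarray                 # core minus surface-shell MR
    chamber_pressure_series: np.ndarray  # kPa
    drying_time_to_target: Optional[float]
    energy_ledger: dict
    mass_ledger: dict
    dry_matter_density: float

    def state_at(self, t: float) -> FieldState:
        """Linearly interpolated field state at time ``t`` seconds."""
        t = float(np.clip(t, self.times[0], self.times[-1]))
        j = int(np.searchsorted(self.times, t, side="right") - 1)
        j = min(j, len(self.times) - 2) if len(self.times) > 1 else 0
        if len(self.times) == 1 or self.times[j + 1] == self.times[j]:
            w = 0.0
        else:
            w = (t - self.times[j]) / (self.times[j + 1] - self.times[j])
        temp = (1 - w) * self.temperature_history[j] + w * self.temperature_history[j + 1]
        conc = (1 - w) * self.concentration_history[j] + w * self.concentration_history[j + 1]
        return FieldState(
            time=t,
            coordinates=self.coordinates,
            nodal_temperature=temp,
            nodal_water_concentration=conc,
            dry_matter_density=self.dry_matter_density,
            chamber_pressure=float(np.interp(t, self.times, self.chamber_pressure_series)),
            geometry=self.config.geometry,
        )

    def series_at(self, t: float) -> dict:
        """Summary quantities interpolated at time ``t`` seconds."""
        return {
            name: float(np.interp(t, self.times, series))
            for name, series in (
                ("surface_temperature", self.surface_temperature),
                ("core_temperature", self.core_temperature),
                ("mr_mean", self.mr_mean),
                ("delta_mr", self.delta_mr),
                ("chamber_pressure", self.chamber_pressure_series),
            )
        }

    def to_summary_frame(self):
        """Tidy summary series as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "mr_mean": self.mr_mean,
                "t_surface_c": self.surface_temperature,
                "t_core_c": self.core_temperature,
                "delta_mr": self.delta_mr,
                "chamber_pressure_kpa": self.chamber_pressure_series,
            }
        )

    def to_field_frame(self):
        """Tidy nodal field history as a pandas DataFrame."""
        import pandas as pd

        n_t, n_x = self.temperature_history.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, n_x),
                "node_index": np.tile(np.arange(n_x), n_t),
                "coordinate_m": np.tile(self.coordinates, n_t),
                "temperature_c": self.temperature_history.ravel(),
                "water_concentration": self.concentration_history.ravel(),
                "moisture_db": self.concentration_history.ravel() / self.dry_matter_density,
            }
        )


def evaporation_sink(
    temperature_k: "float | np.ndarray",
    water_concentration: "float | np.ndarray",
    opposing_pressure_kpa: "float | np.ndarray",
    props: MaterialProperties,
    moisture_db: "float | np.ndarray | None" = None,
    equilibrium_moisture: float = 0.0,
) -> "float | np.ndarray":
    """Volumetric evaporation rate, kg/(m^3 s).

    G_evap = K_evap * C_w * max(0, p_sat(T) - p_opp) / p_atm, zero where the
    dry-basis moisture is at or below the equilibrium value (no free water).
    The associated volumetric heat sink is Q_evap = L_v * G_evap.
    """
    p_sat = antoine_saturation_pressure(temperature_k, props)
    driving = np.maximum(0.0, p_sat - np.asarray(opposing_pressure_kpa, float))
    g = (
        props.evaporation_rate_constant
        * np.asarray(water_concentration, float)
        * driving
        / ATMOSPHERIC_PRESSURE_KPA
    )
    if moisture_db is not None:
        g = np.where(np.asarray(moisture_db, float) <= equilibrium_moisture, 0.0, g)
    return g if np.ndim(g) else float(g)


# ---------------------------------------------------------------------------
# internal grid / source helpers


class _Grid:
    """Cell-centered finite-volume grid on [0, L]; sphere areas per steradian."""

    def __init__(self, geometry: str, size: float, n: int):
        self.geometry = geometry
        self.size = size
        self.n = n
        self.faces = np.linspace(0.0, size, n + 1)
        self.centers = 0.5 * (self.faces[:-1] + self.faces[1:])
        if geometry == "sphere":
            self.face_area = self.faces**2
            self.volumes = np.diff(self.faces**3) / 3.0
        else:
            self.face_area = np.ones(n + 1)
            self.volumes = np.diff(self.faces)
        self.dxc = np.diff(self.centers)              # center-to-center spacing
        self.surface_area = self.face_area[-1]
        self.d_half = self.faces[-1] - self.centers[-1]  # half cell at surface


def _ir_deposition(grid: _Grid, props: MaterialProperties, eta: float) -> np.ndarray:
    """Cell-averaged Beer-Lambert infrared deposition, W/m^3.

    Slab: planar attenuation from the exposed face, plus the transmitted
    tail of the opposite face of the symmetric layer.  Sphere: spherically
    convergent attenuation (deposition ~ (R/r)^2 e^{-(R-r)/delta}), the
    geometric focusing behind the observed core-concentrated infrared
    heating; the fraction reaching the center continues outward on a second
    pass.  Both forms conserve the absorbed flux exactly on any mesh.
    """
    delta = props.ir_penetration_depth
    flux = eta * props.absorption_coefficient * props.radiation_intensity
    L = grid.size
    if grid.geometry == "slab":
        z_lo = L - grid.faces[1:]   # shallow depth of each cell
        z_hi = L - grid.faces[:-1]  # deep depth of each cell
        dep = flux * (
            (np.exp(-z_lo / delta) - np.exp(-z_hi / delta))
            + (np.exp(-(2 * L - z_hi) / delta) - np.exp(-(2 * L - z_lo) / delta))
        )
    else:
        # cumulative absorbed inside radius r, per steradian
        def cum(r):
            inward = np.exp(-(L - r) / delta) - np.exp(-L / delta)
            outward = np.exp(-L / delta) * (1.0 - np.exp(-r / delta))
            return flux * L**2 * (inward + outward)

        dep = cum(grid.faces[1:]) - cum(grid.faces[:-1])
    return dep / grid.volumes


def _tridiag_solve(lower, main, upper, rhs):
    n = len(main)
    ab = np.zeros((3, n))
    ab[0, 1:] = upper
    ab[1, :] = main
    ab[2, :-1] = lower
    return solve_banded((1, 1), ab, rhs)


# ---------------------------------------------------------------------------
# main solver


def simulate_drying(
    config: SimulationConfig, props: MaterialProperties
) -> SimulationResult:
    """Run the coupled drying simulation described by ``config`` and ``props``.

    Terminates at ``t_end`` or when the volume-mean dry-basis moisture
    reaches ``target_moisture``, whichever comes first.  Raises
    :class:`SolverError` if the implicit step cannot converge after
    bisection to the minimum step.
    """
    grid = _Grid(config.geometry, config.characteristic_size, config.n_nodes)
    n = grid.n
    rho_dry = props.liquid_water_concentration / config.initial_moisture
    c_eq = config.equilibrium_moisture * rho_dry
    rho_cp = props.density * props.specific_heat
    k_p = props.thermal_conductivity
    lv = props.latent_heat
    m0 = config.initial_moisture
    gate_width = max(1e-6, 0.01 * m0)

    mode = config.mode
    if mode is DryingMode.MVD:
        q_source = np.full(n, props.absorbed_fraction * props.power_density * 1000.0 * props.density)
    elif mode is DryingMode.PVD:
        q_source = _ir_deposition(grid, props, props.absorbed_fraction)
    else:
        q_source = np.zeros(n)

    # constant thermal conductances
    g_t_faces = grid.face_area[1:-1] * k_p / grid.dxc
    h_t = config.heat_transfer_coeff
    if h_t > 0:
        g_t_bnd = grid.surface_area / (grid.d_half / k_p + 1.0 / h_t)
    else:
        g_t_bnd = 0.0
    h_m = config.mass_transfer_coeff

    core_mask = grid.centers / grid.size <= 0.5
    surf_mask = grid.centers / grid.size >= 0.9
    v_core = grid.volumes[core_mask].sum()
    v_surf = grid.volumes[surf_mask].sum()
    v_tot = grid.volumes.sum()

    temp = np.full(n, config.initial_temperature, dtype=float)
    conc = np.full(n, props.liquid_water_concentration, dtype=float)

    def p_opposing(t_now: float) -> float:
        if mode is DryingMode.HAD:
            return config.ambient_vapor_pressure
        return float(chamber_pressure(t_now, config.schedule, mode))

    def face_temperature(t_arr, j_m):
        # surface-face value from the discrete flux balance:
        # k (T_N - T_f)/d_half = h_t (T_f - T_a) + L_v J_m / A_s
        a = k_p / grid.d_half
        return (a * t_arr[-1] + h_t * config.air_temperature - lv * j_m / grid.surface_area) / (
            a + h_t
        )

    def summaries(t_arr, c_arr, j_m, t_now):
        mr = c_arr / rho_dry / m0
        mr_mean = float((mr * grid.volumes).sum() / v_tot)
        d_mr = float(
            (mr[core_mask] * grid.volumes[core_mask]).sum() / v_core
            - (mr[surf_mask] * grid.volumes[surf_mask]).sum() / v_surf
        )
        return mr_mean, d_mr, float(face_temperature(t_arr, j_m)), float(t_arr[0])

    # histories
    times = [0.0]
    temp_hist = [temp.copy()]
    conc_hist = [conc.copy()]
    p0 = float(chamber_pressure(0.0, config.schedule, mode))
    mr_mean0, d_mr0, t_face0, t_core0 = summaries(temp, conc, 0.0, 0.0)
    mr_series = [mr_mean0]
    dmr_series = [d_mr0]
    tsurf_series = [t_face0]
    tcore_series = [t_core0]
    press_series = [p0]

    # ledgers (per steradian for spheres; per unit area for slabs)
    e_source = e_latent = e_bound = 0.0
    m_evap = m_bound = 0.0
    sensible0 = float((rho_cp * (temp - config.initial_temperature) * grid.volumes).sum())

    t_now = 0.0
    dt = min(config.max_step, config.t_end)
    min_step = min(1.0, config.max_step)
    drying_time = None
    max_picard = 30

    while t_now < config.t_end - 1e-9:
        dt = min(dt, config.t_end - t_now)
        t_new = t_now + dt
        p_opp = p_opposing(t_new)
        p_chamber_new = float(chamber_pressure(t_new, config.schedule, mode))

        t_iter = temp.copy()
        c_iter = conc.copy()
        accepted = False
        for _ in range(max_picard):
            t_k = np.clip(t_iter + _KELVIN, -props.antoine_c + 5.0, 600.0)
            m_iter = np.maximum(c_iter, 1e-9) / rho_dry
            p_sat = antoine_saturation_pressure(t_k, props)
            gate = np.clip((m_iter - config.equilibrium_moisture) / gate_width, 0.0, 1.0)
            driving = np.maximum(0.0, p_sat - p_opp)
            g_coef = (
                props.evaporation_rate_constant
                * driving
                / ATMOSPHERIC_PRESSURE_KPA
                * gate
            )  # sink = g_coef * C  (1/s)
            # d(g_coef)/dT for the semi-implicit latent sink (stabilizes the
            # strong evaporative cooling feedback)
            dpsat_dt = p_sat * np.log(10.0) * props.antoine_b / (props.antoine_c + t_k) ** 2
            dg_dt = np.where(
                driving > 0,
                props.evaporation_rate_constant * gate * dpsat_dt / ATMOSPHERIC_PRESSURE_KPA,
                0.0,
            )

            # thermostatted source: full power below the set temperature,
            # ramping to zero across the control band above it; linearized in
            # T inside the implicit solve (the regulation feedback is stiff)
            if config.source_control_band is not None and mode is not DryingMode.HAD:
                band = config.source_control_band
                x = (config.air_temperature + band - t_iter) / band
                ctrl = np.clip(x, 0.0, 1.0)
                in_band = (x > 0.0) & (x < 1.0)
                q_eff = q_source * ctrl
                src_diag = np.where(in_band, q_source / band, 0.0)
            else:
                q_eff = q_source
                src_diag = np.zeros(n)

            d_cell = moisture_diffusivity(np.maximum(m_iter, 1e-9), t_k, props)
            d_face = 2.0 * d_cell[:-1] * d_cell[1:] / (d_cell[:-1] + d_cell[1:])
            g_m_faces = grid.face_area[1:-1] * d_face / grid.dxc
            if h_m > 0:
                g_m_bnd = grid.surface_area / (grid.d_half / d_cell[-1] + 1.0 / h_m)
            else:
                g_m_bnd = 0.0

            # --- moisture solve (implicit) ---
            main = grid.volumes / dt + g_coef * grid.volumes
            main[:-1] += g_m_faces
            main[1:] += g_m_faces
            main[-1] += g_m_bnd
            lower = -g_m_faces
            upper = -g_m_faces
            rhs = grid.volumes / dt * conc
            rhs[-1] += g_m_bnd * c_eq
            c_new = _tridiag_solve(lower, main, upper, rhs)
            j_m = g_m_bnd * (c_new[-1] - c_eq)

            # --- temperature solve (implicit; latent sink linearized in T) ---
            # sink(T) ~= L_v c_new [g(T*) + dg/dT (T - T*)], T* = current iterate
            lat_diag = lv * c_new * dg_dt * grid.volumes
            main_t = rho_cp * grid.volumes / dt + lat_diag + src_diag * grid.volumes
            main_t[:-1] += g_t_faces
            main_t[1:] += g_t_faces
            main_t[-1] += g_t_bnd
            lower_t = -g_t_faces
            upper_t = -g_t_faces
            rhs_t = (
                rho_cp * grid.volumes / dt * temp
                + (q_eff + src_diag * t_iter) * grid.volumes
            )
            rhs_t -= lv * (g_coef - dg_dt * t_iter) * c_new * grid.volumes
            rhs_t[-1] += g_t_bnd * config.air_temperature - lv * j_m
            t_new_arr = _tridiag_solve(lower_t, main_t, upper_t, rhs_t)
            # rates actually entering the discrete T equation (linearized)
            g_effective = g_coef + dg_dt * (t_new_arr - t_iter)
            q_effective = q_eff - src_diag * (t_new_arr - t_iter)

            err_t = float(np.max(np.abs(t_new_arr - t_iter)))
            err_c = float(np.max(np.abs(c_new - c_iter)))
            t_iter, c_iter = t_new_arr, c_new
            # successive-iterate change below tolerance, scaled by the
            # change over the step (rel) with an absolute floor (abs)
            step_t = float(np.max(np.abs(t_iter - temp)))
            step_c = float(np.max(np.abs(c_iter - conc)))
            tol_t = config.abs_tol + config.rel_tol * step_t
            tol_c = config.abs_tol * props.liquid_water_concentration + config.rel_tol * step_c
            if err_t <= tol_t and err_c <= tol_c:
                accepted = True
                break

        if not accepted or np.min(c_iter) < -1e-8:
            if dt <= min_step + 1e-12:
                raise SolverError(
                    f"implicit step failed to converge at t={t_now:.1f}s, dt={dt:.3f}s",
                    FieldState(
                        t_now, grid.centers, temp, conc, rho_dry,
                        p_chamber_new, config.geometry,
                    ),
                )
            dt = max(min_step, 0.5 * dt)
            continue

        c_iter = np.maximum(c_iter, 0.0)

        # exact discrete ledgers from the accepted solve's coefficients
        e_source += float((q_effective * grid.volumes).sum()) * dt
        # the moisture equation removed g_coef*C; the temperature equation
        # removed the linearized g_effective*C -- each ledger mirrors its own
        # discrete equation exactly (the two coincide at Picard convergence)
        m_evap += float((g_coef * c_iter * grid.volumes).sum()) * dt
        e_latent += lv * (float((g_effective * c_iter * grid.volumes).sum()) + j_m) * dt
        e_bound += g_t_bnd * (t_iter[-1] - config.air_temperature) * dt
        m_bound += j_m * dt

        temp, conc, t_now = t_iter, c_iter, t_new
        times.append(t_now)
        temp_hist.append(temp.copy())
        conc_hist.append(conc.copy())
        mr_mean, d_mr, t_face, t_core = summaries(temp, conc, j_m, t_now)
        mr_series.append(mr_mean)
        dmr_series.append(d_mr)
        tsurf_series.append(t_face)
        tcore_series.append(t_core)
        press_series.append(p_chamber_new)

        if mr_mean * m0 <= config.target_moisture and drying_time is None:
            prev_m = mr_series[-2] * m0
            frac = (prev_m - config.target_moisture) / max(prev_m - mr_mean * m0, 1e-30)
            drying_time = times[-2] + frac * (times[-1] - times[-2])
            break
        dt = min(config.max_step, dt * 1.5)

    sensible = float((rho_cp * (temp - config.initial_temperature) * grid.volumes).sum())
    # the boundary term may be a net gain (T_s < T_a), hence the signed sum
    scale = max(abs(e_source) + abs(e_bound) + abs(sensible) + abs(e_latent), 1e-12)
    energy_ledger = {
        "source_in_j": e_source,
        "sensible_j": sensible - sensible0,
        "latent_j": e_latent,
        "boundary_loss_j": e_bound,
        "residual_rel": abs(e_source - (sensible - sensible0) - e_latent - e_bound) / scale,
    }
    water0 = props.liquid_water_concentration * v_tot
    water_now = float((conc * grid.volumes).sum())
    mscale = max(water0, 1e-12)
    mass_ledger = {
        "initial_water_kg": water0,
        "remaining_water_kg": water_now,
        "evaporated_kg": m_evap,
        "boundary_flux_kg": m_bound,
        "residual_rel": abs(water0 - water_now - m_evap - m_bound) / mscale,
    }

    return SimulationResult(
        config=config,
        props=props,
        times=np.array(times),
        coordinates=grid.centers,
        temperature_history=np.array(temp_hist),
        concentration_history=np.array(conc_hist),
        surface_temperature=np.array(tsurf_series),
        core_temperature=np.array(tcore_series),
        mr_mean=np.array(mr_series),
        delta_mr=np.array(dmr_series),
        chamber_pressure_series=np.array(press_series),
        drying_time_to_target=drying_time,
        energy_ledger=energy_ledger,
        mass_ledger=mass_ledger,
        dry_matter_density=rho_dry,
    )


def extract_core_surface(
    state_or_result: "FieldState | SimulationResult",
    initial_moisture: "float | None" = None,
    core_cut: float = 0.5,
    surface_cut: float = 0.9,
) -> tuple[float, float, float]:
    """Core and surface-shell moisture ratios and their difference.

    MR_core is the volume-weighted mean MR over cells whose normalized
    coordinate is <= ``core_cut``; MR_surface over >= ``surface_cut``;
    returns (MR_core, MR_surface, MR_core - MR_surface).
    """
    if isinstance(state_or_result, SimulationResult):
        state = state_or_result.state_at(float(state_or_result.times[-1]))
        m0 = state_or_result.config.initial_moisture
    else:
        state = state_or_result
        if initial_moisture is None:
            raise ValueError("initial_moisture required when passing a FieldState")
        m0 = initial_moisture
    x = state.coordinates
    size = x[-1] + (x[-1] - x[-2]) / 2.0
    faces = np.concatenate([[0.0], 0.5 * (x[:-1] + x[1:]), [size]])
    vols = np.diff(faces**3) / 3.0 if state.geometry == "sphere" else np.diff(faces)
    mr = state.nodal_moisture / m0
    xi = x / size
    core = xi <= core_cut
    surf = xi >= surface_cut
    mr_core = float((mr[core] * vols[core]).sum() / vols[core].sum())
    mr_surf = float((mr[surf] * vols[surf]).sum() / vols[surf].sum())
    return mr_core, mr_surf, mr_core - mr_surf


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the source-fraction / evaporation-constant calibration."""

    eta: float
    k_evap_multiplier: float
    rmse: float            # MR units, against the reference curve
    r2: float              # MR fit quality
    objective: float       # combined objective actually minimized
    n_simulations: int

    def apply(self, props: MaterialProperties) -> MaterialProperties:
        return props.replace(
            absorbed_fraction=self.eta,
            evaporation_rate_constant=props.evaporation_rate_constant
            * self.k_evap_multiplier,
        )


def _calibration_initials(
    config: SimulationConfig,
    props: MaterialProperties,
    t_end_s: float,
    mr_end: float,
) -> dict:
    """Energy/rate-balance starting guesses for the calibration search.

    The absorbed fraction starts from the latent-energy balance (energy to
    evaporate the reference's moisture loss over its duration divided by
    the nominal source power) and the evaporation multiplier from the
    first-order sink rate needed at the set temperature.  These are rough
    but land in the basin where source and sink are mutually consistent.
    """
    mode = config.mode
    size = config.characteristic_size
    delta_c = props.liquid_water_concentration * (1.0 - min(mr_end, 0.999))
    power_needed = props.latent_heat * delta_c / max(t_end_s, 1.0)  # W/m^3

    duty = 1.0
    if mode is DryingMode.MVD:
        unit_source = props.power_density * 1000.0 * props.density
        p_opp = config.schedule.vacuum_pressure
    elif mode is DryingMode.PVD:
        area_per_vol = 3.0 / size if config.geometry == "sphere" else 1.0 / size
        path = size if config.geometry == "sphere" else 2.0 * size
        absorbed = 1.0 - math.exp(-path / props.ir_penetration_depth)
        unit_source = (
            props.absorption_coefficient * props.radiation_intensity
            * area_per_vol * absorbed
        )
        p_opp = config.schedule.vacuum_pressure
        duty = config.schedule.vacuum_duration / config.schedule.period
    else:
        unit_source = None
        p_opp = config.ambient_vapor_pressure

    eta0 = power_needed / unit_source if unit_source else props.absorbed_fraction
    k_eff = -math.log(max(mr_end, 1e-3)) / max(t_end_s, 1.0)  # 1/s
    p_sat_set = antoine_saturation_pressure(config.air_temperature + _KELVIN, props)
    driving = max(p_sat_set - p_opp, 0.5) * duty
    g_per_mult = props.evaporation_rate_constant * driving / ATMOSPHERIC_PRESSURE_KPA
    return {"eta": eta0, "k_evap": k_eff / max(g_per_mult, 1e-30)}


def calibrate_source_fraction(
    config: SimulationConfig,
    props: MaterialProperties,
    reference: DryingCurve,
    parameters: "Sequence[str] | None" = None,
    eta_bounds: tuple[float, float] = (1e-4, 1.0),
    k_bounds: tuple[float, float] = (1.0, 1e7),
    n_scan: int = 7,
    golden_tol: float = 0.01,
    max_sweeps: int = 3,
    use_temperature: "bool | None" = None,
) -> CalibrationResult:
    """Calibrate the absorbed source fraction (and evaporation constant).

    Coordinate descent (log-spaced bracket scan followed by golden-section
    refinement, at most ``max_sweeps`` sweeps) minimizing the RMSE between
    the simulated volume-mean MR and the reference curve at the reference
    time points.  When the reference carries a surface-temperature trace and
    the mode has a tunable source, a normalized temperature-RMSE term is
    added: the MR curve alone cannot separate the absorbed power from the
    evaporation constant, while the pair (MR, temperature) pins both — the
    same dual validation the underlying experiments use.

    Hot air has no tunable source, so only the evaporation-constant
    multiplier is searched there by default.
    """
    mode = config.mode
    if parameters is None:
        parameters = ("k_evap",) if mode is DryingMode.HAD else ("eta", "k_evap")
    if use_temperature is None:
        use_temperature = (
            reference.surface_temperature is not None and mode is not DryingMode.HAD
        )
    ref_t_s = reference.times_min * 60.0
    ref_mr = reference.moisture / reference.initial_moisture
    t_span = max(
        abs(config.air_temperature - config.initial_temperature), 1.0
    )
    init = _calibration_initials(config, props, ref_t_s[-1], float(ref_mr[-1]))

    run_cfg = replace(config, t_end=float(ref_t_s[-1]) + 1.0)
    counter = {"n": 0}

    def evaluate(eta: float, k_mult: float) -> tuple[float, float, float]:
        counter["n"] += 1
        trial = props.replace(
            absorbed_fraction=eta,
            evaporation_rate_constant=props.evaporation_rate_constant * k_mult,
        )
        try:
            res = simulate_drying(run_cfg, trial)
        except SolverError:
            return 1e6, 1e6, -1e6
        sim_mr = np.interp(ref_t_s, res.times, res.mr_mean)
        resid = sim_mr - ref_mr
        rmse = float(np.sqrt(np.mean(resid**2)))
        ss_tot = float(np.sum((ref_mr - ref_mr.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
        obj = rmse
        if use_temperature:
            sim_t = np.interp(ref_t_s, res.times, res.surface_temperature)
            obj += float(
                np.sqrt(np.mean(((sim_t - reference.surface_temperature) / t_span) ** 2))
            )
        return obj, rmse, r2

    bounds = {"eta": eta_bounds, "k_evap": k_bounds}
    current = {
        "eta": float(np.clip(init["eta"], *eta_bounds)),
        "k_evap": float(np.clip(init["k_evap"], *k_bounds)),
    }
    if "eta" not in parameters:
        current["eta"] = props.absorbed_fraction
    best = evaluate(current["eta"], current["k_evap"])

    def objective_of(name: str, value: float):
        args = dict(current)
        args[name] = value
        return evaluate(args["eta"], args["k_evap"])

    def scan_and_refine(name: str, lo: float, hi: float, full: bool):
        """Log-spaced scan of [lo, hi] + golden-section refinement."""
        grid_vals = np.logspace(np.log10(lo), np.log10(hi), n_scan)
        scans = [objective_of(name, v) for v in grid_vals]
        objs = np.array([s[0] for s in scans])
        i_best = int(np.argmin(objs))
        if i_best in (0, n_scan - 1):
            at_global_edge = np.isclose(
                grid_vals[i_best], bounds[name][0 if i_best == 0 else 1]
            )
            if not at_global_edge and not full:
                return None  # widen to the full bounds
            # monotone over the whole bracket *and* still improving at a
            # meaningful rate at the boundary -> the minimum lies outside;
            # a flattened tail (objective insensitive) is acceptable
            edge_slope = abs(objs[-1] - objs[-2]) if i_best else abs(objs[1] - objs[0])
            still_improving = edge_slope > 1e-2 * abs(objs[i_best])
            monotone = np.all(np.diff(objs) < 0) or np.all(np.diff(objs) > 0)
            if at_global_edge and monotone and still_improving:
                raise CalibrationError(
                    f"objective is monotone in '{name}' over "
                    f"[{bounds[name][0]:g}, {bounds[name][1]:g}]; widen the bounds"
                )
        a = math.log10(grid_vals[max(i_best - 1, 0)])
        b = math.log10(grid_vals[min(i_best + 1, n_scan - 1)])
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = objective_of(name, 10.0**c)
        fd = objective_of(name, 10.0**d)
        while b - a > golden_tol:
            if fc[0] <= fd[0]:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = objective_of(name, 10.0**c)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = objective_of(name, 10.0**d)
        return 10.0 ** ((a + b) / 2.0)

    span = 1.2  # decades around the current value for the local bracket
    for sweep in range(max_sweeps):
        moved = False
        for name in parameters:
            glo, ghi = bounds[name]
            lo = max(glo, current[name] / 10.0**span)
            hi = min(ghi, current[name] * 10.0**span)
            x_new = scan_and_refine(name, lo, hi, full=False)
            if x_new is None:
                x_new = scan_and_refine(name, glo, ghi, full=True)
            cand = objective_of(name, x_new)
            if cand[0] < best[0] - 1e-12:
                if abs(math.log10(x_new / current[name])) > 1e-3:
                    moved = True
                current[name] = x_new
                best = cand
        span = max(0.4, span * 0.5)
        if not moved:
            break

    return CalibrationResult(
        eta=current["eta"],
        k_evap_multiplier=current["k_evap"],
        rmse=best[1],
        r2=best[2],
        objective=best[0],
        n_simulations=counter["n"],
    )
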