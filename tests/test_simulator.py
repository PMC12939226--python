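"""Coupled solver: conservation, conduction oracle, sink, extraction, calibration."""

from dataclasses import replace

import numpy as np
import pytest

from zandry.kinetics import DryingCurve
from zandry.properties import MaterialProperties
from zandry.simulator import (
    FieldState,
    SimulationConfig,
    calibrate_source_fraction,
    evaporation_sink,
    extract_core_surface,
    simulate_drying,
)

INERT = MaterialProperties(evaporation_rate_constant=1e-30)


def test_isolated_system_stays_at_initial_state():
    """No fluxes, no sources, no sinks: T and M are conserved exactly."""
    cfg = SimulationConfig(
        mode="HAD", geometry="slab", characteristic_size=0.01, n_nodes=20,
        t_end=600.0, heat_transfer_coeff=0.0, mass_transfer_coeff=0.0,
    )
    res = simulate_drying(cfg, INERT)
    assert np.abs(res.temperature_history[-1] - 20.0).max() < 1e-9
    assert np.abs(res.concentration_history[-1] - 707.61).max() < 1e-9


def test_conduction_only_slab_matches_analytic_series():
    """Dirichlet-heated slab against the separation-of-variables solution."""
    cfg = SimulationConfig(
        mode="HAD", geometry="slab", characteristic_size=0.01, n_nodes=60,
        t_end=120.0, max_step=0.25, heat_transfer_coeff=1e7,
        mass_transfer_coeff=0.0, air_temperature=60.0,
    )
    res = simulate_drying(cfg, INERT)
    alpha = INERT.thermal_conductivity / (INERT.density * INERT.specific_heat)
    length = cfg.characteristic_size

    def analytic(x, t, terms=200):
        series = np.zeros_like(x)
        for m in range(terms):
            lam = (2 * m + 1) * np.pi / 2.0
            series += (
                4 * (-1) ** m / ((2 * m + 1) * np.pi)
                * np.exp(-(lam**2) * alpha * t / length**2)
                * np.cos(lam * x / length)
            )
        return 60.0 + (20.0 - 60.0) * series

    for t in (30.0, 60.0, 120.0):
        assert alpha * t / length**2 > 0.05  # within the asymptotic regime
        state = res.state_at(t)
        err = np.abs(state.nodal_temperature - analytic(state.coordinates, t)).max()
        assert err < 0.1


def test_uniform_source_insulated_energy_balance():
    """Mean temperature rise equals the injected energy over rho*Cp exactly."""
    cfg = SimulationConfig(
        mode="MVD", geometry="slab", characteristic_size=0.01, n_nodes=20,
        t_end=300.0, heat_transfer_coeff=0.0, mass_transfer_coeff=0.0,
        source_control_band=None,
    )
    props = INERT.replace(absorbed_fraction=0.001)
    res = simulate_drying(cfg, props)
    q = 0.001 * props.power_density * 1000.0 * props.density
    expected = 20.0 + q * 300.0 / (props.density * props.specific_heat)
    mean_t = res.temperature_history[-1].mean()
    assert mean_t == pytest.approx(expected, rel=1e-6)


def test_evaporation_sink_examples(props):
    # no driving force below the chamber pressure
    assert evaporation_sink(300.0, 707.61, 101.325, props) == 0.0
    # direct evaluation at 60 degC under 10 kPa vacuum
    g = evaporation_sink(333.15, 707.61, 10.0, props)
    assert g == pytest.approx(3.37e-4, rel=5e-3)
    # zero rate constant and equilibrium gating
    off = props.replace(evaporation_rate_constant=1e-30)
    assert evaporation_sink(333.15, 707.61, 10.0, off) < 1e-20
    assert (
        evaporation_sink(333.15, 3.0, 10.0, props, moisture_db=0.005,
                         equilibrium_moisture=0.01)
        == 0.0
    )


class TestExtractCoreSurface:
    def make_state(self, moisture, geometry="slab"):
        n = len(moisture)
        x = (np.arange(n) + 0.5) / n * 0.01
        rho_dry = 707.61 / 2.03
        return FieldState(
            time=0.0, coordinates=x,
            nodal_temperature=np.full(n, 20.0),
            nodal_water_concentration=np.asarray(moisture) * rho_dry,
            dry_matter_density=rho_dry, chamber_pressure=101.325,
            geometry=geometry,
        )

    def test_uniform_profile_gives_zero(self):
        state = self.make_state(np.full(40, 1.5))
        core, surf, diff = extract_core_surface(state, initial_moisture=2.03)
        assert diff == pytest.approx(0.0, abs=1e-12)
        assert core == pytest.approx(1.5 / 2.03)

    def test_linear_profile_sign_convention(self):
        m = np.linspace(2.0, 1.0, 40)  # wet core, dry surface
        core, surf, diff = extract_core_surface(self.make_state(m), initial_moisture=2.0)
        assert core > surf
        assert diff > 0


class TestConservation:
    def test_ledgers_close_on_calibrated_run(self, mvd_run):
        res = mvd_run.result
        assert res.energy_ledger["residual_rel"] <= 1e-3
        assert res.mass_ledger["residual_rel"] <= 1e-3

    def test_mass_ledger_terms_are_physical(self, mvd_run):
        ml = mvd_run.result.mass_ledger
        assert ml["evaporated_kg"] >= 0
        assert ml["initial_water_kg"] > ml["remaining_water_kg"]

    def test_mr_series_non_increasing(self, mvd_run):
        assert np.all(np.diff(mvd_run.result.mr_mean) <= 1e-8)

    def test_temperature_bounded(self, mvd_run):
        cfg = mvd_run.config
        assert mvd_run.result.temperature_history.max() < cfg.air_temperature + 30.0
        assert mvd_run.result.temperature_history.min() >= cfg.initial_temperature - 1e-6

    def test_concentrations_never_negative(self, mvd_run):
        assert mvd_run.result.concentration_history.min() >= 0.0


def test_grid_and_step_convergence(mvd_run):
    """Halving the mesh spacing and maximum step moves the drying time < 2%."""
    base_cfg = mvd_run.config
    coarse = simulate_drying(base_cfg, mvd_run.props)
    fine_cfg = replace(base_cfg, n_nodes=base_cfg.n_nodes * 2,
                       max_step=base_cfg.max_step / 2.0)
    fine = simulate_drying(fine_cfg, mvd_run.props)
    t_coarse = coarse.drying_time_to_target or coarse.times[-1]
    t_fine = fine.drying_time_to_target or fine.times[-1]
    assert abs(t_coarse - t_fine) / t_fine < 0.02


class TestCalibration:
    def test_self_consistency_round_trip(self):
        """A reference made by the simulator itself pins eta to within 5%."""
        eta_true = 0.05
        cfg = SimulationConfig(
            mode="MVD", geometry="slab", characteristic_size=0.01,
            n_nodes=20, t_end=4000.0, air_temperature=50.0,
            source_control_band=None,
        )
        props = MaterialProperties(absorbed_fraction=eta_true,
                                   evaporation_rate_constant=2e-3)
        res = simulate_drying(cfg, props)
        times_h = res.times / 3600.0
        reference = DryingCurve(
            times_h=times_h, moisture=res.mr_mean * cfg.initial_moisture,
        )
        cal = calibrate_source_fraction(
            cfg, MaterialProperties(evaporation_rate_constant=2e-3),
            reference, parameters=("eta",), use_temperature=False,
        )
        assert abs(cal.eta - eta_true) / eta_true < 0.05
        assert cal.rmse < 0.01

    def test_drying_time_monotone_in_eta(self):
        """More absorbed power never slows the drying, all else fixed."""
        cfg = SimulationConfig(
            mode="MVD", geometry="slab", characteristic_size=0.01,
            n_nodes=20, t_end=8000.0, source_control_band=None,
        )
        times = []
        for eta in (0.02, 0.04, 0.08):
            props = MaterialProperties(absorbed_fraction=eta,
                                       evaporation_rate_constant=2e-3)
            res = simulate_drying(cfg, props)
            times.append(res.drying_time_to_target or res.times[-1])
        assert times[0] >= times[1] >= times[2]


class TestModeSignatures:
    """Qualitative thermal signatures of the calibrated 50 degC runs."""

    def test_hot_air_surface_leads_core(self, had_run):
        s = had_run.result.series_at(1200.0)
        assert s["surface_temperature"] > s["core_temperature"]

    def test_pulsed_vacuum_core_leads_surface(self, pvd_run):
        s = pvd_run.result.series_at(1200.0)
        assert s["core_temperature"] > s["surface_temperature"]

    def test_microwave_field_is_uniform(self, mvd_run):
        s = mvd_run.result.series_at(1200.0)
        assert abs(s["surface_temperature"] - s["core_temperature"]) < 1.0
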