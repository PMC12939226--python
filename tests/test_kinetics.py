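"""Thin-layer kinetics: MR/DR transforms, Page fitting, Arrhenius estimation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zandry.kinetics import (
    ArrheniusFit,
    DryingCurve,
    PageFit,
    R_GAS,
    drying_rate,
    fit_arrhenius,
    fit_page,
    moisture_ratio,
)


def page_curve(k, n, t_end=300.0, n_points=31):
    t = np.linspace(0.0, t_end, n_points)
    return t, np.exp(-k * t**n)


class TestMoistureRatio:
    def test_definition(self):
        curve = DryingCurve(times_h=[0, 1, 2], moisture=[2.03, 1.0, 0.11])
        mr = moisture_ratio(curve)
        assert mr[0] == 1.0
        assert mr[-1] == pytest.approx(0.0542, abs=1e-4)

    def test_constant_series(self):
        curve = DryingCurve(times_h=[0, 1, 2], moisture=[1.5, 1.5, 1.5])
        assert np.allclose(moisture_ratio(curve), 1.0)

    def test_zero_initial_moisture_rejected(self):
        with pytest.raises(ValueError):
            DryingCurve(times_h=[0, 1], moisture=[0.0, 0.0])


class TestDryingRate:
    def test_interval_rate(self):
        curve = DryingCurve(times_h=[0.0, 0.5], moisture=[2.03, 1.53])
        mid, dr = drying_rate(curve)
        assert mid[0] == pytest.approx(0.25)
        assert dr[0] == pytest.approx(1.0)

    def test_constant_moisture_gives_zero(self):
        curve = DryingCurve(times_h=[0, 1, 2, 3], moisture=[1.0, 1.0, 1.0, 1.0])
        _, dr = drying_rate(curve)
        assert np.allclose(dr, 0.0)

    def test_monotone_curve_gives_nonnegative_rates(self):
        t = np.linspace(0, 5, 20)
        curve = DryingCurve(times_h=t, moisture=2.03 * np.exp(-t))
        _, dr = drying_rate(curve)
        assert np.all(dr >= 0)

    def test_integral_consistency_with_moisture_loss(self):
        # trapezoid integral of DR over time ~= M0 - M_end on a dense grid
        t = np.linspace(0, 8, 400)
        m = 2.03 * np.exp(-0.5 * t)
        curve = DryingCurve(times_h=t, moisture=m)
        mid, dr = drying_rate(curve)
        integral = np.trapezoid(dr, mid)
        assert integral == pytest.approx(m[0] - m[-1], rel=1e-2)


class TestPageFit:
    @pytest.mark.parametrize("k,n", [(0.02, 1.0), (0.01, 1.2)])
    def test_exact_recovery_noise_free(self, k, n):
        t, mr = page_curve(k, n)
        fit = fit_page(mr, t)
        assert fit.k == pytest.approx(k, abs=1e-6 * k)
        assert fit.n == pytest.approx(n, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_forward_value(self):
        # MR(60) for k=0.01, n=1.2
        assert np.exp(-0.01 * 60**1.2) == pytest.approx(0.2566, abs=2e-4)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0.0, 300.0, 200)
        mr = np.clip(np.exp(-0.01 * t**1.2) + rng.normal(0, 0.01, t.shape), 1e-6, 1.0)
        fit = fit_page(mr, t)
        assert abs(fit.k - 0.01) / 0.01 < 0.10
        assert abs(fit.n - 1.2) < 0.05

    def test_time_rescaling_equivariance(self):
        # rescaling time by c maps k -> k * c^-n exactly on noise-free data
        k, n, c = 0.02, 1.3, 3.0
        t, mr = page_curve(k, n)
        fit = fit_page(mr, t * c)
        assert fit.k == pytest.approx(k * c**-n, rel=1e-6)
        assert fit.n == pytest.approx(n, abs=1e-8)

    def test_degenerate_no_drying(self):
        with pytest.raises(ValueError):
            fit_page(np.ones(10), np.linspace(0, 10, 10))

    def test_accepts_drying_curve_in_hours(self):
        t_min, mr = page_curve(0.02, 1.0)
        curve = DryingCurve(times_h=t_min / 60.0, moisture=2.03 * mr)
        fit = fit_page(curve)
        assert fit.k == pytest.approx(0.02, rel=1e-6)


class TestArrhenius:
    TEMPS = np.array([40.0, 50.0, 60.0, 70.0])

    def test_exact_round_trip(self):
        k0, ea = 100.0, 25_300.0
        ks = k0 * np.exp(-ea / (R_GAS * (self.TEMPS + 273.15)))
        fit = fit_arrhenius(ks, self.TEMPS)
        assert fit.ea == pytest.approx(ea, rel=1e-6)
        assert fit.k0 == pytest.approx(k0, rel=1e-6)
        # forward check at 50 degC: k = k0 exp(-Ea/(R*323.15)) ~= 8.13e-3
        assert ks[1] == pytest.approx(8.13e-3, rel=1e-3)

    def test_two_point_closed_form(self):
        fit = fit_arrhenius([0.01944, 0.0486], [40.0, 70.0])
        assert fit.ea / 1000.0 == pytest.approx(27.3, abs=0.05)

    def test_identical_rate_constants_give_zero_energy(self):
        fit = fit_arrhenius([0.02, 0.02, 0.02], [40.0, 50.0, 60.0])
        assert fit.ea == pytest.approx(0.0, abs=1e-9)

    def test_needs_two_distinct_temperatures(self):
        with pytest.raises(ValueError):
            fit_arrhenius([0.01, 0.02], [50.0, 50.0])

    def test_accepts_page_fits(self):
        fits = [PageFit(k=k, n=1.0, r2=1.0, rmse=0.0) for k in (0.01, 0.02)]
        out = fit_arrhenius(fits, [40.0, 70.0])
        assert isinstance(out, ArrheniusFit)
        assert out.ea > 0


@given(
    k=st.floats(min_value=1e-4, max_value=0.1),
    n=st.floats(min_value=0.5, max_value=2.0),
)
def test_page_fit_recovers_generating_parameters(k, n):
    """Property: the fit inverts the forward model over the physical range."""
    t = np.linspace(0.0, 3.0 / k ** (1.0 / n), 40)
    mr = np.exp(-k * np.clip(t, 0, None) ** n)
    mr = np.clip(mr, 1e-12, 1.0)
    fit = fit_page(mr, t)
    assert fit.k == pytest.approx(k, rel=1e-4)
    assert fit.n == pytest.approx(n, rel=1e-4)
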