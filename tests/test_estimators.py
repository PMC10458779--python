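"""Sealed-chamber and flux-integral estimators, conversions and comparison."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tuberflux import (
    ChamberSpec,
    FluxSeries,
    GasSeries,
    GasUnit,
    PlantParams,
    StoichMode,
    compare_to_observation,
    per_mass_factor,
    per_molecule_factor,
    required_drawdown,
    starch_from_tubers,
    tuber_mass_from_flux,
    tuber_mass_sealed,
    tubers_from_starch,
)
from tuberflux.estimators import AsPublishedModeWarning
from tuberflux.stoichiometry import CO2_MOLECULE_MASS_KG, STARCH_MONOMER_MASS_KG


def number_series(times, values):
    return GasSeries(np.asarray(times, float), np.asarray(values, float), GasUnit.NUMBER)


@pytest.fixture
def cube():
    return ChamberSpec(volume=1.0)


class TestPerMoleculeFactor:
    # frozen hand values: m1 = 2.6924e-25 kg, m_CO2 = 7.3078e-26 kg
    @pytest.mark.parametrize(
        "mode, expected",
        [
            (StoichMode.MASS_BALANCE, 2.2437e-25),
            (StoichMode.AS_PUBLISHED_EQ13, 8.0772e-24),
            (StoichMode.AS_PUBLISHED_EQ14, 2.1924e-24),
        ],
    )
    def test_modes_at_eta_02(self, mode, expected):
        p = PlantParams(eta_starch=0.2, mode=mode)
        assert per_molecule_factor(p) == pytest.approx(expected, rel=1e-4)

    def test_pure_starch_limit(self):
        with pytest.warns(UserWarning):
            p = PlantParams(eta_starch=1.0)
        assert per_molecule_factor(p) == pytest.approx(STARCH_MONOMER_MASS_KG / 6)

    @pytest.mark.parametrize("eta", [0.1, 0.2, 0.25])
    def test_mode_ordering(self, eta):
        factors = {
            m: per_molecule_factor(PlantParams(eta_starch=eta, mode=m)) for m in StoichMode
        }
        assert (
            factors[StoichMode.AS_PUBLISHED_EQ13]
            > factors[StoichMode.AS_PUBLISHED_EQ14]
            > factors[StoichMode.MASS_BALANCE]
        )

    def test_per_mass_factor_eq14_is_six_over_eta(self):
        p = PlantParams(eta_starch=0.2, mode=StoichMode.AS_PUBLISHED_EQ14)
        assert per_mass_factor(p) == pytest.approx(30.0)


class TestSealed:
    def test_zero_drawdown_returns_initial_mass(self, cube):
        s = number_series([0, 60, 120], [1e22, 1e22, 1e22])
        p = PlantParams(m_tubers0=0.225)
        out = tuber_mass_sealed(s, cube, p)
        np.testing.assert_allclose(out.mass, 0.225)

    def test_mass_balance_example(self, cube):
        s = number_series([0, 60], [2e22, 1e22])
        out = tuber_mass_sealed(s, cube, PlantParams(eta_starch=0.2))
        assert out.final_mass == pytest.approx(2.2437e-3, rel=1e-4)
        assert out.absorbed_co2_molecules[-1] == pytest.approx(1e22)

    def test_as_published_eq13_example(self, cube):
        s = number_series([0, 60], [2e22, 1e22])
        p = PlantParams(eta_starch=0.2, mode=StoichMode.AS_PUBLISHED_EQ13)
        with pytest.warns(AsPublishedModeWarning):
            out = tuber_mass_sealed(s, cube, p)
        assert out.final_mass == pytest.approx(8.077e-2, rel=1e-3)

    def test_leaky_chamber_rejected(self):
        ch = ChamberSpec(volume=1.0, leak_coefficient=1e-5)
        s = number_series([0, 60], [2e22, 1e22])
        with pytest.raises(ValueError, match="unsealed"):
            tuber_mass_sealed(s, ch, PlantParams())

    def test_short_series_rejected(self, cube):
        s = number_series([0.0], [1e22])
        with pytest.raises(ValueError):
            tuber_mass_sealed(s, cube, PlantParams())

    def test_starch_mass_is_eta_times_mass(self, cube):
        s = number_series([0, 60, 120], [2e22, 1.5e22, 1e22])
        p = PlantParams(eta_starch=0.2, m_tubers0=0.1)
        out = tuber_mass_sealed(s, cube, p)
        np.testing.assert_allclose(out.starch_mass, 0.2 * out.mass)

    @pytest.mark.parametrize("mode", list(StoichMode))
    def test_monotone_drawdown_gives_monotone_mass(self, cube, rng, mode):
        n = np.sort(rng.uniform(1e21, 2e22, size=50))[::-1]
        s = number_series(np.arange(50) * 60.0, n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AsPublishedModeWarning)
            out = tuber_mass_sealed(s, cube, PlantParams(mode=mode))
        assert np.all(np.diff(out.mass) >= 0)

    def test_partition_ratio_scales_increment(self, cube):
        s = number_series([0, 60], [2e22, 1e22])
        base = tuber_mass_sealed(s, cube, PlantParams(m_tubers0=0.225))
        corr = tuber_mass_sealed(
            s, cube, PlantParams(m_tubers0=0.225, partition_ratio=1.46)
        )
        gain_base = base.final_mass - 0.225
        gain_corr = corr.final_mass - 0.225
        assert gain_corr == pytest.approx(gain_base / 1.46, rel=1e-12)

    def test_negative_drawdown_kept_and_clampable(self, cube):
        # nighttime respiration: concentration rises above the start
        s = number_series([0, 60], [1e22, 2e22])
        out = tuber_mass_sealed(s, cube, PlantParams(m_tubers0=0.0))
        assert out.has_negative and out.final_mass < 0
        clamped = out.clamped()
        assert np.all(clamped.mass >= 0)

    def test_mass_conservation_mass_balance_mode(self, cube):
        # starch gained = (monomer molar mass / 6 CO2 molar masses) x CO2 mass
        s = number_series([0, 60], [3e22, 1e22])
        out = tuber_mass_sealed(s, cube, PlantParams(eta_starch=0.17))
        starch_gain = out.starch_mass[-1] - out.starch_mass[0]
        co2_mass = out.absorbed_co2_molecules[-1] * CO2_MOLECULE_MASS_KG
        assert starch_gain / co2_mass == pytest.approx(162.141 / (6 * 44.009), rel=1e-4)


class TestFluxIntegral:
    def test_zero_flux(self):
        f = FluxSeries(np.array([0.0, 1e5]), np.zeros(2), leaf_area=0.38)
        out = tuber_mass_from_flux(f, PlantParams(m_tubers0=0.225))
        np.testing.assert_allclose(out.mass, 0.225)

    def test_constant_flux_as_published_eq14(self):
        # closed form: 0.5e-6 * 0.38 * 1.728e6 kg CO2 = 0.32832 kg, x 6/eta = 30
        f = FluxSeries(np.array([0.0, 1.728e6]), np.full(2, 0.5e-6), leaf_area=0.38)
        p = PlantParams(eta_starch=0.2, mode=StoichMode.AS_PUBLISHED_EQ14)
        with pytest.warns(AsPublishedModeWarning):
            out = tuber_mass_from_flux(f, p)
        assert out.final_mass == pytest.approx(9.85, rel=1e-3)

    def test_constant_flux_mass_balance(self):
        f = FluxSeries(np.array([0.0, 1.728e6]), np.full(2, 0.5e-6), leaf_area=0.38)
        out = tuber_mass_from_flux(f, PlantParams(eta_starch=0.2))
        assert out.final_mass == pytest.approx(1.008, rel=1e-3)

    def test_trapezoid_exact_on_linear_flux(self):
        # coarse and fine grids agree exactly for linear integrands
        T = 1e5
        coarse = np.linspace(0, T, 3)
        fine = np.linspace(0, T, 1001)
        p = PlantParams()
        out_c = tuber_mass_from_flux(FluxSeries(coarse, 1e-6 * coarse / T, 0.38), p)
        out_f = tuber_mass_from_flux(FluxSeries(fine, 1e-6 * fine / T, 0.38), p)
        assert out_c.final_mass == pytest.approx(out_f.final_mass, rel=1e-12)

    def test_grid_refinement_converges(self):
        # quarter sine wave: int_0^T sin(pi t / 2T) dt = 2T/pi
        T = 1.728e6
        exact_mass_co2 = 0.38 * 1e-6 * 2 * T / np.pi
        p = PlantParams()
        errs = []
        for m in (8, 16, 32):
            t = np.linspace(0, T, m + 1)
            f = FluxSeries(t, 1e-6 * np.sin(np.pi * t / (2 * T)), 0.38)
            got = tuber_mass_from_flux(f, p).final_mass
            want = per_mass_factor(p) * exact_mass_co2
            errs.append(abs(got - want) / want)
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[2] > 8  # about h^2

    def test_sealed_and_flux_routes_agree(self):
        # a smooth drawdown n(t) and the flux computed from its analytic
        # derivative must give the same mass trajectory
        V, S = 40.0, 0.38
        T = 1.728e6
        t = np.linspace(0, T, 2001)
        n0, amp = 2.5e22, 1.5e22
        n = n0 - amp * (1 - np.cos(np.pi * t / T)) / 2
        dndt = -amp * np.pi / (2 * T) * np.sin(np.pi * t / T)
        p = PlantParams()
        sealed = tuber_mass_sealed(number_series(t, n), ChamberSpec(volume=V), p)
        flux = FluxSeries(t, -V * dndt * CO2_MOLECULE_MASS_KG / S, S)
        from_flux = tuber_mass_from_flux(flux, p)
        np.testing.assert_allclose(from_flux.mass, sealed.mass, rtol=1e-6, atol=1e-9)


class TestStarchConversions:
    def test_direct_product(self):
        assert starch_from_tubers(1.0, PlantParams(eta_starch=0.2)) == pytest.approx(0.2)
        assert starch_from_tubers(0.0, PlantParams()) == 0.0

    @given(m=st.floats(min_value=0, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, m):
        p = PlantParams(eta_starch=0.17)
        assert tubers_from_starch(starch_from_tubers(m, p), p) == pytest.approx(m, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            starch_from_tubers(-1.0, PlantParams())


class TestRequiredDrawdown:
    def test_zero_target(self, cube):
        assert required_drawdown(0.0, cube, PlantParams()) == 0.0

    def test_known_inverse(self, cube):
        p = PlantParams(eta_starch=0.2)
        dn = required_drawdown(2.2437e-3, cube, p)
        assert dn == pytest.approx(1e22, rel=1e-4)

    def test_volume_halves_drawdown(self):
        p = PlantParams()
        d1 = required_drawdown(0.5, ChamberSpec(volume=20.0), p)
        d2 = required_drawdown(0.5, ChamberSpec(volume=40.0), p)
        assert d1 == pytest.approx(2 * d2)

    @given(
        gain=st.floats(min_value=1e-4, max_value=10.0),
        rho=st.floats(min_value=1.0, max_value=2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_sealed_estimator_recovers_target(self, gain, rho):
        ch = ChamberSpec(volume=40.0)
        p = PlantParams(partition_ratio=rho)
        dn = required_drawdown(gain, ch, p)
        s = number_series([0, 3600], [2 * dn + 1e20, dn + 1e20])
        out = tuber_mass_sealed(s, ch, p)
        assert out.final_mass == pytest.approx(gain, rel=1e-9)


class TestComparison:
    def test_published_verification_ratio(self):
        rep = compare_to_observation(7.82, 5.24)
        assert rep.ratio_rounded == 1.49

    def test_identity_ratio(self):
        assert compare_to_observation(3.3, 3.3).ratio_rounded == 1.00

    def test_partition_ratio_case(self):
        assert compare_to_observation(2.92, 2.00).ratio_rounded == 1.46

    def test_signed_errors(self):
        rep = compare_to_observation(7.82, 5.24)
        assert rep.abs_error_kg == pytest.approx(2.58)
        assert rep.rel_error == pytest.approx(2.58 / 5.24)

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(ValueError):
            compare_to_observation(1.0, 0.0)
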