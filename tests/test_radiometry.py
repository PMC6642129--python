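"""Planck radiometry: golden irradiance values, Wien and Stefan-Boltzmann oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytotherm import (
    DEFAULT_CONSTANTS,
    PhysicalConstants,
    Spectrum,
    Temperature,
    ir_photon_flux,
    peak_wavelength,
    photon_flux,
    relative_r_ir_ratio,
    solar_spectral_irradiance,
    spectral_energy_density,
    spectral_plane_irradiance,
    total_irradiance,
)
from phytotherm import reference
from phytotherm.radiometry import default_grid

from conftest import GROWTH_TEMPS_C, planck_plane_irradiance_oracle


class TestConstants:
    def test_defaults_are_the_rounded_reference_values(self):
        c = DEFAULT_CONSTANTS
        assert c.planck_h == 6.626e-34
        assert c.light_speed_c == 2.998e8
        assert c.boltzmann_kB == 1.381e-23
        assert c.sun_radius == 6.95e8
        assert c.orbit_radius == 1.50e11
        assert c.sun_temperature == 5778.0

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            PhysicalConstants(planck_h=0.0)
        with pytest.raises(ValueError):
            PhysicalConstants(sun_temperature=-1.0)

    def test_partial_mapping_keeps_defaults(self):
        c = PhysicalConstants.from_mapping({"sun_temperature": 6000.0})
        assert c.sun_temperature == 6000.0
        assert c.planck_h == 6.626e-34
        with pytest.raises(KeyError):
            PhysicalConstants.from_mapping({"plancks_h": 1.0})

    @pytest.mark.parametrize("fmt", ["yaml", "json"])
    def test_from_file(self, tmp_path, fmt):
        if fmt == "yaml":
            p = tmp_path / "c.yaml"
            p.write_text("boltzmann_kB: 1.4e-23\n")
        else:
            p = tmp_path / "c.json"
            p.write_text('{"boltzmann_kB": 1.4e-23}')
        c = PhysicalConstants.from_file(p)
        assert c.boltzmann_kB == 1.4e-23
        assert c.light_speed_c == 2.998e8

    def test_celsius_conversion_is_exact(self):
        assert Temperature.from_celsius(22.0).kelvin == 295.15
        assert Temperature.from_celsius(4.0).kelvin == 277.15
        assert Temperature(300.0).celsius == pytest.approx(26.85)
        with pytest.raises(ValueError):
            Temperature(0.0)
        with pytest.raises(ValueError):
            Temperature.from_celsius(-300.0)


class TestPlanckFormulas:
    @pytest.mark.parametrize(
        "temp_c, expected",
        list(zip(GROWTH_TEMPS_C, reference.TABLE1_THERMAL["IR"])),
    )
    def test_thermal_ir_row_reproduces(self, temp_c, expected):
        """The 10 um plane irradiance matches the published row to 1%."""
        value = spectral_plane_irradiance(10e-6, Temperature.from_celsius(temp_c))
        assert value == pytest.approx(expected, rel=reference.IR_ROW_RTOL)

    @pytest.mark.parametrize(
        "lam, expected",
        [(310e-9, 0.91), (470e-9, 1.77), (660e-9, 1.52), (10e-6, 2.86e-4)],
    )
    def test_solar_cells_reproduce(self, lam, expected):
        """Diluted solar Planck spectrum matches the verified cells to 1.5%."""
        assert solar_spectral_irradiance(lam) == pytest.approx(expected, rel=reference.SOLAR_RTOL)

    def test_energy_density_vs_plane_irradiance_identity(self):
        """rho = 4 E_d / c with E_d per metre: the E = c rho, E_d = E/4 chain."""
        lam, T = 10e-6, Temperature.from_celsius(22.0)
        rho = spectral_energy_density(lam, T)
        e_d_per_m = spectral_plane_irradiance(lam, T) / 1e-9
        assert rho == pytest.approx(4.0 * e_d_per_m / DEFAULT_CONSTANTS.light_speed_c, rel=1e-12)

    def test_zero_temperature_limit(self):
        """The Bose factor kills the density as T -> 0."""
        assert spectral_energy_density(10e-6, Temperature(1e-2)) == 0.0

    def test_agrees_with_independent_arithmetic(self):
        for lam in (310e-9, 660e-9, 10e-6, 1e-4):
            for t_k in (277.15, 295.15, 310.15, 5778.0):
                assert spectral_plane_irradiance(lam, t_k) == pytest.approx(
                    planck_plane_irradiance_oracle(lam, t_k), rel=1e-12
                )

    @given(
        lam=st.floats(1e-7, 1e-4),
        t_k=st.floats(10.0, 6000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_temperature(self, lam, t_k):
        from hypothesis import assume

        # restrict to the numerically representable regime (above underflow)
        assume(spectral_plane_irradiance(lam, t_k) > 1e-290)
        assert spectral_plane_irradiance(lam, 2.0 * t_k) > spectral_plane_irradiance(lam, t_k)

    def test_deep_wien_tail_underflows_to_zero_not_error(self):
        # UV wavelength at leaf temperature: exponent ~ 1.7e2 ... 1e3+
        v = spectral_plane_irradiance(50e-9, 277.15)
        assert 0.0 <= v < 1e-300

    @pytest.mark.parametrize("bad", [0.0, -1e-6])
    def test_nonpositive_wavelength_rejected(self, bad):
        with pytest.raises(ValueError):
            spectral_plane_irradiance(bad, 295.15)


class TestPeakWavelength:
    def test_solar_peak_is_501nm(self):
        assert round(peak_wavelength(DEFAULT_CONSTANTS.sun_temperature) * 1e9) == 501

    def test_environment_peak_near_10um(self):
        lam = peak_wavelength(Temperature.from_celsius(22.0))
        assert lam == pytest.approx(9.82e-6, rel=0.01)

    def test_wien_product_constant(self):
        """lambda_max * T is a single constant across 250-6000 K to 1e-6 relative."""
        temps = np.linspace(250.0, 6000.0, 24)
        products = np.array([peak_wavelength(t) * t for t in temps])
        assert np.ptp(products) / products.mean() < 1e-6

    def test_matches_grid_argmax_oracle(self):
        for t_k in (277.15, 295.15, 5778.0):
            analytic = peak_wavelength(t_k)
            grid = np.linspace(0.5 * analytic, 2.0 * analytic, 200001)
            vals = spectral_plane_irradiance(grid, t_k)
            assert grid[int(np.argmax(vals))] == pytest.approx(analytic, rel=1e-4)

    def test_wien_scaling(self):
        assert peak_wavelength(600.0) == pytest.approx(peak_wavelength(300.0) / 2.0, rel=1e-12)


class TestTotalIrradiance:
    @pytest.mark.parametrize("t_k", [277.15, 295.15, 310.15, 5778.0])
    def test_full_band_matches_stefan_boltzmann(self, t_k):
        sigma = DEFAULT_CONSTANTS.stefan_boltzmann_sigma
        assert total_irradiance(t_k) == pytest.approx(sigma * t_k**4, rel=1e-3)

    def test_fourth_power_scaling(self):
        assert total_irradiance(600.0) / total_irradiance(300.0) == pytest.approx(16.0, rel=5e-3)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            total_irradiance(295.15, lam_lo=1e-5, lam_hi=1e-6)


class TestPhotonFlux:
    def test_zero_irradiance_zero_flux(self):
        assert photon_flux(0.0, 10e-6).value == 0.0

    def test_direct_arithmetic(self):
        """N = E * lambda / (h c) for E = 0.0288 W m^-2 nm^-1 at 10 um."""
        hc = 6.626e-34 * 2.998e8
        flux = photon_flux(0.0288, 10e-6)
        assert flux.value == pytest.approx(0.0288 * 1e-5 / hc, rel=1e-12)

    def test_flux_ratio_equals_irradiance_ratio(self):
        e1 = spectral_plane_irradiance(10e-6, 295.15)
        e2 = spectral_plane_irradiance(10e-6, 310.15)
        f1, f2 = photon_flux(e1, 10e-6), photon_flux(e2, 10e-6)
        assert f1.value / f2.value == pytest.approx(e1 / e2, rel=1e-12)

    def test_negative_irradiance_rejected(self):
        with pytest.raises(ValueError):
            photon_flux(-1.0, 10e-6)


class TestRelativeRIRRatio:
    def test_identity_at_reference(self):
        t = Temperature.from_celsius(22.0)
        assert relative_r_ir_ratio(t, t) == 1.0

    def test_warm_query_lowers_ratio(self):
        """r(22, 37) from the independent Planck arithmetic at 10 um."""
        oracle = planck_plane_irradiance_oracle(10e-6, 295.15) / planck_plane_irradiance_oracle(10e-6, 310.15)
        r = relative_r_ir_ratio(Temperature.from_celsius(22.0), Temperature.from_celsius(37.0))
        assert r == pytest.approx(oracle, rel=1e-12)
        assert r == pytest.approx(0.788, abs=5e-4)

    @given(
        t1=st.floats(250.0, 330.0),
        t2=st.floats(250.0, 330.0),
        t3=st.floats(250.0, 330.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_ratio_telescopes(self, t1, t2, t3):
        r12 = relative_r_ir_ratio(t1, t2)
        r23 = relative_r_ir_ratio(t2, t3)
        r13 = relative_r_ir_ratio(t1, t3)
        assert r12 * r23 == pytest.approx(r13, rel=1e-12)

    def test_ir_photon_flux_helper(self):
        n = ir_photon_flux(Temperature.from_celsius(22.0))
        assert n.wavelength == 10e-6
        assert n.value > 0


class TestTable1Exclusions:
    """The published visible-range thermal cells do not follow from the stated
    plane-irradiance formula; this test measures the deviation rather than
    asserting the cells."""

    @pytest.mark.parametrize("regime", ["UV-B", "B", "FR"])
    def test_uvb_blue_farred_rows_off_by_1_6x(self, regime):
        lam = reference.TABLE1_WAVELENGTHS_M[regime]
        for temp_c, printed in zip(GROWTH_TEMPS_C, reference.TABLE1_THERMAL[regime]):
            direct = spectral_plane_irradiance(lam, Temperature.from_celsius(temp_c))
            assert 1.5 < direct / printed < 1.75

    def test_red_row_deviates_mildly(self):
        lam = reference.TABLE1_WAVELENGTHS_M["R"]
        for temp_c, printed in zip(GROWTH_TEMPS_C, reference.TABLE1_THERMAL["R"]):
            direct = spectral_plane_irradiance(lam, Temperature.from_celsius(temp_c))
            rel = abs(direct - printed) / printed
            assert reference.IR_ROW_RTOL < rel < 0.10

    def test_solar_far_red_cell_outside_tolerance(self):
        direct = solar_spectral_irradiance(730e-9)
        rel = abs(direct - reference.TABLE1_SOLAR["FR"]) / reference.TABLE1_SOLAR["FR"]
        assert reference.SOLAR_RTOL < rel < 0.05


class TestSpectrum:
    def test_validation(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([2e-6, 1e-6]), np.array([1.0, 1.0]), Temperature(300.0), "environment")
        with pytest.raises(ValueError):
            Spectrum(np.array([1e-6, 2e-6]), np.array([1.0, -1.0]), Temperature(300.0), "environment")
        with pytest.raises(ValueError):
            Spectrum(np.array([1e-6, 2e-6]), np.array([1.0]), Temperature(300.0), "environment")

    def test_grid_peak_agrees_with_wien(self):
        spec = Spectrum.environment(Temperature.from_celsius(22.0), default_grid(n=20000))
        lam_grid, _ = spec.grid_peak()
        assert lam_grid == pytest.approx(peak_wavelength(295.15), rel=1e-3)

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        spec = Spectrum.solar(default_grid(n=50))
        path = spec.to_csv(tmp_path / "solar.csv")
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["wavelength_nm", "irradiance_W_m2_nm", "temperature_K", "source"]
        assert frame["wavelength_nm"].is_monotonic_increasing
        np.testing.assert_allclose(frame["irradiance_W_m2_nm"].to_numpy(), spec.irradiance, rtol=1e-6)
        assert (frame["source"] == "solar").all()
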