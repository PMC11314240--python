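"""Correlation models, diffusion conversions and concentration utilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import npfcs as npf
from npfcs import (
    DetectionVolume,
    ModelParams,
    PhysicalConditions,
    Population,
    ValidationError,
)


class TestSingleSpeciesDecay:
    @pytest.mark.parametrize(
        "tau, tau_d, S, expected",
        [
            (0.0, 1e-3, 11.0, 1.0),  # g(0) = 1 by construction
            (1e-3, 1e-3, 1e9, 0.5),  # S -> inf: axial factor -> 1
            # frozen from 0.5 * (1 + 1/121)**-0.5
            (1e-3, 1e-3, 11.0, 0.4979466032338519),
        ],
    )
    def test_values(self, tau, tau_d, S, expected):
        assert npf.single_species_g(tau, tau_d, S) == pytest.approx(
            expected, rel=1e-12
        )

    def test_strictly_decreasing_to_zero(self):
        tau = np.geomspace(1e-7, 1e3, 300)
        g = npf.single_species_g(tau, 1e-3, 11.0)
        assert np.all(np.diff(g) < 0)
        assert g[-1] < 1e-4

    @pytest.mark.parametrize("bad", [{"tau_d": 0.0}, {"tau_d": -1.0}, {"S": 0.5}])
    def test_invalid_parameters(self, bad):
        kwargs = {"tau_d": 1e-3, "S": 11.0}
        kwargs.update(bad)
        with pytest.raises(ValidationError):
            npf.single_species_g(1e-3, kwargs["tau_d"], kwargs["S"])


class TestMultiSpecies:
    def test_amplitude_is_inverse_particle_number(self, volume, water):
        pops = [Population(100e-9, 1.0, 5000.0)]
        for n in (0.3, 1.0, 7.5):
            assert npf.multi_species_G(0.0, pops, n, volume, water) == pytest.approx(
                1.0 / n, rel=1e-14
            )

    def test_equal_species_merge_into_one(self, volume, water):
        one = [Population(100e-9, 1.0, 5000.0)]
        two = [Population(100e-9, 0.4, 5000.0), Population(100e-9, 0.6, 5000.0)]
        tau = np.geomspace(1e-6, 1.0, 40)
        np.testing.assert_allclose(
            npf.multi_species_G(tau, two, 2.0, volume, water),
            npf.multi_species_G(tau, one, 2.0, volume, water),
            rtol=1e-13,
        )

    def test_brightness_weighted_amplitude(self, volume, water):
        # Q2 = 8 Q1 (d2 = 2 d1), X = 0.5, N = 1:
        # (0.5 + 0.5*64) / (0.5 + 0.5*8)^2 = 32.5 / 20.25
        pops = [Population(100e-9, 0.5, 1.0), Population(200e-9, 0.5, 8.0)]
        assert npf.multi_species_G(0.0, pops, 1.0, volume, water) == pytest.approx(
            32.5 / 20.25, rel=1e-12
        )

    def test_fractions_must_sum_to_one(self, volume, water):
        pops = [Population(100e-9, 0.5, 1.0), Population(200e-9, 0.4, 1.0)]
        with pytest.raises(ValidationError):
            npf.multi_species_G(0.0, pops, 1.0, volume, water)


class TestTwoPopulationModel:
    def test_reduces_to_single_population_at_zero_fraction(self, volume, water):
        tau = np.geomspace(1e-6, 1.0, 50)
        params = ModelParams(2.0, 0.0, 100e-9, 400e-9)
        tau_d, _ = npf.diffusion_time(100e-9, volume, water)
        expected = npf.single_species_g(tau, tau_d, volume.aspect_ratio) / 2.0
        np.testing.assert_allclose(
            npf.two_population_G(tau, params, volume, water), expected, rtol=1e-14
        )

    def test_equal_diameters_reduce_to_single_population(self, volume, water):
        tau = np.geomspace(1e-6, 1.0, 50)
        params = ModelParams(3.0, 0.4, 150e-9, 150e-9)
        tau_d, _ = npf.diffusion_time(150e-9, volume, water)
        expected = npf.single_species_g(tau, tau_d, volume.aspect_ratio) / 3.0
        np.testing.assert_allclose(
            npf.two_population_G(tau, params, volume, water), expected, rtol=1e-14
        )

    def test_zero_lag_amplitude(self, volume, water):
        # [0.9 + 0.1*27^2] / (2 * [0.9 + 0.1*27]^2) = 73.8 / 25.92, computed
        # independently from the brightness-weighted multi-species form below
        params = ModelParams(2.0, 0.1, 100e-9, 300e-9)
        got = npf.two_population_G(0.0, params, volume, water)
        assert got == pytest.approx(73.8 / 25.92, rel=1e-12)
        pops = [Population(100e-9, 0.9, 1.0), Population(300e-9, 0.1, 27.0)]
        assert got == pytest.approx(
            npf.multi_species_G(0.0, pops, 2.0, volume, water), rel=1e-14
        )

    def test_ordering_enforced(self):
        with pytest.raises(ValidationError):
            ModelParams(1.0, 0.1, 400e-9, 100e-9)

    def test_equivalent_to_multi_species_with_cubed_brightness(self, volume, water):
        """Volume-scaled brightness makes the two forms algebraically equal."""
        rng = np.random.default_rng(99)
        tau = np.geomspace(1e-6, 10.0, 60)
        for _ in range(1000):
            n = rng.uniform(0.2, 10.0)
            xa = rng.uniform(0.0, 1.0)
            d1 = rng.uniform(20e-9, 300e-9)
            da = d1 * rng.uniform(1.0, 10.0)
            params = ModelParams(n, xa, d1, da)
            pops = [
                Population(d1, 1.0 - xa, 1.0),
                Population(da, xa, (da / d1) ** 3),
            ]
            g2 = npf.two_population_G(tau, params, volume, water)
            gm = npf.multi_species_G(tau, pops, n, volume, water)
            np.testing.assert_allclose(g2, gm, rtol=1e-12)

    def test_strict_monotone_decay(self, volume, water):
        tau = np.geomspace(1e-7, 100.0, 400)
        params = ModelParams(1.5, 0.2, 80e-9, 500e-9)
        g = npf.two_population_G(tau, params, volume, water)
        assert np.all(np.diff(g) < 0)


class TestDiffusion:
    def test_stokes_einstein_value(self, water):
        # kB*294.15 / (3 pi * 0.978e-3 * 110e-9), frozen
        assert npf.diffusion_coefficient(110e-9, water) == pytest.approx(
            4.0054e-12, rel=1e-4
        )

    def test_viscosity_and_size_proportionality(self, water):
        thick = PhysicalConditions(water.temperature, 2 * water.viscosity)
        assert npf.diffusion_coefficient(110e-9, thick) == pytest.approx(
            npf.diffusion_coefficient(110e-9, water) / 2, rel=1e-14
        )
        assert npf.diffusion_coefficient(100e-9, water) == pytest.approx(
            2 * npf.diffusion_coefficient(200e-9, water), rel=1e-14
        )

    def test_diffusion_time_value_and_point_limit(self, volume, water):
        tau_d, valid = npf.diffusion_time(110e-9, volume, water)
        assert valid
        assert tau_d == pytest.approx(7.8347e-3, rel=1e-4)
        # point-particle limit omega0^2 / (4 D)
        d_small = 1e-12
        tau_small, _ = npf.diffusion_time(d_small, volume, water)
        D = npf.diffusion_coefficient(d_small, water)
        assert tau_small == pytest.approx(volume.omega0**2 / (4 * D), rel=1e-9)

    def test_finite_size_validity_flag(self, volume, water):
        # expression only holds for d <= 2 omega0 = 700 nm
        assert npf.diffusion_time(800e-9, volume, water)[1] is False
        assert npf.diffusion_time(699e-9, volume, water)[1] is True

    def test_inversion_value(self, volume, water):
        assert npf.diameter_from_diffusion_time(
            7.8347e-3, volume, water
        ) == pytest.approx(110e-9, rel=1e-4)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(min_value=10e-9, max_value=700e-9))
    def test_inversion_round_trip(self, d):
        volume = DetectionVolume(350e-9, 11.0)
        water = PhysicalConditions()
        tau_d, _ = npf.diffusion_time(d, volume, water)
        assert npf.diameter_from_diffusion_time(tau_d, volume, water) == pytest.approx(
            d, rel=1e-10
        )

    def test_inversion_monotonic(self, volume, water):
        taus = np.geomspace(1e-4, 1.0, 30)
        ds = [npf.diameter_from_diffusion_time(t, volume, water) for t in taus]
        assert np.all(np.diff(ds) > 0)


class TestVolumeFraction:
    @pytest.mark.parametrize(
        "xa, d1, da, expected",
        [
            (0.0, 1.0, 3.0, 0.0),
            (1.0, 1.0, 3.0, 1.0),
            (0.3, 2.0, 2.0, 0.3),
            (0.1, 1.0, 3.0, 0.75),  # 0.1*27 / (0.1*27 + 0.9)
        ],
    )
    def test_values(self, xa, d1, da, expected):
        assert npf.volume_fraction(xa, d1, da) == pytest.approx(expected, abs=1e-14)

    @settings(derandomize=True, max_examples=80)
    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=1e-9, max_value=1e-6),
        st.floats(min_value=1.0, max_value=50.0),
    )
    def test_bounds_and_dominance(self, xa, d1, ratio):
        phi = npf.volume_fraction(xa, d1, d1 * ratio)
        assert 0.0 <= phi <= 1.0
        assert phi >= xa - 1e-12  # volume fraction amplifies the number fraction

    def test_increasing_in_aggregate_size(self):
        phis = [npf.volume_fraction(0.05, 100e-9, 100e-9 * r) for r in (1, 2, 4, 8)]
        assert np.all(np.diff(phis) > 0)

    def test_invalid(self):
        with pytest.raises(ValidationError):
            npf.volume_fraction(1.2, 1.0, 2.0)
        with pytest.raises(ValidationError):
            npf.volume_fraction(0.5, 2.0, 1.0)


class TestConcentrationUtilities:
    def test_stock_conversion(self):
        # 60 nM nanoparticle stock corresponds to 3.6e13 particles/mL
        assert npf.number_concentration(60e-9) == pytest.approx(3.613e13, rel=1e-3)

    def test_zero_and_measurement_concentration(self):
        assert npf.number_concentration(0.0) == 0.0
        assert npf.number_concentration(500e-12) == pytest.approx(3.011e11, rel=1e-3)
        with pytest.raises(ValidationError):
            npf.number_concentration(-1e-9)

    def test_effective_volume(self, volume):
        # pi^1.5 * 11 * (350 nm)^3 ~ 2.63 um^3
        assert npf.effective_volume(volume) == pytest.approx(2.626e-18, rel=1e-3)
        unit = DetectionVolume(1.0, 1.0)
        assert npf.effective_volume(unit) == pytest.approx(math.pi**1.5, rel=1e-14)
        doubled = DetectionVolume(700e-9, 11.0)
        assert npf.effective_volume(doubled) == pytest.approx(
            8 * npf.effective_volume(volume), rel=1e-12
        )

    def test_expected_particles_at_study_concentration(self, volume):
        # ~0.8 particles in the effective volume at 500 pM
        n = 500e-12 * 1000 * npf.N_A * npf.effective_volume(volume)
        assert n == pytest.approx(0.79, abs=0.02)
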