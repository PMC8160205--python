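"""Microprofile analysis: bulk estimation, DBL fit, Fick flux, surface pH."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rhodolith as rh
from rhodolith.errors import (AnalyteMismatchError, DBLOutOfRangeError,
                              DegenerateGradientError, ProfileError,
                              ProfileMismatchError, TooFewPointsError)
from rhodolith.profiles import DBLResults, Microprofile

#: exact hand conversion of a 50 umol/L drop over 500 um with D = 2.01e-9 m2/s
HAND_FLUX = 0.05 / 5e-4 * 2.01e-9 * 3600.0 / 1e4 * 1e6   # = 0.07236


def piecewise_profile(surface=300.0, bulk=250.0, dbl=500.0, analyte="oxygen"):
    depths = np.concatenate([np.arange(0, dbl + 1, 25.0),
                             np.arange(dbl + 100, 1001, 100.0)])
    grad = (bulk - surface) / dbl
    values = np.where(depths <= dbl, surface + grad * depths, bulk)
    return Microprofile("sp", "tip", "light", analyte, depths, values)


class TestBulkEstimate:
    def test_constant_profile_returns_the_constant(self):
        p = Microprofile("sp", "tip", "light", "oxygen",
                         np.arange(0, 125, 25.0), np.full(5, 250.0))
        est = rh.estimate_bulk(p)
        assert est.value == 250.0
        assert est.stationary

    def test_flat_tail_of_piecewise_profile(self):
        est = rh.estimate_bulk(piecewise_profile(), n_outer=3)
        assert est.value == 250.0
        assert est.stationary

    def test_noisy_tail_mean_within_sampling_error(self, rng):
        sigma = 2.0
        p, _ = rh.simulate_microprofile(250.0, 500.0, HAND_FLUX,
                                        noise_sd=sigma, seed=42)
        est = rh.estimate_bulk(p, n_outer=3)
        assert abs(est.value - 250.0) <= 2 * sigma / np.sqrt(3)

    def test_gradient_tail_flagged_non_stationary(self):
        depths = np.arange(0, 300, 25.0)
        values = 300.0 - 0.2 * depths
        p = Microprofile("sp", "tip", "light", "oxygen", depths, values)
        assert not rh.estimate_bulk(p, n_outer=4).stationary

    def test_too_few_points_rejected(self):
        p = piecewise_profile()
        with pytest.raises(TooFewPointsError):
            rh.estimate_bulk(p, n_outer=1)


class TestDBLFit:
    def test_kink_construction_recovers_thickness_exactly(self):
        res = rh.estimate_dbl(piecewise_profile(), bulk=250.0)
        assert res.thickness == pytest.approx(500.0, abs=1e-9)
        assert res.surface_value == pytest.approx(300.0)
        assert res.fit_r2 == pytest.approx(1.0)
        assert res.n_fit >= 3

    def test_noisy_profiles_recover_thickness_within_ten_percent(self):
        est = []
        for seed in range(20):
            p, _ = rh.simulate_microprofile(250.0, 500.0, HAND_FLUX,
                                            noise_sd=1.0, seed=seed)
            est.append(rh.estimate_dbl(p, bulk=250.0).thickness)
        assert abs(np.mean(est) - 500.0) / 500.0 < 0.10

    def test_constant_profile_has_no_definable_dbl(self):
        p = Microprofile("sp", "tip", "light", "oxygen",
                         np.arange(0, 625, 25.0), np.full(25, 250.0))
        with pytest.raises(DegenerateGradientError):
            rh.estimate_dbl(p, bulk=250.0)

    def test_extrapolation_beyond_profile_rejected(self):
        # gentle gradient never reaching a far-away bulk within the profile
        p = piecewise_profile(surface=300.0, bulk=299.0, dbl=500.0)
        with pytest.raises(DBLOutOfRangeError):
            rh.estimate_dbl(p, bulk=150.0)

    def test_fit_r2_approaches_one_as_noise_vanishes(self):
        r2 = []
        for sd in (2.0, 0.5, 0.0):
            p, _ = rh.simulate_microprofile(250.0, 500.0, HAND_FLUX,
                                            noise_sd=sd, seed=7)
            r2.append(rh.estimate_dbl(p, bulk=250.0).fit_r2)
        assert r2 == sorted(r2)
        assert r2[-1] == pytest.approx(1.0)


class TestFickFlux:
    def test_hand_converted_gradient(self):
        res = rh.estimate_dbl(piecewise_profile(), bulk=250.0)
        flux = rh.fick_flux(res)
        assert flux.flux == pytest.approx(0.0724, abs=5e-4)
        assert flux.flux == pytest.approx(HAND_FLUX, rel=1e-9)
        assert flux.direction == "efflux"

    def test_zero_gradient_gives_zero_flux(self):
        dbl = DBLResults(thickness=100.0, surface_value=250.0,
                         surface_gradient=0.0, bulk_value=250.0, fit_r2=1.0,
                         n_fit=5, analyte="oxygen")
        assert rh.fick_flux(dbl).flux == 0.0

    def test_flux_is_linear_in_gradient(self):
        def flux_for(grad):
            dbl = DBLResults(500.0, 300.0, grad, 250.0, 1.0, 5, "oxygen")
            return rh.fick_flux(dbl).flux
        assert flux_for(-0.2) == pytest.approx(2 * flux_for(-0.1))

    def test_ph_profile_rejected(self):
        dbl = DBLResults(500.0, 8.5, -0.001, 8.12, 1.0, 5, "ph")
        with pytest.raises(AnalyteMismatchError):
            rh.fick_flux(dbl)

    def test_thicker_dbl_means_weaker_flux_at_fixed_endpoints(self):
        fluxes = []
        for dbl_um in (250.0, 500.0, 1000.0):
            p = piecewise_profile(surface=300.0, bulk=250.0, dbl=dbl_um)
            res = rh.estimate_dbl(p, bulk=250.0)
            fluxes.append(abs(rh.fick_flux(res).flux))
        assert fluxes[0] > fluxes[1] > fluxes[2]


class TestRoundTrip:
    @pytest.mark.parametrize("dbl_um,flux", [(250.0, 0.12), (500.0, HAND_FLUX),
                                             (450.0, -0.05)])
    def test_noise_free_generator_inversion(self, dbl_um, flux):
        p, truth = rh.simulate_microprofile(250.0, dbl_um, flux, noise_sd=0.0)
        res = rh.estimate_dbl(p, bulk=250.0)
        assert abs(res.thickness - dbl_um) <= 12.5          # half a grid step
        recovered = rh.fick_flux(res).flux
        assert recovered == pytest.approx(flux, rel=0.01)


class TestDeltaPh:
    @pytest.mark.parametrize("ph_s,ph_b,expected", [
        (8.12, 8.12, 0.0),
        (7.72, 8.12, -0.40),    # dark base anomaly of the most reactive species
        (8.72, 8.12, +0.60),    # inside the reported light-base range
    ])
    def test_surface_minus_bulk(self, ph_s, ph_b, expected):
        p, _ = rh.simulate_ph_profile(ph_b, 300.0, ph_s - ph_b, seed=0)
        res = rh.delta_ph(p, ph_b)
        assert res.delta_ph == pytest.approx(expected, abs=1e-9)

    def test_oxygen_profile_rejected(self):
        with pytest.raises(AnalyteMismatchError):
            rh.delta_ph(piecewise_profile(), 8.12)

    @given(ph_s=st.floats(7.0, 9.0), ph_b=st.floats(7.0, 9.0))
    @settings(deadline=None, max_examples=30)
    def test_antisymmetric_under_swapping_surface_and_bulk(self, ph_s, ph_b):
        p1, _ = rh.simulate_ph_profile(ph_b, 300.0, ph_s - ph_b, seed=0)
        p2, _ = rh.simulate_ph_profile(ph_s, 300.0, ph_b - ph_s, seed=0)
        d1 = rh.delta_ph(p1, ph_b).delta_ph
        d2 = rh.delta_ph(p2, ph_s).delta_ph
        assert d1 == pytest.approx(-d2, abs=1e-9)


class TestDielRange:
    @pytest.mark.parametrize("light,dark,expected", [
        (0.78, -0.40, 1.18), (0.0, 0.0, 0.0), (0.37, 0.0, 0.37),
    ])
    def test_light_minus_dark_swing(self, light, dark, expected):
        mk = lambda d, cond: rh.DeltaPh(d, 8.12 + d, 8.12, "sp", "base", cond)
        assert rh.diel_ph_range(mk(light, "light"), mk(dark, "dark")) == \
            pytest.approx(expected)

    def test_mismatched_location_rejected(self):
        a = rh.DeltaPh(0.1, 8.22, 8.12, "sp", "tip", "light")
        b = rh.DeltaPh(-0.1, 8.02, 8.12, "sp", "base", "dark")
        with pytest.raises(ProfileMismatchError):
            rh.diel_ph_range(a, b)


class TestProfileContainer:
    def test_invariants_enforced(self):
        with pytest.raises(ProfileError):
            Microprofile("s", "tip", "light", "oxygen",
                         [10, 35, 60, 85, 110], [1, 2, 3, 4, 5])   # no surface point
        with pytest.raises(ProfileError):
            Microprofile("s", "tip", "light", "oxygen",
                         [0, 25, 25, 75, 100], [1, 2, 3, 4, 5])    # not increasing
        with pytest.raises(ProfileError):
            Microprofile("s", "tip", "light", "oxygen",
                         [0, 25, 50, 75, 100], [1, 2, -3, 4, 5])   # negative O2

    def test_consecutive_replicates_average_pointwise(self):
        p1 = piecewise_profile(surface=300.0)
        p2 = piecewise_profile(surface=310.0)
        avg = rh.average_profiles([p1, p2])
        assert avg.values[0] == pytest.approx(305.0)
        assert np.array_equal(avg.depths, p1.depths)

    def test_replicates_with_different_metadata_rejected(self):
        p1 = piecewise_profile()
        p2 = Microprofile("sp", "base", "light", "oxygen",
                          p1.depths.copy(), p1.values.copy())
        with pytest.raises(ProfileMismatchError):
            rh.average_profiles([p1, p2])
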