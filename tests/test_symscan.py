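"""Spectral machinery: ACF closed forms, Wiener–Khinchin, calls, radial scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from ringsym import (
    AnalysisConfig, RadialBand, angular_acf, call_symmetry,
    radial_symmetry_scan, rotational_power_spectrum, to_polar,
)
from ringsym.polarize import PolarImage, angular_profile, estimate_center
from ringsym.population import classify_particle
from ringsym.ringforge import make_phantom
from ringsym.symscan import RotationalSpectrum
from conftest import ring_spec


def _zero_mean(x):
    return x - x.mean()


class TestAngularACF:
    def test_zero_profile_gives_zero_acf(self):
        acf = angular_acf(np.zeros(64))
        np.testing.assert_array_equal(acf.values, 0.0)

    def test_pure_cosine_acf_closed_form(self):
        theta = 2 * np.pi * np.arange(720) / 720
        acf = angular_acf(np.cos(34 * theta))
        np.testing.assert_allclose(acf.values, 0.5 * np.cos(34 * theta), atol=1e-12)

    def test_unit_normalization_of_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            angular_acf(np.zeros(16), normalization="unit-at-zero")

    def test_nonzero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero-mean"):
            angular_acf(np.ones(16))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, st.integers(4, 128),
                      elements=st.floats(-10, 10, allow_nan=False)))
    def test_lag_zero_dominates_and_acf_is_even(self, x):
        acf = angular_acf(_zero_mean(x)).values
        assert np.all(acf[0] >= np.abs(acf) - 1e-9 * max(1.0, acf[0]))
        np.testing.assert_allclose(acf[1:], acf[1:][::-1], atol=1e-9)


class TestRotationalPowerSpectrum:
    def test_pure_cosine_concentrates_in_one_harmonic(self):
        theta = 2 * np.pi * np.arange(720) / 720
        spec = rotational_power_spectrum(np.cos(34 * theta))
        others = np.delete(spec.power, 34)
        assert spec.power[34] == pytest.approx(0.25, rel=1e-12)
        assert others.max() < 1e-12 * spec.power[34]

    def test_wiener_khinchin_routes_agree(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = _zero_mean(rng.normal(size=rng.integers(8, 256)))
            direct = rotational_power_spectrum(x).power
            via_acf = rotational_power_spectrum(angular_acf(x)).power
            np.testing.assert_allclose(via_acf, direct, rtol=1e-9,
                                       atol=1e-9 * direct.max())

    def test_parseval_total_power_equals_mean_square(self):
        rng = np.random.default_rng(1)
        for n in (64, 255, 720):
            x = _zero_mean(rng.normal(size=n))
            spec = rotational_power_spectrum(x)
            assert spec.total_power() == pytest.approx(np.mean(x**2), rel=1e-9)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(10000, 720))
        draws -= draws.mean(axis=1, keepdims=True)
        power = np.abs(np.fft.rfft(draws, axis=1) / 720) ** 2
        mean_k = power.mean(axis=0)[1:]
        assert mean_k.max() / mean_k.min() < 1.1

    def test_polar_routes_and_weights(self, small_ring34, small_config):
        img, _ = small_ring34
        polar = to_polar(img, (80.0, 80.0), small_config.band, 17, 720)
        inc = rotational_power_spectrum(polar)
        coh = rotational_power_spectrum(polar, source="collapsed-profile")
        assert inc.power[34] > 10 * np.median(inc.power[20:41])
        assert coh.power[34] > 10 * np.median(coh.power[20:41])
        with pytest.raises(ValueError, match="nonnegative"):
            rotational_power_spectrum(polar, radial_weights=-np.ones(17))

    def test_non_finite_input_rejected(self):
        x = np.zeros(16)
        x[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            rotational_power_spectrum(x)


class TestCallSymmetry:
    def _spec_from_power(self, power, n_theta=720):
        return RotationalSpectrum(power=np.asarray(power, float), n_theta=n_theta)

    def test_exact_tie_is_ambiguous_and_resolves_low(self):
        power = np.zeros(361)
        power[33] = power[34] = 5.0
        call = call_symmetry(self._spec_from_power(power, 1440), (30, 40))
        assert call.status == "ambiguous"
        assert call.order == 33
        assert {k for k, _ in call.candidates} == {33, 34}

    def test_flat_spectrum_unassigned_with_unit_confidence(self):
        call = call_symmetry(self._spec_from_power(np.ones(361), 1440), (30, 40))
        assert call.status == "unassigned"
        assert call.order is None
        assert call.confidence == pytest.approx(1.0)

    def test_all_zero_spectrum_unassigned_zero_peak(self):
        call = call_symmetry(self._spec_from_power(np.zeros(361), 1440), (30, 40))
        assert call.status == "unassigned"
        assert call.peak_power == 0.0

    def test_range_validation(self):
        spec = self._spec_from_power(np.ones(361), 1440)
        with pytest.raises(ValueError, match="empty"):
            call_symmetry(spec, (35, 30))
        with pytest.raises(ValueError, match="k_lo"):
            call_symmetry(spec, (1, 30))
        with pytest.raises(ValueError, match="anti-aliasing"):
            call_symmetry(self._spec_from_power(np.ones(361), 720), (30, 200))

    def test_harmonic_sum_scorer_agrees_on_clean_ring(self, small_ring34, small_config):
        img, _ = small_ring34
        polar = to_polar(img, (80.0, 80.0), small_config.band, 17, 720)
        spec = rotational_power_spectrum(polar)
        assert call_symmetry(spec, (20, 40), method="harmonic-sum").order == 34

    def test_end_to_end_sring34_called_34(self, sring34):
        img, _ = sring34
        cfg = AnalysisConfig(band=RadialBand(100, 140), n_theta=720, n_r=41,
                             candidate_range=(20, 40))
        call = classify_particle(img, cfg)
        assert call.order == 34
        assert call.status == "assigned"


class TestRecoveryProperties:
    def test_exact_recovery_all_orders(self):
        cfg = AnalysisConfig(band=RadialBand(36, 52), n_theta=720, n_r=33,
                             candidate_range=(2, 45))
        for n in range(2, 41):
            call = classify_particle(make_phantom(ring_spec(n), id=f"n{n}"), cfg)
            assert call.order == n, f"order {n} miscalled as {call.order}"
            assert call.status != "unassigned"

    @pytest.mark.parametrize("n", [11, 23, 34])
    def test_harmonic_overtone_beats_non_multiples(self, n):
        img = make_phantom(ring_spec(n, size=256, radius=60.0, sigma=2.0))
        polar = to_polar(img, (128.0, 128.0), RadialBand(52, 68), 17, 720)
        spec = rotational_power_spectrum(polar)
        ks = np.arange(2, 91)
        non_multiples = ks[ks % n != 0]
        assert spec.power[2 * n] > spec.power[non_multiples].max()

    def test_spectrum_rotation_invariance(self):
        band = RadialBand(52, 68)
        base = make_phantom(ring_spec(34, size=256, radius=60.0, sigma=2.0))
        p0 = rotational_power_spectrum(
            to_polar(base, (128.0, 128.0), band, 17, 720)).power
        for delta in (0.13, 1.0, np.pi / 3):
            img = make_phantom(ring_spec(34, size=256, radius=60.0, sigma=2.0,
                                         rotation_rad=delta))
            p1 = rotational_power_spectrum(
                to_polar(img, (128.0, 128.0), band, 17, 720)).power
            assert np.linalg.norm(p1 - p0) <= 1e-3 * np.linalg.norm(p0)


class TestRadialScan:
    def test_three_shell_fixture_resolves_subsymmetries(self, msring_shells):
        img, _ = msring_shells
        center = estimate_center(img)
        polar = to_polar(img, center, RadialBand(36, 140), n_r=105, n_theta=720,
                         k_max=40)
        annuli = [RadialBand(40, 56), RadialBand(64, 80), RadialBand(112, 128)]
        calls = [c for _, _, c in radial_symmetry_scan(polar, annuli, (5, 40))]
        assert [c.order for c in calls] == [23, 11, 34]
        assert all(c.status == "assigned" for c in calls)

    def test_single_shell_hit_and_miss_annuli(self, small_ring34):
        img, _ = small_ring34
        polar = to_polar(img, (80.0, 80.0), RadialBand(20, 76), n_r=57, n_theta=720)
        annuli = [RadialBand(20, 36), RadialBand(52, 68)]
        (_, _, miss), (_, _, hit) = radial_symmetry_scan(polar, annuli, (5, 40))
        assert miss.status == "unassigned"
        assert hit.order == 34

    def test_zero_annulus_and_empty_annulus(self):
        polar = PolarImage(
            values=np.zeros((10, 360)), r_grid=np.linspace(10, 19, 10),
            theta_grid=2 * np.pi * np.arange(360) / 360,
            center_used_xy_px=(0.0, 0.0),
        )
        (_, _, call), = radial_symmetry_scan(polar, [RadialBand(10, 19)], (5, 40))
        assert call.status == "unassigned"
        assert call.peak_power == 0.0
        with pytest.raises(ValueError, match="zero radius rows"):
            radial_symmetry_scan(polar, [RadialBand(30, 40)], (5, 40))

    def test_overlapping_annuli_warn(self, small_ring34):
        img, _ = small_ring34
        polar = to_polar(img, (80.0, 80.0), RadialBand(40, 76), n_r=37, n_theta=720)
        with pytest.warns(UserWarning, match="overlap"):
            radial_symmetry_scan(
                polar, [RadialBand(44, 60), RadialBand(56, 72)], (5, 40))
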