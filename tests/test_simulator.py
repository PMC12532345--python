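"""Physics factors, phantom generation, and stochastic trajectories."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import find_peaks

from octfocus import (
    FocusState,
    OUParams,
    SystemParams,
    attenuation,
    compose_axial_intensity,
    cpsf,
    make_phantom,
    ou_trajectory,
    render_bscan,
    sensitivity_rolloff,
)
from octfocus.simulator import SimulationError


class TestCPSF:
    def test_unity_in_focus(self, params):
        assert cpsf(123.0, 123.0, params) == 1.0

    def test_half_maximum_at_twice_n_zr_eff(self, params):
        half_width = 2 * params.refractive_index_n * params.effective_rayleigh_length
        assert cpsf(500.0 + half_width, 500.0, params) == pytest.approx(0.5, abs=1e-15)
        assert cpsf(500.0 - half_width, 500.0, params) == pytest.approx(0.5, abs=1e-15)

    def test_symmetric_and_decreasing(self, params):
        offsets = np.linspace(0.0, 600.0, 200)
        t_plus = cpsf(500.0 + offsets, 500.0, params)
        t_minus = cpsf(500.0 - offsets, 500.0, params)
        np.testing.assert_allclose(t_plus, t_minus, rtol=1e-12)
        assert np.all(np.diff(t_plus) < 0)

    def test_rejects_non_finite(self, params):
        with pytest.raises(SimulationError):
            cpsf(np.nan, 0.0, params)


class TestAttenuation:
    def test_surface_value(self, params):
        assert attenuation(0.0, params) == params.mu_backscatter

    def test_half_life(self, params):
        z_half = np.log(2) / (2 * params.mu_oct_attenuation)
        assert attenuation(z_half, params) == pytest.approx(
            params.mu_backscatter / 2, rel=1e-14
        )

    def test_constant_without_attenuation(self, params):
        p0 = replace(params, mu_oct_attenuation=0.0)
        z = np.linspace(0, 1200, 50)
        np.testing.assert_array_equal(attenuation(z, p0), np.full(50, p0.mu_backscatter))


class TestSensitivityRolloff:
    def test_unity_at_zero(self, params):
        assert sensitivity_rolloff(0.0, params) == 1.0

    def test_sinc_factor_at_max_ranging_depth(self, params):
        # at z = zRD the sinc^2 factor is forced to 4/pi^2
        quiet = replace(params, spectral_resolution=1e-12)
        h = sensitivity_rolloff(quiet.max_ranging_depth, quiet)
        assert h == pytest.approx(4 / np.pi**2, rel=1e-9)

    def test_monotone_nonincreasing_within_ranging_depth(self, params):
        z = np.linspace(0.0, params.max_ranging_depth, 2000)
        h = sensitivity_rolloff(z, params)
        assert np.all(np.diff(h) <= 1e-12)
        assert np.all((h >= 0) & (h <= 1))


class TestComposeAxialIntensity:
    def test_factors_collapse_to_reflectivity_times_cpsf(self, phantom):
        p = SystemParams(
            n_lateral_ascans=32,
            mu_oct_attenuation=0.0,
            noise_floor_sigma=0.0,
            pixel_wavelength_spacing=1e-9,  # zRD huge -> sinc factor ~ 1
            spectral_resolution=1e-9,  # Gaussian roll-off factor ~ 1 too
        )
        zf = phantom.outer_band_center * p.axial_pixel_pitch
        profile = compose_axial_intensity(phantom, FocusState(zf), p)
        expected = phantom.reflectivity_R * cpsf(p.depth_um, zf, p)
        np.testing.assert_allclose(profile, expected, rtol=1e-10)

    def test_defocus_signature_band_ratio(self, phantom, quiet_params):
        """Focusing on the inner band must raise the inner/outer peak ratio
        relative to focusing on the outer band."""
        p = quiet_params
        pitch = p.axial_pixel_pitch
        inner_px = int(phantom.inner_band_center)
        outer_px = int(phantom.outer_band_center)

        def ratio(zf_px):
            prof = compose_axial_intensity(phantom, FocusState(zf_px * pitch), p)
            return prof[inner_px] / prof[outer_px]

        assert ratio(inner_px) > ratio(outer_px)

    def test_band_ratio_monotone_in_focus(self, phantom, quiet_params):
        p = quiet_params
        pitch = p.axial_pixel_pitch
        inner_px = int(phantom.inner_band_center)
        outer_px = int(phantom.outer_band_center)
        ratios = []
        for zf_px in np.linspace(inner_px, outer_px, 15):
            prof = compose_axial_intensity(phantom, FocusState(zf_px * pitch), p)
            ratios.append(prof[inner_px] / prof[outer_px])
        assert np.all(np.diff(ratios) < 0)

    def test_deterministic_given_seed(self, phantom, params):
        state = FocusState(600.0, axial_shift=12.5)
        a = compose_axial_intensity(phantom, state, params, rng=42)
        b = compose_axial_intensity(phantom, state, params, rng=42)
        np.testing.assert_array_equal(a, b)

    def test_out_of_window_shift_flagged(self, phantom, params):
        with pytest.raises(SimulationError):
            compose_axial_intensity(phantom, FocusState(600.0, axial_shift=2000.0), params)


class TestRenderBScan:
    def test_zero_variation_zero_noise_columns_identical(self, phantom, quiet_params):
        b = render_bscan(phantom, FocusState(600.0), quiet_params, lateral_variation=0.0)
        np.testing.assert_array_equal(b.intensity, b.intensity[:, :1].repeat(
            quiet_params.n_lateral_ascans, axis=1))

    def test_column_mean_matches_axial_profile(self, phantom, params):
        state = FocusState(600.0)
        b = render_bscan(phantom, state, params, rng=3)
        profile = compose_axial_intensity(phantom, state, replace(params, noise_floor_sigma=0.0))
        resid = b.intensity.mean(axis=1) - profile
        assert np.abs(resid).max() < 6 * params.noise_floor_sigma

    def test_integer_shift_equals_shifted_reflectivity(self, quiet_params):
        """With zero noise, rendering with a k-pixel shift equals rendering
        an unshifted phantom whose reflectivity was rolled by k (away from
        the window edges): the shift acts on R before the focus weighting."""
        ph = make_phantom()
        k = 7
        pitch = quiet_params.axial_pixel_pitch
        shifted = render_bscan(ph, FocusState(600.0, axial_shift=k * pitch),
                               quiet_params, lateral_variation=0.0)
        rolled_R = np.roll(ph.reflectivity_R, k)
        ph_rolled = replace(ph,
                            reflectivity_R=rolled_R,
                            inner_band_center=ph.inner_band_center + k,
                            outer_band_center=ph.outer_band_center + k)
        direct = render_bscan(ph_rolled, FocusState(600.0), quiet_params,
                              lateral_variation=0.0)
        interior = slice(k + 1, -1)
        np.testing.assert_allclose(
            shifted.intensity[interior], direct.intensity[interior], rtol=1e-9
        )


class TestOUTrajectory:
    def test_zero_sigma_constant(self):
        x = ou_trajectory(OUParams(0.5, 0.0, equilibrium_mu=3.0), 100, rng=0)
        np.testing.assert_array_equal(x, np.full(100, 3.0))

    def test_stationary_std_calibration(self):
        x = ou_trajectory(OUParams(0.5, 53.2, dt=0.04), 100_000, rng=1)
        assert x.std() == pytest.approx(53.2, rel=0.05)
        assert x.mean() == pytest.approx(0.0, abs=0.05 * 53.2)

    def test_seed_reproducibility(self):
        a = ou_trajectory(OUParams(2.0, 1.0), 500, rng=7)
        b = ou_trajectory(OUParams(2.0, 1.0), 500, rng=7)
        np.testing.assert_array_equal(a, b)

    def test_invalid_theta_rejected(self):
        with pytest.raises(SimulationError):
            OUParams(mean_reversion_theta=0.0, stationary_sigma=1.0)


class TestMakePhantom:
    def test_two_band_default(self, phantom):
        peaks, _ = find_peaks(phantom.reflectivity_R, height=0.2)
        assert len(peaks) == 2
        assert peaks[0] < phantom.inner_band_center + 5
        assert peaks[-1] > phantom.outer_band_center - 5

    def test_foveal_single_band(self, foveal_phantom):
        peaks, _ = find_peaks(foveal_phantom.reflectivity_R, height=0.2)
        assert len(peaks) == 1
        assert foveal_phantom.is_foveal

    def test_peak_ratio_tracks_amplitudes(self):
        ph = make_phantom(band_amplitudes=(0.5, 1.0), background_level=0.0)
        r = ph.reflectivity_R
        inner_peak = r[: 200].max()
        outer_peak = r[200:].max()
        assert inner_peak / outer_peak == pytest.approx(0.5, rel=0.01)

    def test_nonnegative_and_ordered(self):
        ph = make_phantom(randomize=True, rng=11)
        assert (ph.reflectivity_R >= 0).all()
        assert ph.outer_band_center > ph.inner_band_center
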