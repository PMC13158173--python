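"""PWI, SDM and SLDM attenuation estimators and the local AC map."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st_

from qusatten import attenuation as atn
from qusatten.beamforming import BeamformedImage, fk_migrate
from qusatten.rf_simulator import ProbeGeometry, build_phantom, sample_scatterers, \
    simulate_channel_data_fast
from qusatten.study import simulate_beamformed


def _exp_intensity(alpha0, f_eff=5.2, a2=3.0, z=None):
    z = np.linspace(2.0, 5.7, 400) if z is None else z
    return a2 * np.exp(-4.0 * alpha0 * f_eff * z), z


class TestEstimateAcPwi:
    def test_noiseless_exponential_recovered_exactly(self):
        intensity, z = _exp_intensity(0.05)
        est = atn.estimate_ac_pwi(intensity, z)
        assert est.alpha0 == pytest.approx(0.05, rel=1e-12)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)

    @given(alpha0=st_.floats(0.01, 0.3))
    def test_closed_form_inversion_over_alpha_range(self, alpha0):
        intensity, z = _exp_intensity(alpha0)
        est = atn.estimate_ac_pwi(intensity, z)
        assert abs(est.alpha0 - alpha0) / alpha0 < 1e-10

    def test_constant_intensity_gives_zero(self):
        z = np.linspace(2.0, 5.0, 200)
        est = atn.estimate_ac_pwi(np.full_like(z, 5.0), z)
        assert est.alpha0 == pytest.approx(0.0, abs=1e-14)

    def test_lateral_average_of_2d_grid(self):
        intensity, z = _exp_intensity(0.08)
        grid = np.vstack([intensity * g for g in (0.5, 1.0, 2.0)])
        est = atn.estimate_ac_pwi(grid, z)
        assert est.alpha0 == pytest.approx(0.08, rel=1e-12)

    def test_too_few_samples_rejected(self):
        z = np.linspace(2.0, 5.7, 30)
        intensity = np.exp(-z)
        with pytest.raises(ValueError, match="10 depth samples"):
            atn.estimate_ac_pwi(intensity, z, depth_range_cm=(2.0, 2.05))

    def test_nonpositive_intensity_rejected_with_guidance(self):
        z = np.linspace(2.0, 5.0, 100)
        intensity = np.exp(-z)
        intensity[50] = 0.0
        with pytest.raises(ValueError, match="floor"):
            atn.estimate_ac_pwi(intensity, z)
        est = atn.estimate_ac_pwi(intensity, z, floor=1e-12)
        assert np.isfinite(est.alpha0)


class TestAcSlope:
    def test_single_point_forced_through_origin(self):
        curve = atn.AlphaCurve(np.array([5.0]), np.array([0.4]))
        assert atn.ac_slope(curve) == pytest.approx(0.08)

    def test_exact_linear_curve(self):
        f = np.linspace(3.0, 7.0, 9)
        curve = atn.AlphaCurve(f, 0.08 * f)
        assert atn.ac_slope(curve) == pytest.approx(0.08, rel=1e-12)

    def test_noisy_linear_curve_recovered_within_2_se(self, rng):
        f = np.linspace(3.0, 7.0, 17)
        sigma = 0.005
        slopes = [
            atn.ac_slope(atn.AlphaCurve(f, 0.066 * f + rng.normal(0, sigma, f.size)))
            for _ in range(50)
        ]
        se = sigma / np.sqrt(np.sum(f**2))
        assert abs(np.mean(slopes) - 0.066) < 2 * se

    def test_empty_band_rejected(self):
        curve = atn.AlphaCurve(np.array([5.0]), np.array([0.4]))
        with pytest.raises(ValueError, match="empty"):
            atn.ac_slope(curve, band_mhz=(8.0, 9.0))


def _make_spectra(alpha0, f, z, g=None):
    """Constructed spectra with known frequency-linear decay."""
    g = np.ones_like(f) if g is None else g
    S = g[:, None] * np.exp(-4.0 * alpha0 * f[:, None] * z[None, :])
    return atn.SpectralEstimate(S, f, z, (f.min(), f.max()))


class TestSdmSldm:
    f = np.linspace(3.0, 7.0, 9)
    z = np.linspace(2.0, 5.5, 8)

    def _reference(self, alpha0_ref=0.05):
        g = np.exp(-((self.f - 5.2) ** 2))  # arbitrary system response
        return atn.ReferenceMedium(alpha0_ref, _make_spectra(alpha0_ref, self.f, self.z, g))

    def test_sample_equals_reference_returns_alpha_ref(self):
        ref = self._reference()
        sample = atn.SpectralEstimate(ref.spectra.S.copy(), self.f, self.z,
                                      ref.spectra.band_mhz)
        curve = atn.estimate_ac_sdm(sample, ref)
        np.testing.assert_allclose(curve.alpha_np_cm, 0.05 * self.f, rtol=1e-12)
        curve2 = atn.estimate_ac_sldm(sample, ref, 2.0, 5.5)
        np.testing.assert_allclose(curve2.alpha_np_cm, 0.05 * self.f, rtol=1e-12)

    def test_injected_excess_decay_recovered(self):
        ref = self._reference(0.05)
        g = np.exp(-((self.f - 5.2) ** 2))
        sample = _make_spectra(0.07, self.f, self.z, g)
        curve = atn.estimate_ac_sdm(sample, ref)
        np.testing.assert_allclose(curve.alpha_np_cm, 0.07 * self.f, rtol=1e-10)
        assert atn.ac_slope(curve) == pytest.approx(0.07, rel=1e-10)

    def test_sldm_equals_sdm_with_two_windows(self):
        z2 = np.array([2.5, 5.0])
        ref = atn.ReferenceMedium(0.05, _make_spectra(0.05, self.f, z2))
        sample = _make_spectra(0.09, self.f, z2)
        sdm = atn.estimate_ac_sdm(sample, ref)
        sldm = atn.estimate_ac_sldm(sample, ref, 2.5, 5.0)
        np.testing.assert_allclose(sdm.alpha_np_cm, sldm.alpha_np_cm, rtol=1e-12)

    def test_grid_mismatch_rejected(self):
        ref = self._reference()
        other = _make_spectra(0.07, self.f, self.z + 0.1)
        with pytest.raises(ValueError, match="grid"):
            atn.estimate_ac_sdm(other, ref)

    def test_nonpositive_reference_rejected(self):
        ref = self._reference()
        ref.spectra.S[0, 0] = 0.0
        sample = _make_spectra(0.07, self.f, self.z)
        with pytest.raises(ValueError, match="reference"):
            atn.estimate_ac_sdm(sample, ref)

    def test_sldm_degenerate_depths_rejected(self):
        ref = self._reference()
        sample = _make_spectra(0.07, self.f, self.z)
        with pytest.raises(ValueError):
            atn.estimate_ac_sldm(sample, ref, 3.0, 3.0)
        with pytest.raises(ValueError):
            atn.estimate_ac_sldm(sample, ref, 5.0, 2.5)

    def test_reference_sound_speed_contract(self):
        ref = self._reference()
        ref.check_sound_speed(1540.0)
        with pytest.raises(ValueError, match="1%"):
            ref.check_sound_speed(1600.0)


class TestPowerSpectrumVsDepth:
    def test_sinusoid_peaks_at_carrier(self, probe):
        z = np.arange(1400) * 0.154 / (2 * 20.8)
        f0 = 4.0  # MHz
        s = np.tile(np.sin(2 * np.pi * f0 * 2 * z / 0.154), (probe.n_elements, 1))
        image = BeamformedImage(s, probe.element_positions_cm(), z, 1540.0, probe)
        spec = atn.power_spectrum_vs_depth(image, band_mhz=(2.0, 8.0))
        peak_f = spec.freqs_mhz[np.argmax(spec.S[:, spec.S.shape[1] // 2])]
        assert peak_f == pytest.approx(f0, abs=0.25)

    def test_window_shorter_than_four_pulses_rejected(self, probe):
        z = np.arange(1400) * 0.154 / (2 * 20.8)
        s = np.zeros((probe.n_elements, z.size))
        image = BeamformedImage(s, probe.element_positions_cm(), z, 1540.0, probe)
        with pytest.raises(ValueError, match="pulse"):
            atn.power_spectrum_vs_depth(image, window_mm=0.5)

    def test_attenuated_speckle_spectra_decay_with_depth(self):
        """ln S(f, z) decreases with z at every in-band frequency."""
        ph = build_phantom("cirs_strong")
        acc = None
        for seed in range(3):
            image = simulate_beamformed(ph, 2000 + seed)
            sel = (image.z_axis_cm >= 2.0) & (image.z_axis_cm <= 5.5)
            crop = BeamformedImage(image.s[:, sel], image.x_axis_cm,
                                   image.z_axis_cm[sel], 1540.0, image.probe)
            spec = atn.power_spectrum_vs_depth(crop, band_mhz=(3.0, 7.0))
            acc = spec.S if acc is None else acc + spec.S
        lnS = np.log(acc)
        slopes = np.polyfit(spec.window_centers_cm, lnS.T, 1)[0]
        assert np.all(slopes < 0)

    def test_stationary_speckle_centroid_constant(self):
        ph = build_phantom({"background": {"alpha0": 0.0}})
        acc = None
        for seed in range(3):
            image = simulate_beamformed(ph, 2100 + seed)
            spec = atn.power_spectrum_vs_depth(image, band_mhz=(2.5, 8.0))
            acc = spec.S if acc is None else acc + spec.S
        cent = (spec.freqs_mhz @ acc) / acc.sum(axis=0)
        mid = (spec.window_centers_cm > 1.0) & (spec.window_centers_cm < 5.5)
        assert np.ptp(cent[mid]) < 0.25  # MHz


@pytest.fixture(scope="module")
def weak_image():
    return simulate_beamformed(build_phantom("cirs_weak"), seed=31415)


class TestMapLocalAc:

    def test_uniform_phantom_recovery(self, weak_image):
        maps = {
            p: atn.map_local_ac(weak_image, pixel_size_lambda=p)
            for p in (8.5, 17.0, 25.0)
        }
        m17 = maps[17.0]
        vals = m17.alpha0[np.isfinite(m17.alpha0)]
        assert abs(vals.mean() - 0.079) < vals.std()
        stds = [np.nanstd(maps[p].alpha0) for p in (8.5, 17.0, 25.0)]
        assert stds[0] >= stds[1] >= stds[2]

    def test_map_grid_respects_depth_floor(self, weak_image):
        acmap = atn.map_local_ac(weak_image)
        assert acmap.z_centers_cm.min() >= 2.0
        assert acmap.z_centers_cm.max() <= 5.7

    def test_gain_invariance(self, weak_image):
        m1 = atn.map_local_ac(weak_image)
        scaled = BeamformedImage(13.7 * weak_image.s, weak_image.x_axis_cm,
                                 weak_image.z_axis_cm, weak_image.sound_speed_m_s,
                                 weak_image.probe)
        m2 = atn.map_local_ac(scaled)
        np.testing.assert_allclose(m2.alpha0, m1.alpha0, rtol=1e-9, atol=1e-12)

    def test_zero_attenuation_map_is_near_zero(self):
        image = simulate_beamformed(build_phantom({"background": {"alpha0": 0.0}}),
                                    seed=999)
        acmap = atn.map_local_ac(image)
        vals = acmap.alpha0[np.isfinite(acmap.alpha0)]
        assert abs(vals.mean()) < 0.005

    def test_pixel_below_two_pulse_lengths_rejected(self, weak_image):
        with pytest.raises(ValueError, match="pulse"):
            atn.map_local_ac(weak_image, pixel_size_lambda=1.0)

    def test_invalid_overlap_rejected(self, weak_image):
        with pytest.raises(ValueError, match="overlap"):
            atn.map_local_ac(weak_image, overlap=1.0)


class TestRoiAverage:
    def _map(self, values):
        values = np.asarray(values, dtype=float)
        return atn.ACMap(values, np.arange(values.shape[0], dtype=float),
                         np.arange(values.shape[1], dtype=float), 17.0, 0.95,
                         (2.0, 5.7), np.ones_like(values))

    def test_constant_region(self):
        acmap = self._map(np.full((4, 5), 0.07))
        mask = np.zeros((4, 5), dtype=bool)
        mask[1:3, 1:4] = True
        summary = atn.roi_average_ac(acmap, mask)
        assert summary.mean == pytest.approx(0.07)
        assert summary.std == 0.0
        assert summary.n == 6

    def test_full_mask_equals_global_mean(self, rng):
        vals = rng.uniform(0.05, 0.1, (6, 7))
        acmap = self._map(vals)
        summary = atn.roi_average_ac(acmap, np.ones_like(vals, dtype=bool))
        assert summary.mean == pytest.approx(vals.mean())

    def test_nan_pixels_excluded(self):
        vals = np.full((3, 3), 0.08)
        vals[0, 0] = np.nan
        summary = atn.roi_average_ac(self._map(vals), np.ones((3, 3), dtype=bool))
        assert summary.n == 8
        assert summary.mean == pytest.approx(0.08)

    def test_empty_mask_rejected(self):
        acmap = self._map(np.full((3, 3), 0.08))
        with pytest.raises(ValueError, match="empty"):
            atn.roi_average_ac(acmap, np.zeros((3, 3), dtype=bool))


class TestGainInvarianceEndToEnd:
    def test_all_estimators_unchanged_by_rf_gain(self):
        """Scaling the raw RF rescales intensity but not any alpha estimate."""
        probe = ProbeGeometry()
        ph = build_phantom("cirs_weak")
        field = sample_scatterers(ph, seed=4242)
        data = simulate_channel_data_fast(field, ph, probe)
        img1 = fk_migrate(data)
        from qusatten.rf_simulator import ChannelData

        img2 = fk_migrate(ChannelData(5.0 * data.rf, data.time_axis_us, probe))
        est1 = atn.estimate_ac_pwi(img1.s**2, img1.z_axis_cm, floor=0.0)
        est2 = atn.estimate_ac_pwi(img2.s**2, img2.z_axis_cm, floor=0.0)
        assert est2.alpha0 == pytest.approx(est1.alpha0, rel=1e-9)
        s1 = atn.power_spectrum_vs_depth(img1)
        s2 = atn.power_spectrum_vs_depth(img2)
        ref = atn.ReferenceMedium(0.05, s1)
        curve = atn.estimate_ac_sdm(s2, ref)
        # the log-ratio of gain-scaled vs original spectra is flat in depth
        assert atn.ac_slope(curve) == pytest.approx(0.05, rel=1e-6)
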