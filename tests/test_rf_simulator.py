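"""Phantom construction, scatterer sampling, and the two RF generators."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.signal import hilbert

from qusatten.attenuation import _ols_line
from qusatten.rf_simulator import (
    ProbeGeometry,
    ScattererField,
    build_phantom,
    sample_scatterers,
    simulate_channel_data_fast,
    simulate_channel_data_pointwise,
)


class TestProbeGeometry:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ProbeGeometry(n_elements=1)
        with pytest.raises(ValueError):
            ProbeGeometry(pitch_um=200.0, element_width_um=250.0)
        with pytest.raises(ValueError):
            ProbeGeometry(sampling_frequency_mhz=10.0)

    def test_default_grid(self, probe):
        assert probe.element_positions_cm().mean() == pytest.approx(0.0, abs=1e-12)
        assert probe.wavelength_cm() == pytest.approx(0.0296, abs=2e-4)


class TestBuildPhantom:
    def test_cirs_weak_preset_is_uniform(self):
        ph = build_phantom("cirs_weak")
        assert np.all(ph.alpha0_map == 0.079)

    def test_cirs_inclusion_preset(self):
        ph = build_phantom("cirs_inclusion")
        assert ph.alpha0_map.max() == 0.107
        assert ph.alpha0_map.min() == 0.079
        # 8 mm diameter disc at (0, 3 cm)
        assert ph.alpha0_at(0.0, 3.0) == 0.079
        assert ph.alpha0_at(0.0, 3.0 + 0.5) == 0.107
        area_frac = (ph.alpha0_map == 0.079).mean()
        expected = np.pi * 0.4**2 / np.prod(ph.extent_cm)
        assert area_frac == pytest.approx(expected, rel=0.1)

    def test_two_zone_preset_split_at_midline(self):
        ph = build_phantom("cirs_two_zone")
        assert ph.alpha0_at(-1.0, 3.0) == 0.079
        assert ph.alpha0_at(1.0, 3.0) == 0.107

    @pytest.mark.parametrize("cfg", [None, {}, ""])
    def test_empty_config_rejected(self, cfg):
        with pytest.raises((ValueError, TypeError)):
            build_phantom(cfg)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            build_phantom({"background": {"alpha0": -0.01}})

    def test_overlapping_inclusions_rejected(self):
        cfg = {
            "background": {"alpha0": 0.1},
            "inclusions": [
                {"center": [0.0, 3.0], "radius_cm": 0.4, "alpha0": 0.05},
                {"center": [0.3, 3.0], "radius_cm": 0.4, "alpha0": 0.05},
            ],
        }
        with pytest.raises(ValueError, match="overlap"):
            build_phantom(cfg)

    def test_inclusion_outside_extent_rejected(self):
        cfg = {
            "background": {"alpha0": 0.1},
            "inclusions": [{"center": [0.0, 6.4], "radius_cm": 0.4, "alpha0": 0.05}],
        }
        with pytest.raises(ValueError, match="extent"):
            build_phantom(cfg)


class TestSampleScatterers:
    def test_count_matches_density(self):
        ph = build_phantom({"background": {"alpha0": 0.05}, "extent": [4.0, 6.0],
                            "scatterer_density": 10})
        field = sample_scatterers(ph, seed=0)
        expected = 10 * 4.0 * 6.0 / ph.resolution_cell_cm2
        assert field.amplitudes.size == round(expected)

    def test_seeded_determinism_is_bit_identical(self, weak_phantom):
        f1 = sample_scatterers(weak_phantom, seed=7)
        f2 = sample_scatterers(weak_phantom, seed=7)
        assert np.array_equal(f1.positions_cm, f2.positions_cm)
        assert np.array_equal(f1.amplitudes, f2.amplitudes)
        f3 = sample_scatterers(weak_phantom, seed=8)
        assert not np.array_equal(f1.amplitudes, f3.amplitudes)

    def test_zero_echogenicity_region_scatters_nothing(self):
        cfg = {
            "background": {"alpha0": 0.05, "echogenicity": 1.0},
            "zones": [{"z_range": [2.0, 4.0], "alpha0": 0.05, "echogenicity": 0.0}],
            "extent": [2.0, 5.0],
        }
        field = sample_scatterers(build_phantom(cfg), seed=3)
        z = field.positions_cm[:, 1]
        inside = (z >= 2.0) & (z < 4.0)
        assert np.all(field.amplitudes[inside] == 0.0)
        assert np.any(field.amplitudes[~inside] != 0.0)

    def test_low_density_warns(self):
        ph = build_phantom({"background": {"alpha0": 0.05}, "extent": [2.0, 3.0],
                            "scatterer_density": 0.01})
        with pytest.warns(UserWarning, match="speckle"):
            sample_scatterers(ph, seed=0)


class TestPointwiseSimulator:
    def test_single_scatterer_two_way_delay(self, small_probe, small_phantom_cfg):
        ph = build_phantom(small_phantom_cfg)
        field = ScattererField(np.array([[0.0, 3.0]]), np.array([1.0]), seed=0)
        data = simulate_channel_data_pointwise(field, ph, small_probe)
        k = int(np.argmin(np.abs(small_probe.element_positions_cm())))
        env = np.abs(hilbert(data.rf[k]))
        t_peak = data.time_axis_us[np.argmax(env)]
        x_k = small_probe.element_positions_cm()[k]
        expected = (3.0 + np.hypot(x_k, 3.0)) / ph.c_cm_us  # ~38.96 us
        assert t_peak == pytest.approx(expected, abs=2 * small_probe.dt_us)

    def test_zero_scatterers_give_zero_rf(self, small_probe, small_phantom_cfg):
        ph = build_phantom(small_phantom_cfg)
        field = ScattererField(np.empty((0, 2)), np.empty(0), seed=0)
        data = simulate_channel_data_pointwise(field, ph, small_probe)
        assert np.all(data.rf == 0.0)

    def test_scatterer_outside_extent_rejected(self, small_probe, small_phantom_cfg):
        ph = build_phantom(small_phantom_cfg)
        field = ScattererField(np.array([[0.0, 5.0]]), np.array([1.0]), seed=0)
        with pytest.raises(ValueError, match="outside"):
            simulate_channel_data_pointwise(field, ph, small_probe)

    def test_linearity_in_amplitudes(self, small_probe, small_phantom_cfg):
        ph = build_phantom(small_phantom_cfg)
        field = sample_scatterers(
            build_phantom({**small_phantom_cfg, "scatterer_density": 0.5}), seed=5
        )
        d1 = simulate_channel_data_pointwise(field, ph, small_probe)
        d2 = simulate_channel_data_pointwise(field.scaled(3.0), ph, small_probe)
        np.testing.assert_allclose(d2.rf, 3.0 * d1.rf, rtol=1e-12, atol=1e-12)

    def test_energy_decay_matches_attenuation(self, small_probe):
        """Monte-Carlo: ln<envelope^2> depth slope ~ -4 alpha(f_c) for a
        uniform phantom, within 10% once the band is narrow enough for the
        spectral downshift to stay small."""
        alpha0 = 0.079
        probe = ProbeGeometry(n_elements=32, fractional_bandwidth=0.35)
        ph = build_phantom({
            "background": {"alpha0": alpha0},
            "extent": [32 * 298e-4, 3.6],
            "scatterer_density": 6,
        })
        acc = None
        for seed in range(6):
            field = sample_scatterers(ph, seed=100 + seed)
            data = simulate_channel_data_pointwise(field, ph, probe)
            env2 = np.abs(hilbert(data.rf, axis=1)) ** 2
            acc = env2 if acc is None else acc + env2
        z = ph.c_cm_us * data.time_axis_us / 2
        sel = (z >= 1.0) & (z <= 3.2)
        slope, _, _ = _ols_line(z[sel], np.log(acc.mean(axis=0)[sel]))
        expected = -4 * alpha0 * probe.center_frequency_mhz
        assert slope == pytest.approx(expected, rel=0.10)


class TestFastSimulator:
    def test_seeded_determinism(self, probe):
        ph = build_phantom("cirs_weak")
        field = sample_scatterers(ph, seed=11)
        d1 = simulate_channel_data_fast(field, ph, probe)
        d2 = simulate_channel_data_fast(field, ph, probe)
        assert np.array_equal(d1.rf, d2.rf)

    def test_linearity_in_amplitudes(self, probe):
        ph = build_phantom("cirs_weak")
        field = sample_scatterers(ph, seed=12)
        d1 = simulate_channel_data_fast(field, ph, probe)
        d2 = simulate_channel_data_fast(field.scaled(2.5), ph, probe)
        np.testing.assert_allclose(d2.rf, 2.5 * d1.rf, rtol=1e-9, atol=1e-12)

    def test_block_shorter_than_pulse_rejected(self, probe):
        ph = build_phantom("cirs_weak")
        field = sample_scatterers(ph, seed=1)
        with pytest.raises(ValueError, match="pulse"):
            simulate_channel_data_fast(field, ph, probe, block_samples=8)

    def test_zero_attenuation_speckle_is_stationary(self, probe):
        ph = build_phantom({"background": {"alpha0": 0.0}})
        acc = None
        for seed in range(4):
            field = sample_scatterers(ph, seed=40 + seed)
            data = simulate_channel_data_fast(field, ph, probe)
            env2 = np.abs(hilbert(data.rf, axis=1)) ** 2
            acc = env2 if acc is None else acc + env2
        z = ph.c_cm_us * data.time_axis_us / 2
        sel = (z >= 1.0) & (z <= 5.5)
        slope, _, _ = _ols_line(z[sel], np.log(acc.mean(axis=0)[sel]))
        # 0.01 Np/cm resolution: well below any attenuation of interest
        assert abs(slope) < 4 * 0.01 * probe.center_frequency_mhz

    def test_envelope_is_rayleigh_in_homogeneous_region(self, probe):
        ph = build_phantom({"background": {"alpha0": 0.0}})
        field = sample_scatterers(ph, seed=77)
        data = simulate_channel_data_fast(field, ph, probe)
        env = np.abs(hilbert(data.rf, axis=1))
        z = ph.c_cm_us * data.time_axis_us / 2
        sel = (z >= 2.0) & (z <= 5.0)
        # decimate to roughly independent samples (pulse length apart)
        samples = env[::4, sel][:, ::16].ravel()
        scale = np.sqrt(np.mean(samples**2) / 2)
        _, p = sps.kstest(samples, "rayleigh", args=(0, scale))
        assert p > 0.01

    def test_matches_pointwise_intensity_depth_profile(self):
        """Fast vs pointwise oracle: gain-matched mean-intensity-vs-depth
        curves agree within 15% RMS on a matched small phantom."""
        probe = ProbeGeometry(n_elements=32)
        cfg = {
            "background": {"alpha0": 0.10},
            "extent": [32 * 298e-4, 3.0],
            "scatterer_density": 6,
        }
        ph = build_phantom(cfg)
        prof = {}
        z_bins = np.arange(0.8, 2.8, 0.1)
        for sim, label in ((simulate_channel_data_pointwise, "pointwise"),
                           (simulate_channel_data_fast, "fast")):
            acc = None
            for seed in range(6):
                field = sample_scatterers(ph, seed=500 + seed)
                data = sim(field, ph, probe)
                env2 = np.abs(hilbert(data.rf, axis=1)) ** 2
                acc = env2 if acc is None else acc + env2
            z = ph.c_cm_us * data.time_axis_us / 2
            curve = np.array([
                acc.mean(axis=0)[(z >= lo) & (z < lo + 0.1)].mean() for lo in z_bins
            ])
            prof[label] = curve
        a, b = prof["pointwise"], prof["fast"]
        gain = np.dot(a, b) / np.dot(b, b)  # least-squares gain match
        rms = np.sqrt(np.mean((a - gain * b) ** 2)) / a.mean()
        assert rms < 0.15
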