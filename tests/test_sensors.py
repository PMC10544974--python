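"""Canopy spectra and observation channels (drift, noise, DN transfer)."""

import numpy as np
import pandas as pd
import pytest

import phenospectra as ps
from phenospectra.errors import ParameterError, SchedulingError
from phenospectra.spectral import narrowband_to_broadband


def _ndvi_from(spectrum):
    r680 = narrowband_to_broadband(spectrum.wavelengths, spectrum.reflectance, 680)
    r800 = narrowband_to_broadband(spectrum.wavelengths, spectrum.reflectance, 800)
    return (r800 - r680) / (r800 + r680)


class TestCanopySpectrum:
    def test_vegetation_shape(self, vegetation_spectrum):
        wl, r = vegetation_spectrum.wavelengths, vegetation_spectrum.reflectance
        near_680 = r[(wl >= 660) & (wl <= 700)].mean()
        near_800 = r[(wl >= 780) & (wl <= 820)].mean()
        assert near_680 < near_800
        red_edge = r[(wl >= 680) & (wl <= 780)]
        assert np.all(np.diff(red_edge) > 0), "red edge must rise monotonically"
        assert np.all((r >= 0) & (r <= 1.2))

    def test_degenerate_canopy_is_soil_like(self):
        s = ps.simulate_canopy_spectrum(-30.0, 0.5)
        assert _ndvi_from(s) < 0.3

    def test_ndvi_strictly_increasing_in_latent_trait(self):
        lats = np.linspace(-4, 3, 12)
        vals = [_ndvi_from(ps.simulate_canopy_spectrum(lt, 0.5)) for lt in lats]
        assert np.all(np.diff(vals) > 0)

    def test_higher_water_lowers_970nm_reflectance(self):
        lo = ps.simulate_canopy_spectrum(0.0, 0.1)
        hi = ps.simulate_canopy_spectrum(0.0, 0.9)
        r970 = lambda s: narrowband_to_broadband(s.wavelengths, s.reflectance, 970)
        assert r970(hi) < r970(lo)

    def test_coarse_or_short_grid_rejected(self):
        with pytest.raises(ParameterError):
            ps.simulate_canopy_spectrum(0.0, 0.5, wavelengths=np.arange(400, 1000, 2.0))
        with pytest.raises(ParameterError):
            ps.simulate_canopy_spectrum(0.0, 0.5, wavelengths=np.arange(338, 2515, 10.0))


class TestObservePlot:
    def test_identity_channel_returns_band_window_means(self, vegetation_spectrum):
        sensor = ps.SensorModel(platform="radiometer_broadband")
        ob = ps.observe_plot(vegetation_spectrum, sensor, 0.0)
        for center, value in ob.band_values.items():
            expected = narrowband_to_broadband(
                vegetation_spectrum.wavelengths, vegetation_spectrum.reflectance, center
            )
            assert value == pytest.approx(expected, abs=1e-12)
        assert not ob.is_dn

    def test_linear_drift_closed_form_at_reference_band(self, vegetation_spectrum):
        # 1 - a|t| at the 800 nm reference: a=0.05, t=2 h -> factor 0.90
        sensor = ps.SensorModel(
            platform="radiometer_broadband", drift_amplitude=0.05, window_hours=3.0
        )
        ob0 = ps.observe_plot(vegetation_spectrum, sensor, 0.0)
        ob2 = ps.observe_plot(vegetation_spectrum, sensor, 2.0)
        assert ob2.band_values[800.0] == pytest.approx(0.90 * ob0.band_values[800.0])
        assert sensor.drift_multiplier(0.0, 800.0) == 1.0

    def test_uncalibrated_dn_flag(self, vegetation_spectrum):
        sensor = ps.SensorModel(
            platform="uas_broadband", dn_gain=100.0, dn_offset=500.0
        )
        ob = ps.observe_plot(vegetation_spectrum, sensor, 0.0)
        assert ob.is_dn
        assert ob.qc_flag == "uncalibrated_dn"
        assert all(v > 1.0 for v in ob.band_values.values())

    def test_outside_window_raises(self, vegetation_spectrum):
        sensor = ps.radiometer_sensor()  # six-hour window -> half-width 3 h
        with pytest.raises(SchedulingError):
            ps.observe_plot(vegetation_spectrum, sensor, 3.5)

    def test_hyperspectral_returns_full_curve(self, vegetation_spectrum):
        sensor = ps.hyperspectral_sensor(
            noise_sd=0.0, illum_noise_sd=0.0, illum_tilt_sd=0.0, illum_chroma_sd=0.0
        )
        ob = ps.observe_plot(vegetation_spectrum, sensor, 0.0)
        assert ob.curve is not None
        np.testing.assert_allclose(
            ob.curve["reflectance"], vegetation_spectrum.reflectance, atol=1e-12
        )

    def test_channel_mixture_combines_component_bands(self, vegetation_spectrum):
        mix = {450.0: ((450.0, 0.25), (800.0, 0.75))}
        sensor = ps.SensorModel(
            platform="radiometer_broadband",
            band_centers=(450.0, 800.0),
            band_mixtures=mix,
        )
        ob = ps.observe_plot(vegetation_spectrum, sensor, 0.0)
        pure = {
            c: narrowband_to_broadband(
                vegetation_spectrum.wavelengths, vegetation_spectrum.reflectance, c
            )
            for c in (450.0, 800.0)
        }
        assert ob.band_values[450.0] == pytest.approx(
            0.25 * pure[450.0] + 0.75 * pure[800.0], abs=1e-12
        )


class TestDriftProperty:
    def test_repeat_observation_deviation_grows_with_window(self, vegetation_spectrum):
        """Longer collection windows make repeated readings less repeatable."""
        rng = np.random.default_rng(0)
        mads = []
        for window in (0.5, 2.0, 4.0, 6.0):
            sensor = ps.radiometer_sensor(window_hours=window / 2.0, noise_sd=0.0)
            devs = []
            for _ in range(80):
                t = rng.uniform(-window / 2.0, window / 2.0)
                ob = ps.observe_plot(vegetation_spectrum, sensor, t, rng=rng)
                ref = ps.observe_plot(vegetation_spectrum, sensor, 0.0, rng=rng)
                devs.append(
                    np.mean(
                        [abs(ob.band_values[c] - ref.band_values[c]) for c in ob.band_values]
                    )
                )
            mads.append(np.mean(devs))
        assert np.all(np.diff(mads) > 0), mads


class TestPanels:
    def test_noiseless_identity_channel(self):
        panels = ps.default_panel_set()
        sensor = ps.SensorModel(platform="uas_broadband")
        table = ps.observe_panels(panels, sensor, 0.0)
        assert np.allclose(table["dn"], table["true_reflectance"])

    def test_linear_channel_arithmetic(self):
        panels = ps.single_panel_set()  # one 85% panel
        sensor = ps.SensorModel(platform="uas_broadband", dn_gain=1000.0)
        table = ps.observe_panels(panels, sensor, 0.0)
        assert np.allclose(table["dn"], 850.0)

    def test_repeated_noisy_observation_gives_distinct_rows(self):
        panels = ps.single_panel_set()
        sensor = ps.SensorModel(
            platform="uas_broadband", dn_gain=1000.0, noise_sd=2.0
        )
        t1 = ps.observe_panels(panels, sensor, 0.0, seed=1)
        t2 = ps.observe_panels(panels, sensor, 0.0, seed=2)
        both = pd.concat([t1, t2])
        assert both["panel_id"].nunique() == 1
        assert (t1["dn"] != t2["dn"]).any()

    @pytest.mark.parametrize(
        "reflectances",
        [(), (0.5, 0.3), (0.01, 0.5), (0.5, 0.9)],
    )
    def test_invalid_panel_sets_rejected(self, reflectances):
        with pytest.raises(ParameterError):
            ps.PanelSet(tuple(reflectances))
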