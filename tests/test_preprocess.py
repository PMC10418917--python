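"""Preprocessing chain: despiking, ModPoly baseline, averaging, and the
no-smoothing contract of the assembled pipeline."""

import numpy as np
import pytest

import ccframan as cf
from ccframan.errors import AlignmentError, ParameterError
from conftest import flat_spectrum


class TestDespike:
    def test_noop_on_spike_free_spectrum(self, male_spectrum):
        _, spec, _ = male_spectrum
        assert cf.despike(spec) == spec

    def test_injected_spike_restored(self, male_spectrum):
        config, spec, _ = male_spectrum
        ch = 1500
        spiked = spec.with_intensities(
            spec.intensities + 1000.0 * (np.arange(len(spec)) == ch)
        )
        cleaned = cf.despike(spiked)
        assert abs(cleaned.intensities[ch] - spec.intensities[ch]) < 3 * config.noise_sigma
        untouched = np.delete(np.arange(len(spec)), ch)
        assert np.array_equal(
            cleaned.intensities[untouched], spec.intensities[untouched]
        )

    def test_peak_positions_unmoved_by_despiking(self, male_spectrum):
        config, spec, _ = male_spectrum
        spiked = spec.with_intensities(
            spec.intensities + 1500.0 * (np.arange(len(spec)) == 800)
        )
        cleaned = cf.despike(spiked)
        for pk in config.peaks:
            lo = np.searchsorted(spec.shifts, pk.center - 10)
            hi = np.searchsorted(spec.shifts, pk.center + 10)
            before = lo + np.argmax(spec.intensities[lo:hi])
            after = lo + np.argmax(cleaned.intensities[lo:hi])
            assert abs(int(after) - int(before)) <= 1

    def test_constant_plus_spike_restored_exactly(self):
        spec = flat_spectrum(42.0)
        spiked = spec.with_intensities(
            spec.intensities + 900.0 * (np.arange(len(spec)) == 250)
        )
        assert np.array_equal(cf.despike(spiked).intensities, spec.intensities)

    def test_idempotent_on_simulated_spiky_input(self, windows):
        config = cf.config_from_reference(
            "Healthy Female ccfDNA", windows, defaults=cf.SyntheticGroupConfig(spike_rate=3.0)
        )
        spec = cf.simulate_spectrum(config, 0, 0, seed=21)
        once = cf.despike(spec)
        assert cf.despike(once) == once

    @pytest.mark.parametrize("window", [2, 1, 4, -3])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ParameterError):
            cf.despike(flat_spectrum(1.0), window=window)


class TestFitBaseline:
    def test_polynomial_input_recovered_exactly(self):
        x = 300.0 + np.arange(1001.0)
        true = 100 + 0.05 * x - 2e-5 * x**2 + 4e-9 * x**3
        spec = cf.RamanSpectrum(shifts=x, intensities=true)
        fit = cf.fit_baseline(spec, order=3)
        assert np.max(np.abs(true - fit.baseline)) < 1e-6 * np.max(np.abs(true))

    def test_matches_direct_least_squares_on_smooth_input(self):
        x = 300.0 + np.arange(801.0)
        y = 20 + 0.01 * x + 3e-6 * x**2
        spec = cf.RamanSpectrum(shifts=x, intensities=y)
        fit = cf.fit_baseline(spec, order=4)
        direct = np.polynomial.Polynomial.fit(x, y, 4)(x)
        assert np.allclose(fit.baseline, direct, atol=1e-8 * np.max(np.abs(y)))

    def test_zero_spectrum_gives_zero_baseline(self):
        fit = cf.fit_baseline(flat_spectrum(0.0), order=5)
        assert np.allclose(fit.baseline, 0.0, atol=1e-12)

    def test_peak_excluded_from_background(self):
        x = 300.0 + np.arange(1501.0)
        true = 400 - 0.08 * (x - 300) + 2e-5 * (x - 300) ** 2
        peak = cf.pseudo_voigt(x, 1000.0, 900.0, 10.0, 0.5)
        spec = cf.RamanSpectrum(shifts=x, intensities=true + peak)
        fit = cf.fit_baseline(spec, order=3)
        at_center = np.argmin(np.abs(x - 1000.0))
        assert fit.baseline[at_center] == pytest.approx(true[at_center], rel=0.05)

    def test_recovers_simulated_background_on_peak_free_channels(self, male_spectrum):
        _, spec, components = male_spectrum
        fit = cf.fit_baseline(spec)
        peak_free = components["peak_sum"] < 0.5
        rel = np.abs(fit.baseline - components["baseline"])[peak_free]
        rel /= components["baseline"][peak_free]
        assert np.max(rel) < 0.05

    def test_underdetermined_fit_rejected(self):
        spec = cf.RamanSpectrum(shifts=[1.0, 2.0, 3.0], intensities=[0.0, 1.0, 0.0])
        with pytest.raises(ParameterError):
            cf.fit_baseline(spec, order=5)


class TestSubtractBaseline:
    def test_self_subtraction_is_zero(self):
        x = 300.0 + np.arange(501.0)
        y = 10 + 0.02 * x
        spec = cf.RamanSpectrum(shifts=x, intensities=y)
        fit = cf.fit_baseline(spec, order=1)
        assert np.allclose(
            cf.subtract_baseline(spec, fit).intensities, 0.0, atol=1e-8
        )

    def test_zero_baseline_is_identity(self):
        spec = flat_spectrum(5.0)
        fit = cf.BaselineFit(
            coefficients=np.zeros(1),
            baseline=np.zeros(len(spec)),
            order=0,
            n_iterations=1,
        )
        out = cf.subtract_baseline(spec, fit)
        assert np.array_equal(out.intensities, spec.intensities)
        assert out.sample_id == spec.sample_id

    def test_axis_mismatch_rejected(self):
        spec = flat_spectrum(1.0, n=100)
        fit = cf.BaselineFit(
            coefficients=np.zeros(1), baseline=np.zeros(99), order=0, n_iterations=1
        )
        with pytest.raises(AlignmentError):
            cf.subtract_baseline(spec, fit)

    def test_corrected_amplitudes_match_configuration(self, windows, quiet_config):
        """After baseline subtraction and replicate averaging, apex heights
        reproduce the configured band amplitudes within 10%."""
        config = cf.config_from_reference(
            "Healthy Male ccfDNA", windows, defaults=quiet_config
        )
        avg = cf.preprocess_pipeline(cf.simulate_group(config, seed=7))
        for pk in config.peaks:
            lo = np.searchsorted(avg.shifts, pk.center - 6)
            hi = np.searchsorted(avg.shifts, pk.center + 6)
            recovered = np.max(avg.mean[lo:hi])
            assert recovered == pytest.approx(pk.amplitude, rel=0.10)


class TestAverageSpectra:
    def test_identical_spectra_average_to_themselves(self, male_spectrum):
        _, spec, _ = male_spectrum
        avg = cf.average_spectra([spec] * 15)
        assert np.allclose(avg.mean, spec.intensities, rtol=1e-12, atol=0)
        assert np.allclose(avg.sd, 0.0, atol=1e-9)
        assert avg.n == 15

    def test_symmetric_pair_averages_to_zero(self):
        x = 300.0 + np.arange(100.0)
        v = np.sin(x / 30.0)
        up = cf.RamanSpectrum(shifts=x, intensities=v)
        down = cf.RamanSpectrum(shifts=x, intensities=-v)
        avg = cf.average_spectra([up, down])
        assert np.allclose(avg.mean, 0.0, atol=1e-15)

    def test_channel_sd_tracks_generator_noise(self, windows, quiet_config):
        config = cf.config_from_reference(
            "Healthy Female ccfDNA", windows, defaults=quiet_config
        )
        spectra = cf.simulate_group(config, seed=13)
        avg = cf.average_spectra(spectra)
        silent = (avg.shifts > 1900) & (avg.shifts < 2700)
        assert np.median(avg.sd[silent]) == pytest.approx(
            config.noise_sigma, rel=0.25
        )

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(AlignmentError):
            cf.average_spectra([])
        a = flat_spectrum(1.0, n=50)
        b = flat_spectrum(1.0, n=60)
        with pytest.raises(AlignmentError):
            cf.average_spectra([a, b])


class TestPreprocessPipeline:
    def test_mean_equals_mean_of_individually_corrected(self, windows, quiet_config):
        config = cf.config_from_reference(
            "T2DM Male ccfDNA", windows, defaults=quiet_config
        )
        spectra = cf.simulate_group(config, seed=2)
        params = cf.PreprocessParams()
        out = cf.preprocess_pipeline(spectra, params)
        manual = []
        for s in spectra:
            s = cf.despike(s, params.despike_window, params.despike_z)
            s = cf.subtract_baseline(s, cf.fit_baseline(s))
            manual.append(s.intensities)
        assert np.array_equal(out.mean, np.mean(manual, axis=0))

    def test_unit_impulse_moves_mean_by_exactly_one_nth(self):
        params = cf.PreprocessParams(despike_enabled=False, baseline_enabled=False)
        base = [flat_spectrum(0.0) for _ in range(5)]
        plain = cf.preprocess_pipeline(base, params)
        bumped = [s.with_intensities(s.intensities.copy()) for s in base]
        bumped[2].intensities[100] += 1.0
        out = cf.preprocess_pipeline(bumped, params)
        delta = out.mean - plain.mean
        expected = np.zeros(len(base[0]))
        expected[100] = 1.0 / 5.0
        assert np.array_equal(delta, expected)

    def test_stage_noops_reduce_to_plain_average(self):
        params = cf.PreprocessParams(despike_enabled=False, baseline_enabled=False)
        rng = np.random.default_rng(0)
        spectra = [
            flat_spectrum(0.0).with_intensities(rng.normal(0, 1, 501))
            for _ in range(4)
        ]
        out = cf.preprocess_pipeline(spectra, params)
        assert np.array_equal(out.mean, np.mean([s.intensities for s in spectra], axis=0))

    def test_single_spectrum_has_zero_sd(self, male_spectrum):
        _, spec, _ = male_spectrum
        out = cf.preprocess_pipeline([spec])
        assert out.n == 1
        assert np.array_equal(out.sd, np.zeros(len(spec)))
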