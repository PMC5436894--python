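"""Multitaper spectra, coherence decomposition, wavelets and coupling."""

import numpy as np
import pytest

from alphagate.fixtures import gen_phase_locked_oscillation
from alphagate.spectral import (
    alpha_gamma_coupling,
    band_metrics,
    coherence_components,
    gamma_power_trace,
    morlet_transform,
    multitaper_coherence,
    multitaper_psd,
    shuffle_bias,
)

FS = 1000.0


def sinusoid(f, n=2000, amp=1.0, phase=0.0):
    t = np.arange(n) / FS
    return amp * np.cos(2 * np.pi * f * t + phase)


class TestPsd:
    def test_peak_at_sinusoid_frequency(self):
        psd = multitaper_psd(sinusoid(40.0))
        assert psd.freqs[np.argmax(psd.values)] == pytest.approx(40.0, abs=1.0)

    def test_parseval_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1.0, size=(5, 2000))
        psd = multitaper_psd(x)
        # mean one-sided density over frequencies ~ variance
        total = psd.values.mean()
        assert total == pytest.approx(x.var(), rel=0.01)

    def test_zero_signal(self):
        psd = multitaper_psd(np.zeros(1000))
        assert not psd.values.any()

    def test_taper_count(self):
        assert multitaper_psd(np.ones(500)).n_tapers == 9

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            multitaper_coherence(np.zeros((2, 100)), np.zeros((2, 99)))


class TestCoherence:
    def test_identity_is_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 1000))
        coh = multitaper_coherence(x, x)
        good = ~np.isnan(coh.values)
        assert np.allclose(coh.values[good], 1.0)

    def test_independent_noise_near_bias_floor(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 1000))
        y = rng.normal(size=(8, 1000))
        coh = multitaper_coherence(x, y)
        bias = shuffle_bias(x, y, n_shuffles=10, seed=0)
        assert coh.values[5:].mean() == pytest.approx(bias.values[5:].mean(), rel=0.5)
        assert coh.values[5:].mean() < 0.1

    def test_shared_component_localized_in_frequency(self):
        rng = np.random.default_rng(3)
        n, trials = 2000, 8
        common = [sinusoid(40.0, n, phase=rng.uniform(0, 2 * np.pi)) for _ in range(trials)]
        x = np.array([c + rng.normal(0, 0.5, n) for c in common])
        y = np.array([np.roll(c, 3) + rng.normal(0, 0.5, n) for c in common])
        coh = multitaper_coherence(x, y)
        at40 = coh.values[np.argmin(np.abs(coh.freqs - 40.0))]
        off = coh.values[(coh.freqs > 100) & (coh.freqs < 200)].mean()
        assert at40 > 0.8 and off < 0.2

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(3, 800))
        y = rng.normal(size=(3, 800)) + 0.5 * x
        a = multitaper_coherence(x, y).values
        b = multitaper_coherence(5.0 * x, 0.2 * y).values
        assert np.allclose(a, b, atol=1e-10, equal_nan=True)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(3, 800))
        y = rng.normal(size=(3, 800)) + 0.5 * x
        assert np.allclose(
            multitaper_coherence(x, y).values,
            multitaper_coherence(y, x).values,
            equal_nan=True,
        )


class TestCoherenceDecomposition:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_phase_kills_phase_component(self, seed):
        """Identical amplitudes, uniformly random relative phase per trial:
        amplitude component high, phase component near the bias floor."""
        rng = np.random.default_rng(seed)
        n, trials = 1000, 12
        amps = rng.uniform(0.5, 1.5, trials)
        x = np.array([sinusoid(40.0, n, a) + rng.normal(0, 0.05, n) for a in amps])
        y = np.array(
            [
                sinusoid(40.0, n, a, phase=rng.uniform(0, 2 * np.pi))
                + rng.normal(0, 0.05, n)
                for a in amps
            ]
        )
        dec = coherence_components(x, y)
        i40 = np.argmin(np.abs(dec.freqs - 40.0))
        assert dec.amplitude_component[i40] > 0.8
        assert dec.phase_component[i40] < 0.3

    @pytest.mark.parametrize("seed", range(10))
    def test_constant_phase_random_amplitude(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, trials = 1000, 24
        ax = rng.uniform(0.3, 2.0, trials)
        ay = rng.uniform(0.3, 2.0, trials)  # independent of ax
        x = np.array([sinusoid(40.0, n, a) + rng.normal(0, 0.02, n) for a in ax])
        y = np.array([sinusoid(40.0, n, a, phase=1.0) + rng.normal(0, 0.02, n) for a in ay])
        dec = coherence_components(x, y)
        i40 = np.argmin(np.abs(dec.freqs - 40.0))
        assert dec.phase_component[i40] > 0.9
        # independent amplitudes: correlation is sampling noise around 0
        assert dec.amplitude_component[i40] < 0.5

    def test_identity_both_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(6, 800))
        dec = coherence_components(x, x)
        assert np.nanmin(dec.phase_component[1:]) > 0.99
        assert np.nanmin(dec.amplitude_component[1:]) > 0.99

    def test_needs_multiple_trials(self):
        with pytest.raises(ValueError):
            coherence_components(np.zeros((1, 100)), np.zeros((1, 100)))

    def test_components_bounded(self):
        fx = gen_phase_locked_oscillation(trials=10, seed=0)
        dec = coherence_components(fx.x, fx.y)
        for comp in (dec.total, dec.amplitude_component, dec.phase_component):
            good = ~np.isnan(comp)
            assert comp[good].min() >= 0.0 and comp[good].max() <= 1.0 + 1e-9


class TestShuffleBias:
    def test_zero_shuffles_rejected(self):
        x = np.zeros((4, 100))
        with pytest.raises(ValueError):
            shuffle_bias(x, x, n_shuffles=0)

    def test_shared_envelope_biases_amplitude_not_phase(self):
        """A shared slow envelope with independent carriers biases the
        amplitude component far more than the phase component."""
        rng = np.random.default_rng(7)
        n, trials = 2000, 10
        t = np.arange(n) / FS
        x, y = [], []
        for _ in range(trials):
            env = 1.0 + 0.8 * np.cos(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi))
            x.append(env * sinusoid(40.0, n, phase=rng.uniform(0, 2 * np.pi)) + rng.normal(0, 0.1, n))
            y.append(env * sinusoid(40.0, n, phase=rng.uniform(0, 2 * np.pi)) + rng.normal(0, 0.1, n))
        x, y = np.array(x), np.array(y)
        amp_bias = shuffle_bias(x, y, 8, seed=1, component="amplitude")
        ph_bias = shuffle_bias(x, y, 8, seed=1, component="phase")
        band = (amp_bias.freqs >= 35) & (amp_bias.freqs <= 45)
        assert amp_bias.values[band].mean() > 1.5 * ph_bias.values[band].mean()


class TestMorlet:
    def test_phase_ramp_and_peak(self):
        f0 = 40.0
        tf = morlet_transform(sinusoid(f0), [f0, 20.0])
        v = tf.valid[0]
        dph = np.diff(np.unwrap(tf.phase[0][v]))
        assert dph.mean() * FS / (2 * np.pi) == pytest.approx(f0, rel=0.01)
        assert tf.power[0][v].mean() > 5 * tf.power[1][tf.valid[1]].mean()

    def test_zero_signal(self):
        tf = morlet_transform(np.zeros(500), [10.0])
        assert not tf.power.any()

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            morlet_transform(np.zeros(500), [600.0])

    def test_envelope_recovery(self):
        n = 4000
        t = np.arange(n) / FS
        env = 1.0 + 0.5 * np.cos(2 * np.pi * 5 * t)
        sig = env * np.cos(2 * np.pi * 40 * t)
        tf = morlet_transform(sig, [40.0])
        amp = np.sqrt(tf.power[0])
        v = tf.valid[0]
        corr = np.corrcoef(amp[v], env[v])[0, 1]
        assert corr > 0.98


class TestBandMetrics:
    def test_delta_peak(self):
        freqs = np.arange(0.0, 101.0, 0.5)
        vals = np.ones_like(freqs)
        vals[freqs == 42.0] = 50.0
        from alphagate.spectral import SpectralEstimate

        est = SpectralEstimate(freqs, vals, 9, 2.5, 1)
        peak, power = band_metrics(est)
        assert peak == 42.0
        band = (freqs >= 32) & (freqs <= 52)
        assert power == pytest.approx(vals[band].mean())

    def test_flat_spectrum(self):
        from alphagate.spectral import SpectralEstimate

        freqs = np.arange(0.0, 101.0, 1.0)
        est = SpectralEstimate(freqs, np.full_like(freqs, 3.0), 9, 2.5, 1)
        _, power = band_metrics(est)
        assert power == pytest.approx(3.0)

    def test_band_outside_rejected(self):
        from alphagate.spectral import SpectralEstimate

        est = SpectralEstimate(np.arange(0.0, 30.0), np.ones(30), 9, 2.5, 1)
        with pytest.raises(ValueError):
            band_metrics(est, search_band=(20.0, 80.0))


class TestAlphaGammaCoupling:
    def test_cosine_power_peaks_at_zero_bin(self):
        phase = np.linspace(0, 40 * np.pi, 4000)
        power = 1.0 + np.cos(phase)
        centers, means = alpha_gamma_coupling(phase, power, 12)
        assert abs(centers[np.nanargmax(means)]) <= 15.0

    def test_constant_power_flat(self):
        phase = np.linspace(0, 40 * np.pi, 4000)
        centers, means = alpha_gamma_coupling(phase, np.ones(4000), 12)
        assert np.nanmax(means) - np.nanmin(means) < 1e-12

    def test_misaligned_traces_rejected(self):
        with pytest.raises(ValueError):
            alpha_gamma_coupling(np.zeros(10), np.zeros(11))
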