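"""Network assembly, integration loop, and derived measurements."""

import numpy as np
import pytest

from alphagate.alpha import AlphaConfig
from alphagate.network import (
    AreaSpec,
    FeedforwardSpec,
    NetworkSpec,
    StimulusSpec,
    compute_sth,
    make_alpha_phases,
    mean_firing_rates,
    run_simulation,
    stimulus_response,
)


@pytest.fixture(scope="module")
def small_area():
    """Down-scaled single area for fast structural tests."""
    noise = {"RS": (4.0, 6.0), "FS": (5.0, 4.0), "LTS": (4.0, 4.0)}
    return NetworkSpec(areas=[AreaSpec(n_rs=80, n_fs=15, n_lts=5, noise=noise)])


class TestRunSimulation:
    def test_deterministic_given_seed(self, small_area):
        a = run_simulation(small_area, duration=500.0, seed=3)
        b = run_simulation(small_area, duration=500.0, seed=3)
        assert a.spikes.equals(b.spikes)

    def test_different_seeds_differ(self, small_area):
        a = run_simulation(small_area, duration=500.0, seed=3)
        b = run_simulation(small_area, duration=500.0, seed=4)
        assert not a.spikes.equals(b.spikes)

    def test_no_drive_no_spikes(self):
        noise = {"RS": (0.0, 0.0), "FS": (0.0, 0.0), "LTS": (0.0, 0.0)}
        spec = NetworkSpec(areas=[AreaSpec(n_rs=20, n_fs=4, n_lts=2, noise=noise)])
        res = run_simulation(spec, duration=300.0, seed=0)
        assert len(res.spikes) == 0

    def test_spike_times_within_duration(self, small_area):
        res = run_simulation(small_area, duration=400.0, seed=1)
        t = res.spikes["time_ms"]
        assert (t > 0).all() and (t <= 400.0).all()

    def test_short_duration_rejected(self, small_area):
        with pytest.raises(ValueError):
            run_simulation(small_area, duration=50.0)

    def test_two_area_layout_and_ff_targets(self):
        spec = NetworkSpec(
            areas=[AreaSpec(n_rs=40, n_fs=8, n_lts=4), AreaSpec(n_rs=40, n_fs=8, n_lts=4)],
            directionality="forward",
            feedforward=FeedforwardSpec(probability=0.5),
        )
        res = run_simulation(spec, duration=300.0, seed=0)
        assert set(res.spikes["area"].unique()) <= {0, 1}
        # feedforward target map: sources are area-1 RS, targets area-2 RS
        assert res.ff_targets
        src = np.array(sorted(res.ff_targets))
        assert src.min() >= 0 and src.max() < 40
        tgts = np.concatenate([v for v in res.ff_targets.values() if len(v)])
        assert tgts.min() >= 52 and tgts.max() < 92

    def test_selective_wiring_respects_subpopulations(self):
        spec = NetworkSpec(
            areas=[AreaSpec(n_rs=40, n_fs=8, n_lts=4), AreaSpec(n_rs=40, n_fs=8, n_lts=4)],
            directionality="forward",
            feedforward=FeedforwardSpec(probability=1.0),
            subpopulations=True,
            selective=True,
        )
        res = run_simulation(spec, duration=300.0, seed=0)
        for pre, posts in res.ff_targets.items():
            pre_sub = 0 if pre < 20 else 1
            for p in posts:
                post_sub = 0 if (p - 52) < 20 else 1
                assert post_sub == pre_sub


class TestSth:
    def test_counts_and_sum(self, small_area):
        res = run_simulation(small_area, duration=500.0, seed=2)
        sth = compute_sth(res, 0, ("RS", "FS", "LTS"))
        assert sth.sum() == len(res.spikes)
        assert sth.size == 500

    def test_empty_selection_zero_series(self, small_area):
        res = run_simulation(small_area, duration=300.0, seed=2)
        sth = compute_sth(res, area=1, types=("RS",))
        assert not sth.any()

    def test_manual_binning(self, small_area):
        res = run_simulation(small_area, duration=300.0, seed=5)
        sth = compute_sth(res, 0, ("RS",))
        df = res.select(area=0, types="RS")
        t = df["time_ms"].to_numpy()
        assert sth[10] == np.count_nonzero((t >= 10.0) & (t < 11.0))


class TestRatesAndResponse:
    def test_rate_formula(self, small_area):
        res = run_simulation(small_area, duration=1000.0, seed=0)
        rates = mean_firing_rates(res)
        n_rs = small_area.areas[0].n_rs
        expect = len(res.select(area=0, types="RS")) / (n_rs * 1.0)
        assert rates[(0, "RS")] == pytest.approx(expect)

    def test_zero_spikes_zero_rate(self):
        noise = {"RS": (0.0, 0.0), "FS": (0.0, 0.0), "LTS": (0.0, 0.0)}
        spec = NetworkSpec(areas=[AreaSpec(n_rs=10, n_fs=2, n_lts=1, noise=noise)])
        res = run_simulation(spec, duration=200.0, seed=0)
        assert all(v == 0.0 for v in mean_firing_rates(res).values())

    def test_zero_amplitude_stimulus_zero_response(self, small_area):
        stim = StimulusSpec(area=0, onsets=(200.0,), duration=30.0, amplitude=0.0)
        res = run_simulation(small_area, stim=stim, duration=400.0, seed=9)
        base = run_simulation(small_area, duration=400.0, seed=9)
        assert stimulus_response(res, stim, base) == pytest.approx(0.0, abs=1e-12)

    def test_positive_stimulus_positive_response(self, small_area):
        stim = StimulusSpec(area=0, onsets=(200.0,), duration=30.0, amplitude=60.0)
        res = run_simulation(small_area, stim=stim, duration=400.0, seed=9)
        base = run_simulation(small_area, duration=400.0, seed=9)
        assert stimulus_response(res, stim, base) > 0.0

    def test_window_past_end_rejected(self, small_area):
        stim = StimulusSpec(area=0, onsets=(390.0,), duration=10.0, amplitude=10.0)
        with pytest.raises(ValueError):
            run_simulation(small_area, stim=stim, duration=395.0, seed=0)


class TestAlphaIntegration:
    def test_external_phases_are_used_verbatim(self, small_area):
        alpha = AlphaConfig()
        phases = make_alpha_phases(alpha, 1, 400.0, seed=5)
        res = run_simulation(small_area, alpha=alpha, duration=400.0, seed=5,
                             alpha_phases=phases)
        assert np.array_equal(res.alpha_phases[0].phases, phases[0].phases)

    def test_alpha_modulates_inhibitory_rates(self, small_area):
        base = run_simulation(small_area, duration=1000.0, seed=1)
        mod = run_simulation(small_area, alpha=AlphaConfig(), duration=1000.0, seed=1)
        r0 = mean_firing_rates(base)
        r1 = mean_firing_rates(mod)
        assert r1[(0, "FS")] > r0[(0, "FS")]  # extra non-negative drive

    def test_currents_recorded(self, small_area):
        res = run_simulation(small_area, alpha=AlphaConfig(), duration=400.0, seed=1)
        assert len(res.alpha_currents) == 1
        assert res.alpha_currents[0].min() >= 0.0  # sin^2 waveform
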