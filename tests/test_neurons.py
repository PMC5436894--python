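"""Single-neuron dynamics, synaptic decay and connectivity construction."""

import numpy as np
import pytest

from alphagate.neurons import (
    CONNECTIVITY_BOUNDS,
    CellType,
    NeuronState,
    SynapticState,
    UnknownCellTypeError,
    build_connectivity,
    fi_curve,
    izhikevich_step,
    make_neuron_params,
    resting_state,
    rheobase,
    update_synaptic_currents,
)


@pytest.mark.parametrize(
    "cell_type, expected",
    [
        ("RS", (0.02, 0.2, -65.0, 8.0)),
        ("FS", (0.1, 0.2, -65.0, 2.0)),
        ("LTS", (0.02, 0.25, -65.0, 2.0)),
    ],
)
def test_parameter_table(cell_type, expected):
    p = make_neuron_params(cell_type)
    assert (p.a, p.b, p.c, p.d) == expected


def test_unknown_cell_type_rejected():
    with pytest.raises(UnknownCellTypeError):
        make_neuron_params("chattering")


@pytest.mark.parametrize("cell_type", ["RS", "FS", "LTS"])
def test_resting_state_is_fixed_point(cell_type):
    """The analytic rest point stays stationary over 10^4 steps at I=0."""
    p = make_neuron_params(cell_type)
    state = resting_state(p)
    v0, u0 = state.v, state.u
    for _ in range(10_000):
        state, spiked = izhikevich_step(state, p, 0.0, 0.5)
        assert not spiked
    assert state.v == pytest.approx(v0, abs=1e-9)
    assert state.u == pytest.approx(u0, abs=1e-9)


def test_spike_resets_membrane_and_increments_recovery():
    p = make_neuron_params("RS")
    state = NeuronState(v=29.0, u=0.0)
    new, spiked = izhikevich_step(state, p, 200.0, 0.5)
    assert spiked
    assert new.v == p.c
    # u after reset = euler-updated u + d
    u_euler = 0.0 + 0.5 * p.a * (p.b * 29.0 - 0.0)
    assert new.u == pytest.approx(u_euler + p.d)


def test_suprathreshold_rate_matches_fine_step_reference():
    """Tonic spike count at dt=0.5 ms stays close to a dt=0.01 ms reference
    (forward Euler at the production step carries a few-percent period
    error; 5% bounds it across the tested drive range)."""
    p = make_neuron_params("RS")
    I = 10.0
    counts = {}
    for dt in (0.5, 0.01):
        state = resting_state(p)
        n = 0
        steps = int(round(2000.0 / dt))
        for _ in range(steps):
            state, spiked = izhikevich_step(state, p, I, dt)
            n += spiked
        counts[dt] = n
    assert counts[0.5] == pytest.approx(counts[0.01], rel=0.05)


def test_reset_count_equals_spike_count():
    p = make_neuron_params("FS")
    state = resting_state(p)
    spikes = resets = 0
    for _ in range(4000):
        prev_v = state.v
        state, spiked = izhikevich_step(state, p, 8.0, 0.5)
        spikes += spiked
        resets += state.v == p.c and prev_v != p.c
    assert spikes > 0 and spikes == resets


class TestFiCurve:
    def test_zero_current_is_silent(self):
        for ct in ("RS", "FS", "LTS"):
            rates = fi_curve(make_neuron_params(ct), [0.0], duration=1000.0)
            assert rates[0] == 0.0

    def test_monotone_above_rheobase(self):
        p = make_neuron_params("RS")
        grid = np.linspace(0, 20, 9)
        rates = fi_curve(p, grid, duration=1000.0)
        assert np.all(np.diff(rates) >= 0)

    def test_rheobase_brackets_onset(self):
        """Sustained firing from rest starts where the quadratic fixed
        points merge (discriminant of 0.04 v^2 + (5 - b) v + 140 + I = 0).
        Below it at most a transient spike occurs on current onset; above
        it the neuron fires tonically."""
        p = make_neuron_params("RS")
        rb = rheobase(p)
        disc = (5.0 - p.b) ** 2 - 4 * 0.04 * (140.0 + rb)
        assert disc == pytest.approx(0.0, abs=1e-12)
        below, above = fi_curve(p, [rb - 1.0, rb + 1.0], duration=1500.0)
        assert below <= 1.0  # at most one onset transient
        assert above >= 5.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            fi_curve(make_neuron_params("RS"), [])


class TestConnectivity:
    sizes = {"RS": 20, "FS": 6, "LTS": 4}

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_signs_and_diagonal(self, seed):
        cm = build_connectivity(self.sizes, seed)
        W = cm.weights
        assert np.all(np.diag(W) == 0.0)
        for (pre, post), bound in CONNECTIVITY_BOUNDS.items():
            rows = np.flatnonzero(cm.pre_type == pre.value)
            cols = np.flatnonzero(cm.post_type == post.value)
            block = W[np.ix_(rows, cols)]
            if bound >= 0:
                assert np.all(block >= 0) and np.all(block <= bound)
            else:
                assert np.all(block <= 0) and np.all(block >= bound)

    def test_lts_to_lts_absent(self):
        cm = build_connectivity(self.sizes, 3)
        lts = np.flatnonzero(cm.pre_type == "LTS")
        assert np.all(cm.weights[np.ix_(lts, lts)] == 0.0)

    def test_reproducible_from_seed(self):
        a = build_connectivity(self.sizes, 11).weights
        b = build_connectivity(self.sizes, 11).weights
        assert np.array_equal(a, b)

    def test_nonzero_off_diagonal(self):
        cm = build_connectivity(self.sizes, 0)
        rs = np.flatnonzero(cm.pre_type == "RS")
        block = cm.weights[np.ix_(rs, rs)]
        assert (block > 0).sum() > 0.9 * (block.size - len(rs))


class TestSynapticDecay:
    def test_exponential_decay_closed_form(self):
        syn = SynapticState(psc_e=np.array([1.0]), psc_i=np.array([-1.0]))
        cm = build_connectivity({"RS": 1, "FS": 1}, 0)
        no_spikes = np.zeros(2, dtype=bool)
        t = 0.0
        while t < 100.0 - 1e-9:
            syn = update_synaptic_currents(syn, no_spikes, cm, 0.5)
            t += 0.5
        assert syn.psc_e[0] == pytest.approx(np.exp(-100.0 / 2.5), rel=1e-12)
        assert syn.psc_i[0] == pytest.approx(-np.exp(-100.0 / 6.0), rel=1e-12)

    def test_single_step_scale(self):
        syn = SynapticState(psc_e=np.array([2.0]), psc_i=np.array([0.0]))
        cm = build_connectivity({"RS": 1, "FS": 1}, 0)
        out = update_synaptic_currents(syn, np.zeros(2, dtype=bool), cm, 0.5)
        assert out.psc_e[0] == pytest.approx(2.0 * np.exp(-0.2))

    def test_spike_adds_weight_row(self):
        cm = build_connectivity({"RS": 3, "FS": 2}, 5)
        syn = SynapticState(psc_e=np.zeros(5), psc_i=np.zeros(5))
        spikes = np.array([True, False, False, False, True])
        out = update_synaptic_currents(syn, spikes, cm, 0.5)
        assert np.allclose(out.psc_e, cm.weights[0])
        assert np.allclose(out.psc_i, cm.weights[4])

    def test_zero_in_zero_out(self):
        cm = build_connectivity({"RS": 2, "FS": 1}, 0)
        syn = SynapticState(psc_e=np.zeros(3), psc_i=np.zeros(3))
        out = update_synaptic_currents(syn, np.zeros(3, dtype=bool), cm, 0.5)
        assert not out.psc_e.any() and not out.psc_i.any()
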