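"""Assembly and integration of one- or two-area spiking networks.

Each cortical area is a local population of 400 regular-spiking (RS)
pyramidal cells, 75 fast-spiking (FS) and 25 low-threshold-spiking (LTS)
interneurons with all-to-all random connectivity.  Gamma oscillations arise
from the pyramidal-interneuron (PING) loop; an alpha-band current injected
into the interneurons rhythmically gates them.  Two areas can be connected
by sparse feedforward (and optionally feedback) projections originating
from the RS cells.

Integration follows the standard scheme for this neuron model: each 1 ms
simulation step consists of two sequential forward-Euler substeps of
0.5 ms, with spike detection (v >= 30 mV) and reset applied after every
substep.  Every neuron receives an independent Gaussian noise current drawn
per substep from a per-type N(mu, sigma) (Table values RS(4,6), FS(5,4),
LTS(4,4)); the draw is deliberately not rescaled by sqrt(dt), so the noise
level is tied to the 0.5 ms substep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alpha import (
    PA_TO_MODEL,
    AlphaConfig,
    PhaseTrace,
    generate_coupled_phases,
    modulation_current,
)
from .neurons import (
    CellType,
    CONNECTIVITY_BOUNDS,
    SimulationDivergedError,
    build_connectivity,
    make_neuron_params,
    resting_state,
)

__all__ = [
    "AreaSpec",
    "FeedforwardSpec",
    "NetworkSpec",
    "StimulusSpec",
    "SimulationResult",
    "make_alpha_phases",
    "run_simulation",
    "compute_sth",
    "mean_firing_rates",
    "stimulus_response",
]

DEFAULT_NOISE = {
    CellType.RS: (4.0, 6.0),
    CellType.FS: (5.0, 4.0),
    CellType.LTS: (4.0, 4.0),
}

_TYPE_CODE = {CellType.RS: 0, CellType.FS: 1, CellType.LTS: 2}
_CODE_TYPE = {v: k for k, v in _TYPE_CODE.items()}


@dataclass
class AreaSpec:
    """One cortical area: population sizes, noise drive, alpha routing."""

    n_rs: int = 400
    n_fs: int = 75
    n_lts: int = 25
    noise: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    alpha_target: str = "inhibitory"  # 'inhibitory' | 'excitatory' | 'none'

    def __post_init__(self):
        if min(self.n_rs, self.n_fs, self.n_lts) <= 0:
            raise ValueError("population sizes must be positive")
        if self.alpha_target not in ("inhibitory", "fs", "excitatory", "none"):
            raise ValueError("alpha_target must be inhibitory/fs/excitatory/none")
        self.noise = {CellType(k): tuple(v) for k, v in self.noise.items()}

    @property
    def n_total(self) -> int:
        return self.n_rs + self.n_fs + self.n_lts


@dataclass
class FeedforwardSpec:
    """Inter-areal projection: random RS -> {RS, FS} connections.

    The projection mirrors the local wiring convention: a source RS cell
    contacts each RS / FS cell of the other area with probability
    ``probability`` (1 = all-to-all, the default, matching the local
    all-to-all rule), with weights drawn uniformly on
    [0, strength_scale * local bound] for the matching (RS -> post) pair.
    LTS cells receive no inter-areal input.  These parameters are the
    largest free choice of the model (no reference values exist); the
    defaults keep receiving-area rates within the single-area ranges while
    the projection entrains the receiving gamma rhythm.
    """

    probability: float = 1.0
    strength_scale: float = 1.0
    fs_strength_scale: float = 1.0  # extra factor on the RS -> FS component

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        if self.strength_scale < 0 or self.fs_strength_scale < 0:
            raise ValueError("strength scales must be >= 0")


@dataclass
class NetworkSpec:
    """One or two areas plus the inter-areal wiring between them."""

    areas: list = field(default_factory=lambda: [AreaSpec()])
    directionality: str = "none"  # 'none' | 'forward' | 'bidirectional'
    feedforward: FeedforwardSpec = field(default_factory=FeedforwardSpec)
    subpopulations: bool = False  # split RS cells into two labeled halves
    selective: bool = False  # feedforward respects subpopulation identity

    def __post_init__(self):
        if self.directionality not in ("none", "forward", "bidirectional"):
            raise ValueError("directionality must be none/forward/bidirectional")
        if self.directionality != "none" and len(self.areas) < 2:
            raise ValueError("inter-areal wiring needs two areas")
        if self.selective and not self.subpopulations:
            raise ValueError("selective wiring requires subpopulations")


@dataclass
class StimulusSpec:
    """Step-current stimulus to (a subpopulation of) the RS cells of an area.

    ``onsets`` allows several presentations within one trial; each lasts
    ``duration`` ms at constant ``amplitude``.  ``subpop`` restricts the
    stimulated cells to one labeled RS half (None stimulates all RS cells).
    """

    area: int = 0
    subpop: int | None = None
    onsets: tuple = (500.0,)
    duration: float = 50.0
    amplitude: float = 40.0  # pA

    def __post_init__(self):
        if np.isscalar(self.onsets):
            self.onsets = (float(self.onsets),)
        self.onsets = tuple(float(o) for o in self.onsets)
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")


@dataclass
class SimulationResult:
    """Spike trains plus the phase/current context of one simulated trial."""

    spikes: pd.DataFrame  # time_ms, neuron_id, area, cell_type, subpop
    duration: float
    dt: float
    areas: list
    alpha_phases: list  # PhaseTrace per area (dt-sampled), or []
    alpha_currents: list  # per-area applied current per substep, or []
    spec: NetworkSpec = None
    alpha: AlphaConfig = None
    stimulus: StimulusSpec = None
    seed: int = None
    ff_targets: dict = None  # area-1 RS id -> array of area-2 RS target ids

    def save_spikes(self, path) -> None:
        """Write the spike table (time_ms, neuron_id, area, cell_type,
        subpop) as CSV."""
        self.spikes.to_csv(path, index=False)

    def select(self, area=None, types=None, subpop=None) -> pd.DataFrame:
        df = self.spikes
        if area is not None:
            df = df[df["area"] == area]
        if types is not None:
            if isinstance(types, (str, CellType)):
                types = [types]
            names = [CellType(t).value for t in types]
            df = df[df["cell_type"].isin(names)]
        if subpop is not None:
            df = df[df["subpop"] == subpop]
        return df


def _area_layout(spec: NetworkSpec):
    """Global index layout: per-neuron type codes, area ids, subpop labels."""
    type_code, area_id, subpop = [], [], []
    offsets = []
    for ai, area in enumerate(spec.areas):
        offsets.append(len(type_code))
        type_code.extend([0] * area.n_rs)
        if spec.subpopulations:
            half = area.n_rs // 2
            subpop.extend([0] * half + [1] * (area.n_rs - half))
        else:
            subpop.extend([-1] * area.n_rs)
        type_code.extend([1] * area.n_fs + [2] * area.n_lts)
        subpop.extend([-1] * (area.n_fs + area.n_lts))
        area_id.extend([ai] * area.n_total)
    return (
        np.array(type_code, dtype=np.int8),
        np.array(area_id, dtype=np.int8),
        np.array(subpop, dtype=np.int8),
        offsets,
    )


def _build_weights(spec: NetworkSpec, type_code, area_id, subpop, offsets, rng):
    """Full weight matrix plus the area-1 RS -> area-2 RS target map used
    by spike-transmission analyses."""
    n = type_code.size
    W = np.zeros((n, n))
    # Within-area all-to-all blocks.
    for ai, area in enumerate(spec.areas):
        sizes = [(CellType.RS, area.n_rs), (CellType.FS, area.n_fs), (CellType.LTS, area.n_lts)]
        local = build_connectivity(sizes, rng)
        sl = slice(offsets[ai], offsets[ai] + area.n_total)
        W[sl, sl] = local.weights
    # Inter-areal projections.
    pairs = []
    if spec.directionality in ("forward", "bidirectional"):
        pairs.append((0, 1))
    if spec.directionality == "bidirectional":
        pairs.append((1, 0))
    ff = spec.feedforward
    ff_targets: dict[int, np.ndarray] = {}
    for src, dst in pairs:
        rows = np.flatnonzero((area_id == src) & (type_code == 0))
        for post_ct in (CellType.RS, CellType.FS):
            bound = ff.strength_scale * CONNECTIVITY_BOUNDS[(CellType.RS, post_ct)]
            if post_ct == CellType.FS:
                bound *= ff.fs_strength_scale
            cols = np.flatnonzero((area_id == dst) & (type_code == _TYPE_CODE[post_ct]))
            if rows.size == 0 or cols.size == 0 or bound == 0:
                continue
            mask = rng.uniform(size=(rows.size, cols.size)) < ff.probability
            w = rng.uniform(0.0, bound, size=(rows.size, cols.size)) * mask
            if spec.selective and post_ct == CellType.RS:
                # Wire subpopulation k of the source only onto subpopulation
                # k of the target (no overlap between the two channels).
                same = subpop[rows][:, None] == subpop[cols][None, :]
                w = w * same
            W[np.ix_(rows, cols)] = w
            if src == 0 and dst == 1 and post_ct == CellType.RS:
                for i, r in enumerate(rows):
                    ff_targets[int(r)] = cols[w[i] > 0].astype(int)
    return W, ff_targets


def make_alpha_phases(
    alpha: AlphaConfig,
    n_areas: int,
    duration: float,
    dt: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> list[PhaseTrace]:
    """Alpha phase trajectories with the simulator's sign convention.

    For two areas the user-facing delta-phi (negative = area 1's excitable
    window leads in time) is mapped onto the phase-lock target; a single
    area gets one zero-offset trace.  Useful for placing stimuli at chosen
    alpha phases: generate the traces first, then pass them to
    ``run_simulation(..., alpha_phases=...)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_areas >= 2:
        cfg = replace(alpha, target_offset=-alpha.target_offset)
        t1, t2 = generate_coupled_phases(cfg, duration, dt, rng)
        return [t1, t2]
    cfg0 = replace(alpha, target_offset=0.0)
    t1, _ = generate_coupled_phases(cfg0, duration, dt, rng)
    return [t1]


def run_simulation(
    spec: NetworkSpec,
    alpha: AlphaConfig | None = None,
    stim: StimulusSpec | None = None,
    duration: float = 2000.0,
    seed: int | None = None,
    dt: float = 0.5,
    alpha_phases: list[PhaseTrace] | None = None,
) -> SimulationResult:
    """Integrate the network for ``duration`` ms and collect spikes.

    Per-neuron input per substep = within/inter-areal PSCs + Gaussian noise
    + alpha modulation current (to each area's configured target cells) +
    stimulus current while active.  Fully deterministic given ``seed``.
    """
    if duration < 100:
        raise ValueError("duration must be at least 100 ms")
    rng = np.random.default_rng(seed)
    type_code, area_id, subpop, offsets = _area_layout(spec)
    n = type_code.size
    W, ff_targets = _build_weights(spec, type_code, area_id, subpop, offsets, rng)
    W_exc_rows = W[type_code == 0, :]
    W_inh_rows = W[type_code != 0, :]
    exc_row_of = np.cumsum(type_code == 0) - 1
    inh_row_of = np.cumsum(type_code != 0) - 1

    # Per-neuron Izhikevich parameters and noise settings.
    abcd = np.empty((n, 4))
    mu = np.empty(n)
    sigma = np.empty(n)
    for ai, area in enumerate(spec.areas):
        for code, ct in _CODE_TYPE.items():
            m = (area_id == ai) & (type_code == code)
            p = make_neuron_params(ct)
            abcd[m] = (p.a, p.b, p.c, p.d)
            mu[m], sigma[m] = area.noise[ct]
    a_par, b_par, c_par, d_par = abcd.T.copy()

    # Initial conditions: per-type analytic rest plus small jitter.
    v = np.empty(n)
    u = np.empty(n)
    for code, ct in _CODE_TYPE.items():
        m = type_code == code
        rest = resting_state(make_neuron_params(ct))
        v[m] = rest.v
        u[m] = rest.u
    v += rng.normal(0.0, 1.0, size=n)

    # Alpha drive: coupled phases for two areas, a single trace otherwise.
    # User-facing delta-phi labels sender-leading offsets negative (the
    # reported optimum, -90 deg, is the state where area 1's excitable
    # window precedes area 2's by ~25 ms); make_alpha_phases applies the
    # corresponding lock target.
    n_sub = int(round(duration / dt))
    alpha_I = np.zeros((max(len(spec.areas), 1), n_sub))
    if alpha is not None and alpha.amplitude > 0:
        if alpha_phases is None:
            alpha_phases = make_alpha_phases(alpha, len(spec.areas), duration, dt, rng)
        amp_model = alpha.amplitude * PA_TO_MODEL
        for ai, tr in enumerate(alpha_phases):
            alpha_I[ai] = modulation_current(tr, amp_model, alpha.waveform)[:n_sub]
    else:
        alpha_phases = []
    alpha_masks = []
    for ai, area in enumerate(spec.areas):
        if area.alpha_target == "inhibitory":
            m = (area_id == ai) & (type_code != 0)
        elif area.alpha_target == "fs":
            m = (area_id == ai) & (type_code == 1)
        elif area.alpha_target == "excitatory":
            m = (area_id == ai) & (type_code == 0)
        else:
            m = np.zeros(n, dtype=bool)
        alpha_masks.append(m)

    stim_mask = None
    stim_steps = None
    if stim is not None:
        stim_mask = (area_id == stim.area) & (type_code == 0)
        if stim.subpop is not None:
            stim_mask &= subpop == stim.subpop
        active = np.zeros(n_sub, dtype=bool)
        for onset in stim.onsets:
            if onset + stim.duration > duration:
                raise ValueError("stimulus extends past simulation end")
            i0 = int(round(onset / dt))
            i1 = int(round((onset + stim.duration) / dt))
            active[i0:i1] = True
        stim_steps = active

    psc_e = np.zeros(n)
    psc_i = np.zeros(n)
    decay_e = np.exp(-dt / 2.5)
    decay_i = np.exp(-dt / 6.0)
    spike_steps: list[np.ndarray] = []
    spike_ids: list[np.ndarray] = []

    for k in range(n_sub):
        I = psc_e + psc_i + rng.normal(mu, sigma)
        if alpha_phases:
            for ai in range(len(spec.areas)):
                m = alpha_masks[ai]
                if m.any():
                    I[m] += alpha_I[ai, k]
        if stim_steps is not None and stim_steps[k]:
            I[stim_mask] += stim.amplitude * PA_TO_MODEL
        v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
        u += dt * a_par * (b_par * v - u)
        v = v_new
        if not np.isfinite(v).all():
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise SimulationDivergedError(
                f"non-finite membrane potential at neuron {bad}, t={(k + 1) * dt} ms"
            )
        spiked = v >= 30.0
        if spiked.any():
            idx = np.flatnonzero(spiked)
            spike_steps.append(np.full(idx.size, k, dtype=np.int32))
            spike_ids.append(idx.astype(np.int32))
            v[idx] = c_par[idx]
            u[idx] += d_par[idx]
            exc = idx[type_code[idx] == 0]
            inh = idx[type_code[idx] != 0]
            psc_e = psc_e * decay_e
            psc_i = psc_i * decay_i
            if exc.size:
                psc_e = psc_e + W_exc_rows[exc_row_of[exc]].sum(axis=0)
            if inh.size:
                psc_i = psc_i + W_inh_rows[inh_row_of[inh]].sum(axis=0)
        else:
            psc_e = psc_e * decay_e
            psc_i = psc_i * decay_i

    if spike_steps:
        steps = np.concatenate(spike_steps)
        ids = np.concatenate(spike_ids)
    else:
        steps = np.empty(0, dtype=np.int32)
        ids = np.empty(0, dtype=np.int32)
    spikes = pd.DataFrame(
        {
            "time_ms": (steps + 1) * dt,
            "neuron_id": ids,
            "area": area_id[ids],
            "cell_type": pd.Categorical.from_codes(
                type_code[ids], categories=["RS", "FS", "LTS"]
            ),
            "subpop": subpop[ids],
        }
    )
    return SimulationResult(
        spikes=spikes,
        duration=duration,
        dt=dt,
        areas=list(spec.areas),
        alpha_phases=alpha_phases,
        alpha_currents=[alpha_I[ai] for ai in range(len(spec.areas))] if alpha_phases else [],
        spec=spec,
        alpha=alpha,
        stimulus=stim,
        seed=seed,
        ff_targets=ff_targets,
    )


def compute_sth(
    result: SimulationResult,
    area: int = 0,
    types=("RS",),
    bin_ms: float = 1.0,
    subpop: int | None = None,
) -> np.ndarray:
    """Spike-time histogram: population spike count per ``bin_ms`` bin."""
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    df = result.select(area=area, types=types, subpop=subpop)
    n_bins = int(round(result.duration / bin_ms))
    counts, _ = np.histogram(
        df["time_ms"].to_numpy(), bins=n_bins, range=(0.0, n_bins * bin_ms)
    )
    return counts.astype(float)


def mean_firing_rates(result: SimulationResult) -> dict:
    """Mean rate per (area, cell type): total spikes / (N * T), in Hz."""
    T = result.duration / 1000.0
    rates = {}
    for ai, area in enumerate(result.areas):
        sizes = {"RS": area.n_rs, "FS": area.n_fs, "LTS": area.n_lts}
        for ct, N in sizes.items():
            count = len(result.select(area=ai, types=ct))
            rates[(ai, ct)] = count / (N * T)
    return rates


def stimulus_response(
    result: SimulationResult,
    stim: StimulusSpec,
    baseline_result: SimulationResult,
    window: float = 30.0,
    area: int | None = None,
    subpop: int | None = None,
) -> float:
    """Stimulus-evoked rate increase (Hz) in a post-onset window.

    Rate of the selected population during [onset, onset + window] minus the
    rate of a matched no-stimulus baseline in the same window (the baseline
    run shares the seed, so its alpha phase is aligned); averaged over all
    presentations in the trial.
    """
    if result.stimulus is None:
        raise ValueError("result does not contain a stimulus")
    target_area = stim.area if area is None else area
    ar = result.areas[target_area]
    if subpop is None:
        n_neurons = ar.n_rs
    else:
        half = ar.n_rs // 2
        n_neurons = half if subpop == 0 else ar.n_rs - half
    t_stim = result.select(area=target_area, types="RS", subpop=subpop)["time_ms"].to_numpy()
    t_base = baseline_result.select(area=target_area, types="RS", subpop=subpop)[
        "time_ms"
    ].to_numpy()
    deltas = []
    for onset in stim.onsets:
        if onset + window > result.duration:
            raise ValueError("response window extends past simulation end")
        c_stim = np.count_nonzero((t_stim >= onset) & (t_stim < onset + window))
        c_base = np.count_nonzero((t_base >= onset) & (t_base < onset + window))
        deltas.append((c_stim - c_base) / (n_neurons * window / 1000.0))
    return float(np.mean(deltas))
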