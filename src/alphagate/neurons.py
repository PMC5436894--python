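"""Izhikevich neuron dynamics, synaptic currents and local connectivity.

Each model neuron follows the two-variable quadratic integrate-and-fire
formulation

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)

with a hard reset when the membrane potential ``v`` crosses +30 mV from
below: ``v <- c`` and ``u <- u + d``.  Three cell types are used: regular
spiking pyramidal cells (RS), fast spiking interneurons (FS) and
low-threshold spiking interneurons (LTS), distinguished only by the four
dimensionless parameters (a, b, c, d).

Synapses are current based: each presynaptic spike instantaneously adds a
fixed per-pair amplitude to the postsynaptic current, which then decays
exponentially with tau_E = 2.5 ms (AMPA-like) or tau_I = 6 ms (GABA-like).
Within a population connectivity is all-to-all (no self-connections) with
per-pair strengths drawn uniformly between zero and a signed bound that
depends on the (pre, post) type pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "CellType",
    "NeuronParams",
    "NeuronState",
    "ConnectivityMatrix",
    "SynapticState",
    "TAU_E",
    "TAU_I",
    "CONNECTIVITY_BOUNDS",
    "make_neuron_params",
    "resting_state",
    "izhikevich_step",
    "fi_curve",
    "rheobase",
    "build_connectivity",
    "update_synaptic_currents",
]

TAU_E = 2.5  # ms, decay of excitatory (AMPA-like) postsynaptic currents
TAU_I = 6.0  # ms, decay of inhibitory (GABA-like) postsynaptic currents

SPIKE_PEAK = 30.0  # mV, membrane potential at the spike peak / reset threshold


class CellType(str, Enum):
    RS = "RS"
    FS = "FS"
    LTS = "LTS"


class UnknownCellTypeError(ValueError):
    """Raised when a cell type is not one of RS, FS, LTS."""


class SimulationDivergedError(FloatingPointError):
    """Raised when the membrane state becomes non-finite during integration."""


# (a, b, c, d) per cell type.
_PARAM_TABLE = {
    CellType.RS: (0.02, 0.2, -65.0, 8.0),
    CellType.FS: (0.1, 0.2, -65.0, 2.0),
    CellType.LTS: (0.02, 0.25, -65.0, 2.0),
}

# Signed per-spike PSC amplitude bounds for (pre -> post) pairs.  Each actual
# weight is drawn uniformly between 0 and the bound (sign carried by the
# bound).  Rows: presynaptic type, columns: postsynaptic type.
CONNECTIVITY_BOUNDS = {
    (CellType.RS, CellType.RS): 0.0375,
    (CellType.RS, CellType.FS): 0.125,
    (CellType.RS, CellType.LTS): 0.125,
    (CellType.FS, CellType.RS): -0.25,
    (CellType.FS, CellType.FS): -0.15,
    (CellType.FS, CellType.LTS): -0.1,
    (CellType.LTS, CellType.RS): -0.3,
    (CellType.LTS, CellType.FS): -0.1,
    (CellType.LTS, CellType.LTS): 0.0,
}


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich parameters for one cell type.

    ``a`` sets the recovery time scale, ``b`` the sensitivity of recovery to
    ``v``, ``c`` the post-spike reset potential (mV) and ``d`` the post-spike
    increment of the recovery variable.
    """

    cell_type: CellType
    a: float
    b: float
    c: float
    d: float


@dataclass
class NeuronState:
    """Membrane potential ``v`` (mV) and recovery variable ``u``."""

    v: float
    u: float


@dataclass
class ConnectivityMatrix:
    """Signed per-pair synaptic strengths with per-index type labels.

    ``weights[i, j]`` is the PSC amplitude that a spike of presynaptic neuron
    ``i`` evokes in postsynaptic neuron ``j``.  Excitatory rows are >= 0,
    inhibitory rows <= 0, and the diagonal is zero.
    """

    weights: np.ndarray
    pre_type: np.ndarray  # array of CellType, one per row
    post_type: np.ndarray  # array of CellType, one per column


@dataclass
class SynapticState:
    """Per-neuron excitatory and inhibitory PSC accumulators."""

    psc_e: np.ndarray
    psc_i: np.ndarray
    tau_e: float = TAU_E
    tau_i: float = TAU_I


def make_neuron_params(cell_type: CellType | str) -> NeuronParams:
    """Return the (a, b, c, d) parameter set for one of RS, FS, LTS."""
    try:
        ct = CellType(cell_type)
    except ValueError as err:
        raise UnknownCellTypeError(f"unknown cell type: {cell_type!r}") from err
    a, b, c, d = _PARAM_TABLE[ct]
    return NeuronParams(ct, a, b, c, d)


def resting_state(params: NeuronParams) -> NeuronState:
    """Analytic resting fixed point at I = 0.

    On the u-nullcline u = b v, so the rest potential solves
    0.04 v^2 + (5 - b) v + 140 = 0; the stable root is the more negative one.
    """
    b = params.b
    disc = (5.0 - b) ** 2 - 4 * 0.04 * 140.0
    if disc < 0:
        raise ValueError("no resting fixed point for these parameters")
    v_rest = (-(5.0 - b) - np.sqrt(disc)) / (2 * 0.04)
    return NeuronState(v=v_rest, u=b * v_rest)


def rheobase(params: NeuronParams) -> float:
    """Constant current at which the resting fixed point disappears.

    The v- and u-nullclines merge when the discriminant of
    0.04 v^2 + (5 - b) v + 140 + I vanishes.
    """
    b = params.b
    return ((5.0 - b) ** 2 - 4 * 0.04 * 140.0) / (4 * 0.04)


def izhikevich_step(
    state: NeuronState, params: NeuronParams, I: float, dt: float
) -> tuple[NeuronState, bool]:
    """Advance one neuron by a single forward-Euler step of length ``dt`` ms.

    Returns the new state and a flag indicating whether the membrane crossed
    the +30 mV spike peak during this step (in which case the returned state
    is already reset).  The spike time is the time of the step at which the
    peak was reached, i.e. the end of this step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(I):
        raise ValueError("input current must be finite")
    v, u = state.v, state.u
    v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
    u_new = u + dt * params.a * (params.b * v - u)
    if not (np.isfinite(v_new) and np.isfinite(u_new)):
        raise SimulationDivergedError(
            f"non-finite state after step: v={v_new}, u={u_new}"
        )
    if v_new >= SPIKE_PEAK:
        return NeuronState(v=params.c, u=u_new + params.d), True
    return NeuronState(v=v_new, u=u_new), False


def fi_curve(
    params: NeuronParams,
    currents,
    duration: float = 2000.0,
    dt: float = 0.5,
) -> np.ndarray:
    """Firing rate (Hz) versus constant input current.

    Integrates the single neuron from rest for ``duration`` ms at each
    current and returns spikes / duration.  Useful for mapping the
    dimensionless current scale of the model onto physiological pA values by
    comparison with measured FI curves.
    """
    currents = np.asarray(currents, dtype=float)
    if currents.size == 0:
        raise ValueError("current grid must be non-empty")
    if duration < 1000.0:
        raise ValueError("duration must be at least 1000 ms for a stable rate")
    n_steps = int(round(duration / dt))
    rates = np.empty(currents.shape, dtype=float)
    for k, I in enumerate(currents.ravel()):
        state = resting_state(params)
        n_spikes = 0
        for _ in range(n_steps):
            state, spiked = izhikevich_step(state, params, I, dt)
            n_spikes += spiked
        rates.ravel()[k] = n_spikes / (duration / 1000.0)
    return rates


def build_connectivity(
    sizes: dict | list,
    rng_seed: int | np.random.Generator | None = None,
    bounds: dict | None = None,
) -> ConnectivityMatrix:
    """All-to-all random connectivity for one population.

    ``sizes`` maps cell type to neuron count (or is an ordered list of
    ``(cell_type, count)`` pairs).  Each directed pair (i -> j, i != j) gets
    an independent weight drawn uniformly between 0 and the signed bound for
    the ordered (type_i, type_j) pair; self-connections are zero.
    """
    if bounds is None:
        bounds = CONNECTIVITY_BOUNDS
    if isinstance(sizes, dict):
        items = list(sizes.items())
    else:
        items = list(sizes)
    types: list[str] = []
    for ct, n in items:
        ct = CellType(ct)
        if n <= 0:
            raise ValueError("population sizes must be positive")
        types.extend([ct.value] * int(n))
    # plain-string labels: numpy elementwise comparison against enum members
    # is unreliable for str-mixin enums
    type_arr = np.array(types)
    n = len(types)
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    weights = np.zeros((n, n), dtype=float)
    # Draw per ordered type-block; uniform on [0, bound] (sign in the bound).
    for (pre, post), bound in bounds.items():
        rows = np.flatnonzero(type_arr == CellType(pre).value)
        cols = np.flatnonzero(type_arr == CellType(post).value)
        if rows.size == 0 or cols.size == 0 or bound == 0.0:
            continue
        block = rng.uniform(0.0, 1.0, size=(rows.size, cols.size)) * bound
        weights[np.ix_(rows, cols)] = block
    np.fill_diagonal(weights, 0.0)
    return ConnectivityMatrix(weights=weights, pre_type=type_arr, post_type=type_arr)


def update_synaptic_currents(
    syn: SynapticState,
    spikes: np.ndarray,
    W: ConnectivityMatrix,
    dt: float,
) -> SynapticState:
    """Decay PSC accumulators by one step and add the currents of new spikes.

    Each accumulator is multiplied by exp(-dt/tau); every presynaptic spike
    then adds its row of ``W`` instantaneously to the targets' accumulators
    (excitatory rows into ``psc_e``, inhibitory rows into ``psc_i``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    spikes = np.asarray(spikes, dtype=bool)
    psc_e = syn.psc_e * np.exp(-dt / syn.tau_e)
    psc_i = syn.psc_i * np.exp(-dt / syn.tau_i)
    if spikes.any():
        idx = np.flatnonzero(spikes)
        exc = np.array([str(W.pre_type[i]) == CellType.RS.value for i in idx])
        if exc.any():
            psc_e = psc_e + W.weights[idx[exc], :].sum(axis=0)
        if (~exc).any():
            psc_i = psc_i + W.weights[idx[~exc], :].sum(axis=0)
    return SynapticState(psc_e=psc_e, psc_i=psc_i, tau_e=syn.tau_e, tau_i=syn.tau_i)
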