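"""Spike-phase histograms and rate-equalized spike-transmission probability.

Both analyses relate single spikes to the instantaneous gamma phase
extracted from a population signal by the Morlet transform.  The
transmission probability asks, for each spike in the sending area, whether
any of its target neurons in the receiving area fires within a short
synaptic window (1 to 4 ms later, half-open (t+1, t+4]); spikes are binned
by gamma phase, and the bins are equalized by randomly discarding spikes
until all bins hold the same count, so a bin's probability is not inflated
merely because more spikes fall into it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0e, i1e

__all__ = [
    "PhaseHistogram",
    "spike_phase_histogram",
    "transmission_probability",
    "fit_vonmises_concentration",
]


@dataclass
class PhaseHistogram:
    """Normalized spike probability per phase bin over one cycle."""

    bin_centers: np.ndarray  # degrees in [-180, 180)
    probability: np.ndarray
    n_spikes: int

    @property
    def peak_phase(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.probability))])


def _phase_at(spike_times, phase_trace, dt, valid=None):
    """Instantaneous phase at each spike time; drops spikes outside the
    trace (or in invalid edge regions).  Returns (phases, n_dropped)."""
    t = np.asarray(spike_times, dtype=float)
    idx = np.round(t / dt).astype(int)
    ok = (idx >= 0) & (idx < len(phase_trace))
    if valid is not None:
        ok &= np.where(ok, valid[np.clip(idx, 0, len(phase_trace) - 1)], False)
    return phase_trace[idx[ok]], int((~ok).sum()), ok


def spike_phase_histogram(
    spike_times,
    phase_trace: np.ndarray,
    dt: float = 1.0,
    n_bins: int = 16,
    valid: np.ndarray | None = None,
) -> PhaseHistogram:
    """Histogram of spikes against the instantaneous phase of a rhythm.

    ``phase_trace`` is in radians sampled every ``dt`` ms; spikes outside
    the trace (or within flagged edge regions) are dropped.
    """
    phases, _, _ = _phase_at(spike_times, phase_trace, dt, valid)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    wrapped = np.angle(np.exp(1j * phases))
    counts, _ = np.histogram(wrapped, bins=edges)
    total = counts.sum()
    prob = counts / total if total > 0 else np.zeros(n_bins)
    centers = np.rad2deg((edges[:-1] + edges[1:]) / 2)
    return PhaseHistogram(bin_centers=centers, probability=prob, n_spikes=int(total))


def fit_vonmises_concentration(spike_phases) -> tuple[float, float]:
    """Estimate (preferred phase, kappa) of von-Mises phase locking.

    kappa solves I1(kappa)/I0(kappa) = R where R is the mean resultant
    length, via a bracketing search.
    """
    z = np.exp(1j * np.asarray(spike_phases, dtype=float))
    mean = z.mean()
    R = np.abs(mean)
    mu = np.angle(mean)
    if R >= 1.0 - 1e-12:
        return mu, np.inf
    from scipy.optimize import brentq

    if R < 1e-12:
        return mu, 0.0
    # scaled Bessel ratio i1e/i0e == i1/i0 without overflow at large kappa
    kappa = brentq(lambda k: i1e(k) / i0e(k) - R, 1e-9, 1e4)
    return float(mu), float(kappa)


def transmission_probability(
    spikes_pre,
    spikes_post,
    phase_trace: np.ndarray,
    targets: dict | None = None,
    window: tuple[float, float] = (1.0, 4.0),
    n_bins: int = 16,
    seed: int | np.random.Generator | None = None,
    dt: float = 1.0,
    valid: np.ndarray | None = None,
) -> PhaseHistogram:
    """Per-phase-bin probability that a sender spike is followed by a spike
    in one of its targets within the synaptic window.

    ``spikes_pre`` / ``spikes_post`` are (neuron_id, time_ms) pairs given as
    DataFrames with columns ``neuron_id``/``time_ms`` or as tuples of
    arrays.  ``targets`` maps a presynaptic neuron id to an array of its
    postsynaptic neuron ids; None uses all post neurons for every sender.
    Each sender spike is assigned the gamma phase at its time, the binary
    outcome is whether any target fires in (t + w0, t + w1], bins are
    equalized to the minimum positive count by seeded random subsampling,
    and the per-bin mean outcome is returned.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _unpack(s):
        if hasattr(s, "columns"):
            return s["neuron_id"].to_numpy(), s["time_ms"].to_numpy(float)
        ids, times = s
        return np.asarray(ids), np.asarray(times, dtype=float)

    pre_ids, pre_t = _unpack(spikes_pre)
    post_ids, post_t = _unpack(spikes_post)
    order = np.argsort(pre_t)
    pre_ids, pre_t = pre_ids[order], pre_t[order]

    # Per-post-neuron sorted spike times for the window query.
    post_by_neuron: dict = {}
    for nid in np.unique(post_ids):
        post_by_neuron[nid] = np.sort(post_t[post_ids == nid])
    all_post_sorted = np.sort(post_t)

    phases, _, ok = _phase_at(pre_t, phase_trace, dt, valid)
    pre_ids, pre_t = pre_ids[ok], pre_t[ok]

    w0, w1 = window
    outcomes = np.zeros(pre_t.size, dtype=bool)
    for i, (nid, t) in enumerate(zip(pre_ids, pre_t)):
        if targets is None:
            ts = all_post_sorted
            lo = np.searchsorted(ts, t + w0, side="right")
            hi = np.searchsorted(ts, t + w1, side="right")
            outcomes[i] = hi > lo
        else:
            for tgt in targets.get(nid, ()):
                ts = post_by_neuron.get(tgt)
                if ts is None:
                    continue
                lo = np.searchsorted(ts, t + w0, side="right")
                hi = np.searchsorted(ts, t + w1, side="right")
                if hi > lo:
                    outcomes[i] = True
                    break

    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    wrapped = np.angle(np.exp(1j * phases))
    bin_idx = np.clip(np.digitize(wrapped, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(bin_idx, minlength=n_bins)
    positive = counts[counts > 0]
    if positive.size == 0:
        raise ValueError("no sender spikes fall inside the phase trace")
    n_keep = int(positive.min())
    prob = np.zeros(n_bins)
    for b in range(n_bins):
        members = np.flatnonzero(bin_idx == b)
        if members.size == 0:
            continue
        keep = rng.choice(members, size=n_keep, replace=False)
        prob[b] = outcomes[keep].mean()
    centers = np.rad2deg((edges[:-1] + edges[1:]) / 2)
    return PhaseHistogram(
        bin_centers=centers, probability=prob, n_spikes=int(n_keep * (counts > 0).sum())
    )
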