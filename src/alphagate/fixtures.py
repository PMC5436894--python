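"""Parametric signal and spike-train generators with known ground truth.

These generators exist to give the analysis modules independent oracles:
every fixture stores the true quantity it was built around (time-domain
Granger causality from nested residual variances, expected phase-locking
from the wrapped-normal characteristic function, the von-Mises preferred
phase and concentration of a modulated point process), so estimator tests
can check convergence toward a value that was never produced by the code
under test.  Fixture randomness is seeded independently of the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VarFixture",
    "PhaseLockedFixture",
    "SpikeFixture",
    "gen_var_process",
    "analytic_var_gc",
    "gen_phase_locked_oscillation",
    "gen_modulated_spikes",
    "gen_direction_switch",
]


@dataclass
class VarFixture:
    data: np.ndarray  # (trials, channels, time)
    coeffs: np.ndarray  # (p, n, n)
    sigma: np.ndarray
    true_gc: dict  # (source, target) -> time-domain GC, nats


@dataclass
class PhaseLockedFixture:
    x: np.ndarray  # (trials, time)
    y: np.ndarray
    f0: float
    expected_phase_locking: float  # |E[e^{i dtheta}]| in closed form


@dataclass
class SpikeFixture:
    spike_times: np.ndarray  # ms
    phase_trace: np.ndarray  # radians per 1 ms sample
    preferred_phase: float  # radians
    kappa: float


def _companion_stable(coeffs: np.ndarray) -> bool:
    p, n, _ = coeffs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = coeffs.transpose(1, 0, 2).reshape(n, n * p)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return np.max(np.abs(np.linalg.eigvals(comp))) < 1.0


def analytic_var_gc(coeffs: np.ndarray, sigma: np.ndarray, source: int, target: int,
                    red_order: int = 60) -> float:
    """Time-domain GC source -> target of a VAR by nested residual variances,
    in closed form.

    The full-model residual variance of the target is sigma[target, target].
    The reduced-model variance follows from the process autocovariances:
    the stationary state covariance solves the discrete Lyapunov equation of
    the companion form, lagged covariances follow by recursion, and the
    best linear predictor of the target from its own past at generous order
    is a Toeplitz (Yule-Walker) solve.  No simulation, no estimator under
    test is involved.
    """
    from scipy.linalg import solve_discrete_lyapunov, solve_toeplitz

    p, n, _ = coeffs.shape
    A = np.zeros((n * p, n * p))
    A[:n, :] = coeffs.transpose(1, 0, 2).reshape(n, n * p)
    if p > 1:
        A[n:, :-n] = np.eye(n * (p - 1))
    Q = np.zeros((n * p, n * p))
    Q[:n, :n] = sigma
    P = solve_discrete_lyapunov(A, Q)
    # autocovariance of the target channel at lags 0..red_order
    gammas = [P[target, target]]
    Ak_P = P
    for _ in range(red_order):
        Ak_P = A @ Ak_P
        gammas.append(Ak_P[target, target])
    gammas = np.asarray(gammas)
    r = gammas[1:]
    phi = solve_toeplitz(gammas[:-1], r)
    var_red = gammas[0] - phi @ r
    return float(np.log(var_red / sigma[target, target]))


def simulate_var(coeffs: np.ndarray, sigma: np.ndarray, n: int,
                 rng: np.random.Generator, burn: int = 500) -> np.ndarray:
    p, n_ch, _ = coeffs.shape
    L = np.linalg.cholesky(sigma)
    total = n + burn
    x = np.zeros((n_ch, total))
    eps = L @ rng.normal(size=(n_ch, total))
    for t in range(p, total):
        acc = eps[:, t].copy()
        for k in range(p):
            acc += coeffs[k] @ x[:, t - k - 1]
        x[:, t] = acc
    return x[:, burn:]


def gen_var_process(
    coeffs,
    sigma,
    n: int,
    trials: int = 1,
    seed: int | None = None,
) -> VarFixture:
    """Simulate a stable VAR and attach its true directed GC values."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim == 2:
        coeffs = coeffs[None]
    sigma = np.asarray(sigma, dtype=float)
    if not _companion_stable(coeffs):
        raise ValueError("unstable VAR coefficients")
    rng = np.random.default_rng(seed)
    data = np.stack([simulate_var(coeffs, sigma, n, rng) for _ in range(trials)])
    n_ch = coeffs.shape[1]
    true_gc = {}
    for s in range(n_ch):
        for t in range(n_ch):
            if s != t:
                true_gc[(s, t)] = analytic_var_gc(coeffs, sigma, s, t)
    return VarFixture(data=data, coeffs=coeffs, sigma=sigma, true_gc=true_gc)


def gen_phase_locked_oscillation(
    f0: float = 40.0,
    jitter_sd: float = 0.5,
    amp_sd: float = 0.0,
    trials: int = 50,
    n: int = 2000,
    noise_sd: float = 0.1,
    seed: int | None = None,
    fs: float = 1000.0,
) -> PhaseLockedFixture:
    """Pairs of sinusoids with wrapped-normal relative-phase jitter.

    The expected phase-locking value is the wrapped-normal characteristic
    function exp(-jitter_sd^2 / 2).  Per-trial amplitudes are lognormal-free
    positive gaussians around 1 with sd ``amp_sd`` (clipped at 0.1).
    """
    if f0 >= fs / 2:
        raise ValueError("f0 must be below Nyquist")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = np.empty((trials, n))
    y = np.empty((trials, n))
    for m in range(trials):
        phi0 = rng.uniform(0, 2 * np.pi)
        dphi = rng.normal(0.0, jitter_sd)
        ax = max(0.1, rng.normal(1.0, amp_sd)) if amp_sd > 0 else 1.0
        ay = max(0.1, rng.normal(1.0, amp_sd)) if amp_sd > 0 else 1.0
        x[m] = ax * np.cos(2 * np.pi * f0 * t + phi0) + rng.normal(0, noise_sd, n)
        y[m] = ay * np.cos(2 * np.pi * f0 * t + phi0 + dphi) + rng.normal(0, noise_sd, n)
    return PhaseLockedFixture(
        x=x, y=y, f0=f0, expected_phase_locking=float(np.exp(-(jitter_sd**2) / 2))
    )


def gen_modulated_spikes(
    base_rate: float,
    phase_trace: np.ndarray,
    kappa: float = 0.0,
    preferred_phase: float = 0.0,
    dt: float = 1.0,
    seed: int | None = None,
) -> SpikeFixture:
    """Inhomogeneous Poisson spikes with von-Mises phase modulation.

    rate(t) = base_rate * exp(kappa * cos(phase(t) - preferred)) / I0(kappa)
    keeps the cycle-averaged rate equal to ``base_rate`` (Hz).
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    from scipy.special import i0

    rng = np.random.default_rng(seed)
    phase_trace = np.asarray(phase_trace, dtype=float)
    rate = base_rate * np.exp(kappa * np.cos(phase_trace - preferred_phase)) / i0(kappa)
    p_spike = rate * dt / 1000.0
    hits = rng.uniform(size=phase_trace.size) < p_spike
    times = np.flatnonzero(hits) * dt
    return SpikeFixture(
        spike_times=times.astype(float),
        phase_trace=phase_trace,
        preferred_phase=preferred_phase,
        kappa=kappa,
    )


def gen_direction_switch(
    n_half: int = 2000,
    coupling: float = 0.5,
    seed: int | None = None,
) -> np.ndarray:
    """Two-channel series whose causal direction flips at the midpoint.

    First half: x drives y with lag 1; second half: y drives x.  Returns an
    array of shape (2, 2 * n_half).
    """
    rng = np.random.default_rng(seed)
    a = 0.5

    def _uni(n, forward):
        x = np.zeros(n)
        y = np.zeros(n)
        ex = rng.normal(size=n)
        ey = rng.normal(size=n)
        for t in range(1, n):
            if forward:
                x[t] = a * x[t - 1] + ex[t]
                y[t] = a * y[t - 1] + coupling * x[t - 1] + ey[t]
            else:
                y[t] = a * y[t - 1] + ey[t]
                x[t] = a * x[t - 1] + coupling * y[t - 1] + ex[t]
        return np.stack([x, y])

    return np.concatenate([_uni(n_half, True), _uni(n_half, False)], axis=1)
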