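"""Coupled noisy alpha-phase trajectories and their modulation currents.

Two phase oscillators, one per cortical area, stand in for the alpha-band
drive a higher-order thalamic nucleus (pulvinar) sends to each area.  Each
phase advances at an average rate of 2*pi*10 Hz with white frequency noise,
and a Kuramoto-style coupling of strength ``J`` pulls the instantaneous
phase difference phi1 - phi2 toward a configurable target offset
``delta_phi``:

    dphi1/dt = w0 + eta1(t) + J sin((phi2 + delta_phi) - phi1)
    dphi2/dt = w0 + eta2(t) + J sin((phi1 - delta_phi) - phi2)

With delta_phi = 0 this reduces to the classic symmetric two-oscillator
Kuramoto model; a nonzero target simply shifts the locked configuration so
that an arbitrary phase difference is maintained against the noise.

The phase is converted to an injected current either as
``A * sin^2(phi/2)`` (non-negative, mean A/2, effective frequency 10 Hz
because the squared waveform doubles the frequency of the half-rate phase)
or as a plain zero-mean ``A * sin(phi)`` control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AlphaConfig",
    "PhaseTrace",
    "generate_coupled_phases",
    "modulation_current",
    "wrap_degrees",
    "PA_TO_MODEL",
]

# Conversion from the pA values quoted at the interfaces to the neuron
# model's dimensionless current units.  The model's currents have no
# physical scale of their own; this factor is calibrated so that the
# 0-45 pA alpha-amplitude range spans the qualitative regimes expected of
# it (moderate rhythmic gating of the excitatory population at 23 pA,
# near-complete silencing of the low-activity phase only near 45 pA).
PA_TO_MODEL = 0.13


def wrap_degrees(x):
    """Wrap angles in degrees to [-180, 180)."""
    return (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class AlphaConfig:
    """Settings of the alpha-band modulation.

    amplitude : peak current of the modulation, pA (23 by default).
    base_freq : mean oscillation frequency, Hz.
    coupling : Kuramoto coupling strength J, rad/ms; 0.2 holds the offset
        tightly against the default phase noise.
    target_offset : desired phase difference phi1 - phi2, degrees.
    phase_noise_sd : white frequency-noise amplitude, rad/sqrt(ms).
    waveform : 'sin2' (non-negative, biologically plausible default) or
        'sin' (zero-mean control).
    """

    amplitude: float = 23.0
    base_freq: float = 10.0
    coupling: float = 0.2
    target_offset: float = 0.0
    phase_noise_sd: float = 0.05
    waveform: str = "sin2"

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.base_freq <= 0:
            raise ValueError("base_freq must be positive")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")
        if self.waveform not in ("sin2", "sin"):
            raise ValueError("waveform must be 'sin2' or 'sin'")
        self.target_offset = float(wrap_degrees(self.target_offset))


@dataclass
class PhaseTrace:
    """Unwrapped phase time series (radians) sampled every ``dt`` ms."""

    phases: np.ndarray
    dt: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.phases.size) * self.dt


def generate_coupled_phases(
    config: AlphaConfig,
    duration: float,
    dt: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> tuple[PhaseTrace, PhaseTrace]:
    """Euler-integrate the two coupled noisy phases over ``duration`` ms.

    The traces have ``round(duration/dt) + 1`` samples including t = 0 and
    start in the locked configuration (phi1 - phi2 equal to the target
    offset), so the offset statistics are stationary from the start.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration / dt)) + 1
    w0 = 2 * np.pi * config.base_freq / 1000.0  # rad/ms
    offset = np.deg2rad(config.target_offset)
    J = config.coupling
    sd = config.phase_noise_sd * np.sqrt(dt)
    phi1 = np.empty(n)
    phi2 = np.empty(n)
    phi1[0] = offset
    phi2[0] = 0.0
    noise = rng.normal(0.0, 1.0, size=(n - 1, 2)) * sd if sd > 0 else np.zeros((n - 1, 2))
    for k in range(n - 1):
        p1, p2 = phi1[k], phi2[k]
        d1 = w0 * dt + noise[k, 0] + J * np.sin((p2 + offset) - p1) * dt
        d2 = w0 * dt + noise[k, 1] + J * np.sin((p1 - offset) - p2) * dt
        phi1[k + 1] = p1 + d1
        phi2[k + 1] = p2 + d2
    return PhaseTrace(phi1, dt), PhaseTrace(phi2, dt)


def modulation_current(
    trace: PhaseTrace, A: float, waveform: str = "sin2"
) -> np.ndarray:
    """Convert a phase trace to an injected current time series (pA).

    'sin2' gives A*sin^2(phi/2): non-negative, mean A/2, fundamental at the
    phase's base frequency (the half-rate argument is squared back up).
    'sin' gives the zero-mean control A*sin(phi).
    """
    if waveform == "sin2":
        return A * np.sin(trace.phases / 2.0) ** 2
    if waveform == "sin":
        return A * np.sin(trace.phases)
    raise ValueError("waveform must be 'sin2' or 'sin'")
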