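"""Multitaper spectra, coherence (with amplitude/phase decomposition and
trial-shuffle bias), complex Morlet wavelet transforms, and alpha-phase to
gamma-power coupling curves.

All estimators assume population spike-time histograms sampled at 1 kHz
(1 ms bins), the package's proxy for the local field potential.  Spectra
use Slepian (DPSS) tapers with a time-half-bandwidth product NW = 5 and
K = 2 NW - 1 = 9 tapers, giving a half-bandwidth W = NW / T (2.5 Hz for the
standard 2000 ms trial).

The coherence between two signals x, y is

    C(f) = |S_xy(f)|^2 / (S_xx(f) S_yy(f)),

with cross- and auto-spectra averaged over tapers and trials.  Coherence
mixes two sources of across-trial covariation, and the decomposition
separates them: the *phase component* discards amplitude information by
averaging unit-magnitude cross-spectral terms (so it grows when the
relative phase of the two signals is consistent across trials/tapers), and
the *amplitude component* is the across-trial correlation of the two
spectral amplitudes (so it grows when the two areas' power fluctuates up
and down together).  Both lie in [0, 1].  A shuffle estimate of the bias of
either quantity is obtained by re-pairing trials at random (never pairing a
trial with itself), which destroys genuine single-trial coupling but keeps
slow commonalities such as a shared alpha envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, windows

__all__ = [
    "SpectralEstimate",
    "CoherenceDecomposition",
    "TimeFreq",
    "multitaper_psd",
    "multitaper_coherence",
    "coherence_components",
    "shuffle_bias",
    "morlet_transform",
    "band_metrics",
    "gamma_power_trace",
    "alpha_gamma_coupling",
]

FS = 1000.0  # Hz; STH bins are 1 ms throughout


@dataclass
class SpectralEstimate:
    """Frequency-resolved power or coherence values."""

    freqs: np.ndarray
    values: np.ndarray
    n_tapers: int
    bandwidth: float  # half-bandwidth W in Hz
    n_trials: int


@dataclass
class CoherenceDecomposition:
    freqs: np.ndarray
    total: np.ndarray
    amplitude_component: np.ndarray
    phase_component: np.ndarray
    n_trials: int


@dataclass
class TimeFreq:
    """Complex Morlet coefficients on a (frequency, time) grid.

    ``power`` is |coefficient|^2 and ``phase`` its argument in (-pi, pi].
    ``valid`` flags samples further than two Gaussian widths from either
    edge of the signal, where the convolution is uncontaminated.
    """

    freqs: np.ndarray
    times: np.ndarray
    coefficients: np.ndarray  # shape (n_freqs, n_times)
    valid: np.ndarray  # bool, same shape

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.coefficients)


def _as_trials(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError("trials must be a 1-D series or a (trials, time) array")
    return x


def _taper_ffts(trials: np.ndarray, nw: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-trial, per-taper FFTs; returns (freqs, X[trial, taper, freq], K)."""
    n_trials, n = trials.shape
    k = int(2 * nw - 1)
    tapers = windows.dpss(n, nw, Kmax=k)  # (k, n), unit-energy tapers
    tapered = trials[:, None, :] * tapers[None, :, :]
    X = np.fft.rfft(tapered, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / FS)
    return freqs, X, k


def multitaper_psd(trials, nw: float = 5.0) -> SpectralEstimate:
    """Trial- and taper-averaged multitaper power spectral density.

    Accepts a single series or a (trials, time) array of equal-length
    trials; unit-energy DPSS tapers make the estimate satisfy Parseval
    (mean power over frequencies equals the signal variance for detrended
    input; no detrending is applied here).
    """
    trials = _as_trials(trials)
    freqs, X, k = _taper_ffts(trials, nw)
    n = trials.shape[1]
    # Unit-energy tapers: E|X(f)|^2 equals the variance contributed per
    # frequency bin, so a white-noise spectrum is flat at the signal
    # variance (Parseval) without further scaling.
    psd = (np.abs(X) ** 2).mean(axis=(0, 1))
    return SpectralEstimate(
        freqs=freqs,
        values=psd,
        n_tapers=k,
        bandwidth=nw / (n / FS),
        n_trials=trials.shape[0],
    )


def _cross_spectra(x_trials, y_trials, nw):
    x = _as_trials(x_trials)
    y = _as_trials(y_trials)
    if x.shape != y.shape:
        raise ValueError("x and y must have matching trial counts and lengths")
    freqs, X, k = _taper_ffts(x, nw)
    _, Y, _ = _taper_ffts(y, nw)
    return freqs, X, Y, k


def multitaper_coherence(x_trials, y_trials, nw: float = 5.0) -> SpectralEstimate:
    """Magnitude-squared coherence averaged over tapers and trials.

    Frequencies where either signal has zero power get value ``nan`` via a
    guarded division (they carry no phase information), not a propagated
    warning.
    """
    n = _as_trials(x_trials).shape[1]
    freqs, X, Y, k = _cross_spectra(x_trials, y_trials, nw)
    sxy = (X * np.conj(Y)).mean(axis=(0, 1))
    sxx = (np.abs(X) ** 2).mean(axis=(0, 1))
    syy = (np.abs(Y) ** 2).mean(axis=(0, 1))
    denom = sxx * syy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(sxy) ** 2 / np.where(denom > 0, denom, 1.0), np.nan)
    return SpectralEstimate(
        freqs=freqs,
        values=coh,
        n_tapers=k,
        bandwidth=nw / (n / FS),
        n_trials=X.shape[0],
    )


def _phase_component(X, Y):
    """Coherence of unit-magnitude per-trial cross-spectra.

    Tapers are averaged within a trial before normalization (individual
    tapers can have spectral nulls whose phase is pure noise); the squared
    resultant of the unit vectors across trials then measures phase
    consistency with all amplitude information removed."""
    sxy = (X * np.conj(Y)).mean(axis=1)  # (trials, freq)
    mag = np.abs(sxy)
    unit = np.where(mag > 0, sxy / np.where(mag > 0, mag, 1.0), 0.0)
    return np.abs(unit.mean(axis=0)) ** 2


def _amplitude_component(X, Y):
    """Across-trial Pearson correlation of taper-averaged spectral
    amplitudes, floored at zero (anticorrelated amplitudes carry no
    coherence).  Tapers are averaged within a trial first so that the
    deterministic taper-to-taper leakage pattern does not masquerade as
    amplitude covariation."""
    ax = np.abs(X).mean(axis=1)
    ay = np.abs(Y).mean(axis=1)
    ax = ax - ax.mean(axis=0)
    ay = ay - ay.mean(axis=0)
    num = (ax * ay).sum(axis=0)
    den = np.sqrt((ax**2).sum(axis=0) * (ay**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(r, 0.0, 1.0)


def coherence_components(x_trials, y_trials, nw: float = 5.0) -> CoherenceDecomposition:
    """Split coherence into amplitude-covariation and phase-consistency parts."""
    x = _as_trials(x_trials)
    if x.shape[0] < 2:
        raise ValueError("coherence decomposition needs at least 2 trials")
    freqs, X, Y, _ = _cross_spectra(x_trials, y_trials, nw)
    total = multitaper_coherence(x_trials, y_trials, nw).values
    return CoherenceDecomposition(
        freqs=freqs,
        total=total,
        amplitude_component=_amplitude_component(X, Y),
        phase_component=_phase_component(X, Y),
        n_trials=X.shape[0],
    )


def shuffle_bias(
    x_trials,
    y_trials,
    n_shuffles: int = 20,
    seed: int | np.random.Generator | None = None,
    nw: float = 5.0,
    component: str = "total",
) -> SpectralEstimate:
    """Coherence bias estimated from randomly re-paired trials.

    Each shuffle applies a random derangement to the y-trials (no trial is
    ever paired with itself) and recomputes the requested quantity
    ('total', 'phase' or 'amplitude'); the mean over shuffles estimates the
    bias floor induced by finite trial counts and shared slow modulation.
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    x = _as_trials(x_trials)
    y = _as_trials(y_trials)
    if x.shape[0] < 3:
        raise ValueError("shuffle bias needs at least 3 trials")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = x.shape[0]
    acc = None
    for _ in range(n_shuffles):
        while True:
            perm = rng.permutation(m)
            if not np.any(perm == np.arange(m)):
                break
        if component == "total":
            vals = multitaper_coherence(x, y[perm], nw).values
        else:
            dec = coherence_components(x, y[perm], nw)
            vals = dec.phase_component if component == "phase" else dec.amplitude_component
        acc = vals if acc is None else acc + vals
    freqs = np.fft.rfftfreq(x.shape[1], d=1.0 / FS)
    return SpectralEstimate(
        freqs=freqs,
        values=acc / n_shuffles,
        n_tapers=int(2 * nw - 1),
        bandwidth=nw / (x.shape[1] / FS),
        n_trials=m,
    )


def morlet_transform(signal, freqs, fs: float = FS) -> TimeFreq:
    """Complex Morlet wavelet transform on a grid of center frequencies.

    The Gaussian envelope width scales as sigma_t = 1/f0 (one period of the
    center frequency), trading frequency precision for the temporal
    resolution needed to track gamma phase cycle by cycle.  Wavelets are
    L1-normalized so a unit-amplitude sinusoid at f0 yields |coefficient|
    independent of f0.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    if np.any(freqs > fs / 2):
        raise ValueError("frequency above Nyquist")
    n = signal.size
    times = np.arange(n) / fs * 1000.0  # ms
    coeffs = np.empty((freqs.size, n), dtype=complex)
    valid = np.ones((freqs.size, n), dtype=bool)
    for i, f0 in enumerate(freqs):
        sigma_t = 1.0 / f0  # seconds
        half = int(np.ceil(4 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        envelope = np.exp(-(t**2) / (2 * sigma_t**2))
        wavelet = envelope * np.exp(2j * np.pi * f0 * t)
        wavelet /= envelope.sum()
        # env is even, so convolving with psi equals correlating with psi*,
        # giving a phase that advances at +2*pi*f0 and is 0 at signal peaks.
        coeffs[i] = fftconvolve(signal, wavelet, mode="same")
        edge = int(np.ceil(2 * sigma_t * fs))
        valid[i, :edge] = False
        if edge > 0:
            valid[i, -edge:] = False
    return TimeFreq(freqs=freqs, times=times, coefficients=coeffs, valid=valid)


def band_metrics(
    spectrum: SpectralEstimate,
    search_band: tuple[float, float] = (20.0, 80.0),
    half_width: float = 10.0,
) -> tuple[float, float]:
    """Locate the spectral peak in a search band and average power around it.

    Returns (peak frequency, mean power over peak +/- ``half_width`` Hz).
    """
    f, p = spectrum.freqs, spectrum.values
    lo, hi = search_band
    if lo < f[0] or hi > f[-1]:
        raise ValueError("search band outside the spectrum")
    m = (f >= lo) & (f <= hi)
    peak_idx = np.nanargmax(p[m])
    peak_freq = f[m][peak_idx]
    band = (f >= peak_freq - half_width) & (f <= peak_freq + half_width)
    return float(peak_freq), float(np.nanmean(p[band]))


def gamma_power_trace(
    signal, band: tuple[float, float] = (20.0, 50.0), n_freqs: int = 7
) -> tuple[np.ndarray, np.ndarray]:
    """Time-resolved gamma power: Morlet power averaged over a fixed band.

    Returns (power trace, validity mask) sampled at the signal rate.
    """
    freqs = np.linspace(band[0], band[1], n_freqs)
    tf = morlet_transform(signal, freqs)
    power = tf.power.mean(axis=0)
    valid = tf.valid.all(axis=0)
    return power, valid


def alpha_gamma_coupling(
    alpha_phase: np.ndarray,
    gamma_power: np.ndarray,
    n_bins: int = 12,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean gamma power per alpha-phase bin.

    ``alpha_phase`` is in radians (wrapped or unwrapped); bins tile
    [-180, 180) degrees.  Returns (bin centers in degrees, mean power per
    bin); empty bins yield nan.
    """
    alpha_phase = np.asarray(alpha_phase, dtype=float)
    gamma_power = np.asarray(gamma_power, dtype=float)
    if alpha_phase.shape != gamma_power.shape:
        raise ValueError("phase and power traces must be time-aligned")
    if valid is not None:
        alpha_phase = alpha_phase[valid]
        gamma_power = gamma_power[valid]
    wrapped = np.angle(np.exp(1j * alpha_phase))  # (-pi, pi]
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(wrapped, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = idx == b
        if m.any():
            means[b] = gamma_power[m].mean()
    centers = np.rad2deg((edges[:-1] + edges[1:]) / 2)
    return centers, means
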